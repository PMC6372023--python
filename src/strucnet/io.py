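"""Reading, writing and validation of connectomes, manifests and run configs.

All on-disk formats are plain delimited text: CSV connectivity matrices
(89 data rows, optional single header row of atlas labels, full double
precision), a CSV cohort manifest and a YAML run configuration.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import N_NODES, default_atlas

__all__ = [
    "ConnectivityMatrix",
    "MatrixValidationError",
    "RunConfig",
    "TIMEPOINTS",
    "read_manifest",
    "read_matrix",
    "validate_manifest",
    "write_manifest",
    "write_matrix",
    "write_report",
]

SYMMETRY_TOL = 1e-10
TIMEPOINTS = ("T1", "T2", "T3")

#: canonical crossover-arm tokens; long aliases accepted on read
_ORDER_ALIASES = {
    "order0": "order0",
    "order0_sham_first": "order0",
    "order1": "order1",
    "order1_active_first": "order1",
    "none": "none",
    "": "none",
}


class MatrixValidationError(ValueError):
    """A connectivity matrix violates a structural invariant."""


@dataclass
class ConnectivityMatrix:
    """One subject-timepoint weighted structural network.

    ``weights`` is a symmetric nonnegative real matrix in connection-density
    units (dimensionless, tractography streamline density), zero diagonal.
    """

    subject_id: str
    timepoint: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        validate_weights(self.weights)
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def validate_weights(w: np.ndarray, n_nodes: int = N_NODES) -> None:
    """Raise :class:`MatrixValidationError` unless ``w`` is a valid weight matrix."""
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise MatrixValidationError(f"weights must be square, got shape {w.shape}")
    if n_nodes is not None and w.shape[0] != n_nodes:
        raise MatrixValidationError(
            f"expected {n_nodes}x{n_nodes} matrix, got {w.shape[0]}x{w.shape[1]}"
        )
    if not np.all(np.isfinite(w)):
        raise MatrixValidationError("weights contain non-finite entries")
    asym = np.abs(w - w.T).max() if w.size else 0.0
    if asym > SYMMETRY_TOL:
        raise MatrixValidationError(f"asymmetry {asym:g} exceeds tolerance {SYMMETRY_TOL:g}")
    if (w < 0).any():
        raise MatrixValidationError("negative weights present")
    if w.size and np.abs(np.diagonal(w)).max() > SYMMETRY_TOL:
        raise MatrixValidationError("nonzero diagonal beyond tolerance")


def _parse_subject_timepoint(path: Path) -> tuple[str, str]:
    stem = path.stem
    if "_" in stem:
        sid, _, tp = stem.rpartition("_")
        if tp in TIMEPOINTS:
            return sid, tp
    return stem, "T1"


def read_matrix(path, atlas: pd.DataFrame | None = None) -> ConnectivityMatrix:
    """Read a CSV connectivity matrix, validating every structural invariant.

    The subject id and timepoint are taken from the file stem
    (``<subject>_<T1|T2|T3>.csv``; bare stems default to T1).  An optional
    single header row of atlas labels is detected and, when an atlas table
    is supplied, checked against its node order.
    """
    path = Path(path)
    if atlas is None:
        atlas = default_atlas()
    with open(path) as fh:
        first = fh.readline()
        tokens = [t.strip() for t in first.strip().split(",")]
        has_header = False
        for tok in tokens:
            try:
                float(tok) if tok else 0.0
            except ValueError:
                has_header = True
                break
        if has_header:
            labels = [t for t in tokens if t]
            expected = list(atlas["label"])
            if labels != expected:
                raise MatrixValidationError(
                    f"{path.name}: header labels do not match the atlas node order"
                )
            body = fh.read()
        else:
            body = first + fh.read()
    w = np.loadtxt(_io.StringIO(body), delimiter=",", ndmin=2)
    n = len(atlas)
    if w.shape != (n, n):
        raise MatrixValidationError(
            f"{path.name}: expected {n}x{n} matrix, got {w.shape[0]}x{w.shape[1]}"
        )
    validate_weights(w, n_nodes=n)
    # average out sub-tolerance asymmetry so downstream code sees exact symmetry
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    sid, tp = _parse_subject_timepoint(path)
    return ConnectivityMatrix(subject_id=sid, timepoint=tp, weights=w)


def write_matrix(cm: ConnectivityMatrix, path, atlas: pd.DataFrame | None = None,
                 header: bool = True) -> None:
    """Write a matrix as CSV in full double precision (round-trips bitwise)."""
    if atlas is None:
        atlas = default_atlas()
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(",".join(atlas["label"]) + "\n")
        for row in cm.weights:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def matrix_path(directory, subject_id: str, timepoint: str) -> Path:
    return Path(directory) / f"{subject_id}_{timepoint}.csv"


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ["subject_id", "group", "age", "sex", "order",
                     "hdrs_t1", "hdrs_t2", "hdrs_t3"]


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(_MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    df = df[_MANIFEST_COLUMNS].copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id rows: {dupes}")
    bad_group = set(df["group"]) - {"control", "patient"}
    if bad_group:
        raise ValueError(f"unknown group tokens: {sorted(bad_group)}")
    order = df["order"].fillna("").astype(str).str.strip().str.lower()
    unknown = set(order) - set(_ORDER_ALIASES)
    if unknown:
        raise ValueError(f"unknown order tokens: {sorted(unknown)}")
    df["order"] = order.map(_ORDER_ALIASES)
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"unknown sex tokens: {sorted(bad_sex)}")
    controls = df["group"] == "control"
    if (df.loc[controls, "order"] != "none").any():
        offenders = df.loc[controls & (df["order"] != "none"), "subject_id"].tolist()
        raise ValueError(f"controls with a crossover order assigned: {offenders}")
    if (df.loc[~controls, "order"] == "none").any():
        offenders = df.loc[~controls & (df["order"] == "none"), "subject_id"].tolist()
        raise ValueError(f"patients without a crossover order: {offenders}")
    for col in ("hdrs_t1", "hdrs_t2", "hdrs_t3"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype("Float64")
        if (df[col].dropna() < 0).any():
            raise ValueError(f"negative HDRS values in {col}")
    df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
    return df.reset_index(drop=True)


def read_manifest(path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path))


def write_manifest(df: pd.DataFrame, path) -> None:
    validate_manifest(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Analysis settings: density grid, permutation and null-model counts, seed."""

    d_min: float = 0.10
    d_max: float = 0.20
    d_step: float = 0.01
    n_perm: int = 5000
    n_null: int = 20
    swaps_per_edge: int = 10
    seed: int = 0
    global_metrics: list[str] = field(default_factory=lambda: [
        "sigma", "gamma", "lambda", "global_efficiency",
        "clustering_coefficient", "modularity_q", "assortativity_r",
    ])
    nodal_metrics: list[str] = field(default_factory=lambda: [
        "degree", "local_efficiency", "betweenness", "clustering",
    ])
    longitudinal_metrics: list[str] = field(default_factory=lambda: [
        "mean_betweenness", "gamma", "lambda", "sigma",
        "global_efficiency", "local_efficiency", "modularity_q",
    ])

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max <= 1):
            raise ValueError("require 0 < d_min < d_max <= 1")
        if self.n_perm < 1 or self.n_null < 1:
            raise ValueError("n_perm and n_null must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def write_report(outdir, tables: dict[str, pd.DataFrame], *,
                 config: RunConfig | None = None, log_lines: list[str] | None = None) -> list[Path]:
    """Write analysis tables as CSV plus a plain-text run log.

    ``tables`` maps basenames (without extension) to data frames; empty
    frames produce header-only files.  Returns the written paths.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    log = outdir / "run_log.txt"
    with open(log, "w") as fh:
        fh.write(f"strucnet version {__version__}\n")
        if config is not None:
            fh.write(f"density grid: {config.d_min}:{config.d_step}:{config.d_max}\n")
            fh.write(f"permutations: {config.n_perm}\n")
            fh.write(f"null networks: {config.n_null}\n")
            fh.write(f"swaps per edge: {config.swaps_per_edge}\n")
            fh.write(f"seed: {config.seed}\n")
        for line in log_lines or []:
            fh.write(line.rstrip() + "\n")
    written.append(log)
    return written
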