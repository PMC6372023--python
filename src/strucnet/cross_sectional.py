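"""Baseline group inference: AUC summarization, permutation tests, hubs.

Each subject's metric-versus-density curve is reduced to one trapezoidal
area-under-the-curve (AUC) scalar, AUCs are age-adjusted by pooled OLS
residualization, and group differences (patients minus controls) are tested
with label-shuffling permutation tests (default 5,000 repetitions, two-
tailed, +1-corrected p).  Regional tests run the same engine per node with
Benjamini–Hochberg FDR correction across nodes.  Hubs are nodes whose
group-mean betweenness AUC exceeds the network mean by more than two
population standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .io import ConnectivityMatrix, RunConfig
from .thresholding import DensityGrid, metric_curves, threshold_at_density
from . import metrics as gm

__all__ = [
    "HubSet",
    "PermutationResult",
    "age_adjust",
    "auc",
    "cross_sectional_analysis",
    "identify_hubs",
    "nodal_metric_curves",
    "permutation_test_global",
    "permutation_test_nodal",
]

log = logging.getLogger(__name__)


def auc(values, densities) -> float:
    """Trapezoidal area under a metric curve over the density grid."""
    values = np.asarray(values, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if len(values) < 2:
        raise ValueError("AUC needs at least 2 grid points")
    if not np.all(np.diff(densities) > 0):
        raise ValueError("densities must be strictly increasing")
    return float(np.trapezoid(values, densities))


def age_adjust(values: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Residualize values on age over the pooled sample, re-adding the grand mean.

    ``values`` may be a vector (one metric) or an (n_subjects, k) matrix;
    the regression is fitted per column.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(ages) < 3:
        raise ValueError("age adjustment needs at least 3 subjects")
    if np.ptp(ages) == 0:
        raise ValueError("zero age variance: cannot adjust for age")
    squeeze = values.ndim == 1
    y = values.reshape(len(ages), -1)
    x = np.column_stack([np.ones_like(ages), ages])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    adjusted = y - x @ beta + y.mean(axis=0)
    return adjusted[:, 0] if squeeze else adjusted


@dataclass
class PermutationResult:
    """Observed group contrast, its permutation null distribution and p-value."""

    metric: str
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def _null_group_diffs(adjusted: np.ndarray, is_patient: np.ndarray,
                      n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Difference of group means under random label reassignment that
    preserves the original group sizes.  Vectorized via indicator matrices."""
    n = len(is_patient)
    n_pat = int(is_patient.sum())
    y = adjusted.reshape(n, -1)
    ranks = rng.random((n_perm, n)).argsort(axis=1)
    indicator = (ranks < n_pat).astype(float)  # 1 where subject assigned "patient"
    pat_mean = indicator @ y / n_pat
    ctrl_mean = (1.0 - indicator) @ y / (n - n_pat)
    out = pat_mean - ctrl_mean
    return out[:, 0] if adjusted.ndim == 1 else out


def permutation_test_global(auc_values, is_patient, ages, n_perm: int = 5000,
                            seed: int = 0, metric: str = "") -> PermutationResult:
    """Two-tailed permutation test on the age-adjusted group-mean AUC difference.

    p = (1 + #{|null| >= |observed|}) / (n_perm + 1).
    """
    auc_values = np.asarray(auc_values, dtype=float)
    is_patient = np.asarray(is_patient, dtype=bool)
    n_pat, n_ctrl = int(is_patient.sum()), int((~is_patient).sum())
    if n_pat < 2 or n_ctrl < 2:
        raise ValueError("each group needs at least 2 subjects")
    adjusted = age_adjust(auc_values, ages)
    observed = float(adjusted[is_patient].mean() - adjusted[~is_patient].mean())
    rng = np.random.default_rng(seed)
    null = _null_group_diffs(adjusted, is_patient, n_perm, rng)
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return PermutationResult(metric=metric, observed_diff=observed,
                             null_diffs=null, p_value=float(p),
                             n_perm=n_perm, seed=seed)


def permutation_test_nodal(nodal_aucs, is_patient, ages, n_perm: int = 5000,
                           seed: int = 0, metric: str = "",
                           labels=None) -> pd.DataFrame:
    """Per-node permutation tests with BH-FDR adjustment across nodes.

    One joint label shuffle is applied to all nodes per permutation (subjects
    are permuted wholesale, preserving the spatial covariance of the null).
    Returns a data frame with observed differences, raw and adjusted p.
    """
    y = np.asarray(nodal_aucs, dtype=float)
    is_patient = np.asarray(is_patient, dtype=bool)
    if int(is_patient.sum()) < 2 or int((~is_patient).sum()) < 2:
        raise ValueError("each group needs at least 2 subjects")
    adjusted = age_adjust(y, ages)
    observed = adjusted[is_patient].mean(axis=0) - adjusted[~is_patient].mean(axis=0)
    rng = np.random.default_rng(seed)
    null = _null_group_diffs(adjusted, is_patient, n_perm, rng)  # (n_perm, k)
    exceed = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    p_raw = (1.0 + exceed) / (n_perm + 1.0)
    p_fdr = false_discovery_control(p_raw, method="bh")
    out = pd.DataFrame({
        "node_index": np.arange(y.shape[1]),
        "metric": metric,
        "observed_diff": observed,
        "p_value": p_raw,
        "p_fdr": p_fdr,
        "significant_fdr": p_fdr < 0.05,
    })
    if labels is not None:
        out.insert(1, "label", list(labels))
    return out


@dataclass
class HubSet:
    """Nodes whose betweenness AUC exceeds mean + z_threshold * population SD."""

    group: str
    hub_labels: list = field(default_factory=list)
    hub_indices: list = field(default_factory=list)
    z_threshold: float = 2.0


def identify_hubs(mean_betweenness_auc, labels=None, group: str = "",
                  z_threshold: float = 2.0) -> HubSet:
    values = np.asarray(mean_betweenness_auc, dtype=float)
    sd = values.std()  # population (n-denominator) SD
    if sd == 0:
        raise ValueError("zero SD across nodes: hub criterion undefined")
    mask = values > values.mean() + z_threshold * sd
    idx = np.flatnonzero(mask).tolist()
    if labels is None:
        labels = [str(i) for i in range(len(values))]
    return HubSet(group=group, hub_labels=[labels[i] for i in idx],
                  hub_indices=idx, z_threshold=z_threshold)


# ---------------------------------------------------------------------------
# cohort-level orchestration
# ---------------------------------------------------------------------------

def nodal_metric_curves(w, grid: DensityGrid, metric_set) -> dict[str, np.ndarray]:
    """Per-density nodal metric values: metric -> (n_densities, n_nodes)."""
    out = {m: [] for m in metric_set}
    for d in grid.densities:
        g = threshold_at_density(w, d)
        for m in metric_set:
            out[m].append(gm.NODAL_METRICS[m](g))
    return {m: np.array(v) for m, v in out.items()}


def _subject_rng(master_seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master_seed, spawn_key=(subject_index,)))


def subject_global_aucs(matrices: dict[str, ConnectivityMatrix], grid: DensityGrid,
                        metric_set, *, n_null: int = 20, swaps_per_edge: int = 10,
                        seed: int = 0) -> pd.DataFrame:
    """AUC of every global metric curve for every subject (rows = subjects).

    Null-network streams are derived per subject from (seed, subject index)
    so results are reproducible and independent of evaluation order.
    """
    rows = {}
    for idx, (sid, w) in enumerate(sorted(matrices.items())):
        rng = _subject_rng(seed, idx)
        curves = metric_curves(w, grid, metric_set, n_null=n_null,
                               swaps_per_edge=swaps_per_edge, rng=rng)
        rows[sid] = {m: auc(curves[m].to_numpy(), grid.densities)
                     for m in curves.columns}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df


def subject_nodal_aucs(matrices: dict[str, ConnectivityMatrix], grid: DensityGrid,
                       metric_set) -> dict[str, pd.DataFrame]:
    """Nodal AUC matrices: metric -> (subjects x nodes) data frame."""
    per_metric: dict[str, dict[str, np.ndarray]] = {m: {} for m in metric_set}
    for sid, w in sorted(matrices.items()):
        curves = nodal_metric_curves(w, grid, metric_set)
        for m, arr in curves.items():
            per_metric[m][sid] = np.trapezoid(arr, grid.densities, axis=0)
    return {m: pd.DataFrame.from_dict(v, orient="index")
            for m, v in per_metric.items()}


@dataclass
class CrossSectionalResult:
    global_tests: pd.DataFrame
    nodal_tests: pd.DataFrame
    hubs: pd.DataFrame
    global_aucs: pd.DataFrame
    null_distributions: pd.DataFrame
    excluded: list


def cross_sectional_analysis(matrices: dict[str, ConnectivityMatrix],
                             manifest: pd.DataFrame, config: RunConfig,
                             atlas: pd.DataFrame | None = None) -> CrossSectionalResult:
    """Full baseline comparison of patients versus controls at T1.

    Subjects missing a baseline matrix are excluded listwise and reported;
    subjects with an undefined (NaN) AUC for a metric are excluded from that
    metric's test with a logged warning.
    """
    if atlas is None:
        from .atlas import default_atlas
        atlas = default_atlas()
    grid = DensityGrid(config.d_min, config.d_max, config.d_step)
    have = {sid for sid in matrices}
    excluded = sorted(set(manifest["subject_id"]) - have)
    if excluded:
        log.warning("excluding %d subjects without a baseline matrix: %s",
                    len(excluded), excluded)
    kept = manifest[manifest["subject_id"].isin(have)].reset_index(drop=True)
    order = list(kept["subject_id"])
    mats = {sid: matrices[sid] for sid in order}

    g_aucs = subject_global_aucs(mats, grid, config.global_metrics,
                                 n_null=config.n_null,
                                 swaps_per_edge=config.swaps_per_edge,
                                 seed=config.seed)
    g_aucs = g_aucs.loc[order]
    is_patient = (kept["group"] == "patient").to_numpy()
    ages = kept["age"].to_numpy()

    rows = []
    null_rows = {}
    for m in g_aucs.columns:
        vals = g_aucs[m].to_numpy()
        ok = np.isfinite(vals)
        if not ok.all():
            log.warning("metric %s: excluding %d subjects with undefined AUC",
                        m, int((~ok).sum()))
        res = permutation_test_global(vals[ok], is_patient[ok], ages[ok],
                                      n_perm=config.n_perm, seed=config.seed,
                                      metric=m)
        rows.append({"metric": m, "observed_diff": res.observed_diff,
                     "p_auc": res.p_value, "n_perm": res.n_perm,
                     "n_patients": int(is_patient[ok].sum()),
                     "n_controls": int((~is_patient[ok]).sum())})
        null_rows[m] = res.null_diffs
    global_tests = pd.DataFrame(rows)
    null_distributions = pd.DataFrame(null_rows)

    n_aucs = subject_nodal_aucs(mats, grid, config.nodal_metrics)
    nodal_frames = []
    for m, df in n_aucs.items():
        df = df.loc[order]
        nodal_frames.append(permutation_test_nodal(
            df.to_numpy(), is_patient, ages, n_perm=config.n_perm,
            seed=config.seed, metric=m, labels=atlas["label"]))
    nodal_tests = pd.concat(nodal_frames, ignore_index=True)

    bc = n_aucs["betweenness"].loc[order]
    hub_rows = []
    for group, mask in (("control", ~is_patient), ("patient", is_patient)):
        hs = identify_hubs(bc.to_numpy()[mask].mean(axis=0), atlas["label"],
                           group=group)
        for i, lab in zip(hs.hub_indices, hs.hub_labels):
            hub_rows.append({"group": group, "node_index": i, "label": lab,
                             "z_threshold": hs.z_threshold})
    hubs = pd.DataFrame(hub_rows, columns=["group", "node_index", "label",
                                           "z_threshold"])
    return CrossSectionalResult(global_tests=global_tests, nodal_tests=nodal_tests,
                                hubs=hubs, global_aucs=g_aucs,
                                null_distributions=null_distributions,
                                excluded=excluded)
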