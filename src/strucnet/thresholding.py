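"""Density thresholding of weighted connectomes.

A weighted matrix is binarized at a network density d by keeping the
k = round(d * n(n-1)/2) strongest upper-triangle weights as edges.  Metrics
are computed across a density grid (default 0.10:0.01:0.20) and later
summarized by area under the curve, which avoids committing to any single
threshold.  Ties among equal weights are broken by ascending (row, column)
index so runs are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics as gm
from .io import ConnectivityMatrix

__all__ = [
    "BinaryGraph",
    "DensityGrid",
    "ThresholdError",
    "edge_count_at_density",
    "find_dmin",
    "metric_curves",
    "threshold_at_density",
]


class ThresholdError(ValueError):
    pass


@dataclass(frozen=True)
class DensityGrid:
    """Inclusive density range d_min:step:d_max; the default has 11 points."""

    d_min: float = 0.10
    d_max: float = 0.20
    step: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max <= 1):
            raise ValueError("require 0 < d_min < d_max <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if len(self.densities) < 2:
            raise ValueError("grid must contain at least 2 densities")

    @property
    def densities(self) -> np.ndarray:
        n_steps = int(round((self.d_max - self.d_min) / self.step))
        d = self.d_min + self.step * np.arange(n_steps + 1)
        return d[d <= self.d_max + 1e-12]


@dataclass
class BinaryGraph:
    """Symmetric 0/1 adjacency with zero diagonal and its realized density."""

    adjacency: np.ndarray
    density: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def edge_count_at_density(n: int, d: float) -> int:
    """k = round(d * n(n-1)/2), rounding half up."""
    return int(np.floor(d * n * (n - 1) / 2.0 + 0.5))


def threshold_at_density(w, d: float) -> BinaryGraph:
    """Binarize by keeping the k strongest upper-triangle weights as edges.

    Ties among equal weights are resolved by ascending (row, column) index,
    making the retained edge set deterministic.
    """
    weights = w.weights if isinstance(w, ConnectivityMatrix) else np.asarray(w, dtype=float)
    n = weights.shape[0]
    if not (0 < d <= 1):
        raise ThresholdError(f"density must be in (0, 1], got {d}")
    k = edge_count_at_density(n, d)
    iu, ju = np.triu_indices(n, 1)
    vals = weights[iu, ju]
    n_nonzero = int(np.count_nonzero(vals))
    if k > n_nonzero:
        raise ThresholdError(
            f"density {d} needs {k} edges but only {n_nonzero} nonzero weights exist"
        )
    # lexsort: primary descending weight, then ascending (row, col)
    order = np.lexsort((ju, iu, -vals))[:k]
    adj = np.zeros((n, n))
    adj[iu[order], ju[order]] = 1.0
    adj += adj.T
    return BinaryGraph(adjacency=adj, density=d)


def find_dmin(matrices, grid: DensityGrid) -> float:
    """Smallest grid density at which every subject's thresholded graph is
    connected (a single component spanning all nodes).

    Because thresholded edge sets are nested in density, this equals the max
    over subjects of each subject's own first connected density.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("empty matrix list")
    for d in grid.densities:
        try:
            ok = all(gm.is_connected(threshold_at_density(m, d)) for m in matrices)
        except ThresholdError:
            ok = False
        if ok:
            return float(d)
    raise ThresholdError("no grid density yields connected graphs for every subject")


def metric_curves(w, grid: DensityGrid, metric_set=None, *, n_null: int = 20,
                  swaps_per_edge: int = 10, rng=None) -> pd.DataFrame:
    """Threshold a subject at every grid density and evaluate global metrics.

    ``metric_set`` may contain names from :data:`strucnet.metrics.GLOBAL_METRICS`
    plus the null-normalized measures ``gamma`` (C/C_rand), ``lambda``
    (L/L_rand) and ``sigma`` (gamma/lambda); those require ``rng`` and use
    ``n_null`` degree-preserving random networks per density.  Callables are
    also accepted and applied per thresholded graph.  Returns a data frame
    indexed by density, one column per metric.
    """
    from .nulls import normalized_metrics

    if metric_set is None:
        metric_set = list(gm.GLOBAL_METRICS)
    names = [m if isinstance(m, str) else m.__name__ for m in metric_set]
    normalized_wanted = [m for m in metric_set
                         if isinstance(m, str) and m in ("gamma", "lambda", "sigma")]
    rows = {}
    for d in grid.densities:
        g = threshold_at_density(w, d)
        if not gm.is_connected(g):
            raise gm.DisconnectedGraphError(
                f"graph fragmented at density {d:.2f}; analysis requires connectivity "
                "at every grid density"
            )
        row = {}
        if normalized_wanted:
            if rng is None:
                raise ValueError("normalized metrics (gamma/lambda/sigma) require rng")
            nm = normalized_metrics(g, n_null=n_null, rng=rng,
                                    swaps_per_edge=swaps_per_edge)
            row.update({"gamma": nm.gamma, "lambda": nm.lam, "sigma": nm.sigma})
        for m in metric_set:
            if isinstance(m, str):
                if m in ("gamma", "lambda", "sigma"):
                    continue
                row[m] = gm.GLOBAL_METRICS[m](g)
            else:
                row[m.__name__] = m(g)
        rows[float(d)] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "density"
    return df[names]
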