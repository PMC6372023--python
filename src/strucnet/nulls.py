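"""Degree-preserving null networks and small-world normalization.

Observed metrics are compared against degree-matched Maslov–Sneppen
rewirings: gamma = C/C_rand, lambda = L/L_rand, sigma = gamma/lambda, with
null means taken over n_null (default 20) independent connected rewirings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import metrics as gm
from .thresholding import BinaryGraph

__all__ = ["NormalizedMetrics", "RewireError", "normalized_metrics",
           "rewire_preserving_degree"]

_MAX_CONNECT_RETRIES = 50


class RewireError(RuntimeError):
    """Could not produce a connected degree-preserving rewiring."""


@njit(cache=True)
def _swap_loop(adj, edges, n_accept, max_trials, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    m = edges.shape[0]
    accepted = 0
    trials = 0
    while accepted < n_accept and trials < max_trials:
        trials += 1
        e1 = np.random.randint(m)
        e2 = np.random.randint(m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        # proposed swap: (a,b),(c,d) -> (a,d),(c,b)
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] == 1 or adj[c, b] == 1:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        accepted += 1
    return accepted


def _rewire_once(adjacency: np.ndarray, n_accept: int, seed: int) -> np.ndarray:
    adj = adjacency.astype(np.uint8).copy()
    ii, jj = np.nonzero(np.triu(adj, 1))
    edges = np.column_stack([ii, jj]).astype(np.int64)
    if n_accept > 0 and len(edges) >= 2:
        _swap_loop(adj, edges, n_accept, max_trials=max(100 * n_accept, 1000),
                   seed=seed)
    return adj.astype(float)


def rewire_preserving_degree(g, n_swaps_per_edge: int = 10, rng=None,
                             require_connected: bool = True) -> BinaryGraph:
    """Maslov–Sneppen double-edge-swap rewiring.

    Performs ``n_swaps_per_edge`` ACCEPTED swaps per edge (swaps creating
    self-loops or multi-edges are rejected and retried).  The degree sequence
    is preserved exactly.  When ``require_connected`` the whole rewiring is
    resampled (bounded retries) until the result is a single component.
    """
    if rng is None:
        rng = np.random.default_rng()
    adjacency = np.asarray(getattr(g, "adjacency", g), dtype=float)
    m = int(adjacency.sum()) // 2
    n_accept = n_swaps_per_edge * m
    for _ in range(_MAX_CONNECT_RETRIES):
        seed = int(rng.integers(2 ** 31 - 1))
        adj = _rewire_once(adjacency, n_accept, seed)
        if not require_connected or gm.is_connected(adj):
            density = m / (adjacency.shape[0] * (adjacency.shape[0] - 1) / 2.0)
            return BinaryGraph(adjacency=adj, density=density)
    raise RewireError(
        f"no connected rewiring found in {_MAX_CONNECT_RETRIES} attempts"
    )


@dataclass(frozen=True)
class NormalizedMetrics:
    """Small-world measures normalized by degree-preserving null averages."""

    gamma: float  #: C / C_rand
    lam: float    #: L / L_rand
    sigma: float  #: gamma / lambda
    n_null: int


def normalized_metrics(g, n_null: int = 20, rng=None,
                       swaps_per_edge: int = 10) -> NormalizedMetrics:
    """Compute gamma, lambda and sigma against ``n_null`` rewired networks.

    Null means are arithmetic means of clustering and characteristic path
    length over the (connected) rewirings.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    c_obs = gm.clustering(g)[1]
    l_obs = gm.char_path_length(g)
    c_rand = np.empty(n_null)
    l_rand = np.empty(n_null)
    for i in range(n_null):
        null = rewire_preserving_degree(g, n_swaps_per_edge=swaps_per_edge, rng=rng)
        c_rand[i] = gm.clustering(null)[1]
        l_rand[i] = gm.char_path_length(null)
    gamma = c_obs / c_rand.mean()
    lam = l_obs / l_rand.mean()
    return NormalizedMetrics(gamma=float(gamma), lam=float(lam),
                             sigma=float(gamma / lam), n_null=n_null)
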