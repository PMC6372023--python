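"""Binary-undirected graph metrics.

Global measures: mean clustering coefficient, characteristic path length,
global and local efficiency, optimized Newman modularity Q, degree
assortativity and mean node betweenness.  Nodal measures: degree, local
efficiency, clustering and betweenness centrality.  Conventions follow the
standard binary-undirected definitions used throughout structural
connectomics (Watts–Strogatz clustering, Latora–Marchiori efficiencies,
Brandes betweenness with endpoints excluded and no normalization, Newman
degree–degree assortativity and modularity).

All functions accept a :class:`~strucnet.thresholding.BinaryGraph` or a
plain square 0/1 adjacency array.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "DisconnectedGraphError",
    "assortativity",
    "betweenness",
    "char_path_length",
    "clustering",
    "degree",
    "global_efficiency",
    "is_connected",
    "local_efficiency",
    "mean_betweenness",
    "modularity",
    "modularity_q",
    "partition_quality",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]


class DisconnectedGraphError(ValueError):
    """Raised when a metric requiring a connected graph receives a fragmented one."""


def _adjacency(g) -> np.ndarray:
    a = getattr(g, "adjacency", g)
    a = np.asarray(a)
    return a.astype(float, copy=False)


def is_connected(g) -> bool:
    a = _adjacency(g)
    if a.shape[0] == 0:
        return True
    n_comp, _ = connected_components(csr_matrix(a), directed=False)
    return n_comp == 1


def degree(g) -> np.ndarray:
    """Per-node degree (row sums of the adjacency matrix) as integers."""
    a = _adjacency(g)
    return a.sum(axis=1).astype(int)


def clustering(g) -> tuple[np.ndarray, float]:
    """Watts–Strogatz clustering: C_i = 2 t_i / (k_i (k_i - 1)), 0 when k_i < 2.

    Returns (per-node values, mean over all nodes).
    """
    a = _adjacency(g)
    k = a.sum(axis=1)
    tri = np.diagonal(a @ a @ a) / 2.0  # triangles through each node
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * tri / denom, 0.0)
    return c, float(c.mean()) if c.size else 0.0

def _distances(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def char_path_length(g) -> float:
    """Mean shortest-path length over all ordered node pairs; errors if fragmented."""
    a = _adjacency(g)
    n = a.shape[0]
    if n < 2:
        raise DisconnectedGraphError("path length undefined for graphs with < 2 nodes")
    d = _distances(a)
    off = ~np.eye(n, dtype=bool)
    if np.isinf(d[off]).any():
        raise DisconnectedGraphError("characteristic path length undefined on a fragmented graph")
    return float(d[off].mean())


def global_efficiency(g) -> float:
    """Mean over ordered pairs of 1/d_ij, with 1/inf = 0 (finite on fragmented graphs)."""
    a = _adjacency(g)
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = _distances(a)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(g) -> tuple[np.ndarray, float]:
    """E_loc(i) = global efficiency of the subgraph induced by the neighbors of i.

    Zero for nodes with fewer than two neighbors.  Returns (per-node, mean).
    """
    a = _adjacency(g)
    n = a.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        vals[i] = global_efficiency(a[np.ix_(nb, nb)])
    return vals, float(vals.mean()) if n else 0.0


def betweenness(g) -> np.ndarray:
    """Unnormalized shortest-path betweenness with fractional sharing across geodesics."""
    import igraph as ig

    a = _adjacency(g)
    n = a.shape[0]
    ii, jj = np.nonzero(np.triu(a, 1))
    graph = ig.Graph(n, list(zip(ii.tolist(), jj.tolist())))
    return np.asarray(graph.betweenness(), dtype=float)


def mean_betweenness(g) -> float:
    """Network-average nodal betweenness centrality."""
    return float(betweenness(g).mean())


def assortativity(g) -> float:
    """Degree assortativity r: Pearson correlation of end-point degrees over
    the doubly-oriented edge list.  Returns NaN when undefined (zero degree
    variance at edge end points, e.g. regular graphs)."""
    a = _adjacency(g)
    k = a.sum(axis=1)
    ii, jj = np.nonzero(np.triu(a, 1))
    if ii.size < 2:
        return float("nan")
    x = np.concatenate([k[ii], k[jj]])
    y = np.concatenate([k[jj], k[ii]])
    vx = x - x.mean()
    vy = y - y.mean()
    denom = np.sqrt((vx ** 2).sum() * (vy ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((vx * vy).sum() / denom)


# ---------------------------------------------------------------------------
# modularity: deterministic leading-eigenvector bipartitioning with
# Kernighan–Lin-style single-node fine-tuning
# ---------------------------------------------------------------------------

_EPS = 1e-12


def partition_quality(g, labels: np.ndarray) -> float:
    """Newman modularity Q of an explicit partition:
    Q = sum_c [ e_cc / m - (sum_{i in c} k_i / 2m)^2 ]."""
    a = _adjacency(g)
    labels = np.asarray(labels)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        e_cc = a[np.ix_(idx, idx)].sum() / 2.0
        q += e_cc / (two_m / 2.0) - (k[idx].sum() / two_m) ** 2
    return float(q)


def _kl_refine(bh: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Fine-tune a sign vector by greedy single-node moves (each node moved at
    most once per pass, best intermediate state kept); repeat passes while
    they improve.  Ties broken by lowest node index."""
    n = s.size
    s = s.copy()
    diag = np.diagonal(bh)
    while True:
        s_work = s.copy()
        bs = bh @ s_work
        moved = np.zeros(n, dtype=bool)
        cum = 0.0
        best_cum = 0.0
        best_state = s.copy()
        for _ in range(n):
            gains = -4.0 * s_work * bs + 4.0 * diag
            gains[moved] = -np.inf
            i = int(np.argmax(gains))
            cum += gains[i]
            bs -= 2.0 * s_work[i] * bh[:, i]
            s_work[i] = -s_work[i]
            moved[i] = True
            if cum > best_cum + _EPS:
                best_cum = cum
                best_state = s_work.copy()
        if best_cum > _EPS:
            s = best_state
        else:
            return s


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber communities 0..c-1 in order of their smallest node."""
    out = np.empty_like(labels)
    seen: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


def _greedy_refine_partition(a: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Polish a partition with Kernighan-Lin passes over single-node moves
    to any community (or a new singleton).

    Within a pass each node is moved at most once; the best-gain move is
    applied even when negative (so coordinated relocations of several nodes
    are reachable) and the best intermediate partition of the pass is kept.
    Passes repeat while they improve Q.  Deterministic: numpy argmax
    tie-breaks by lowest flat index.
    """
    n = a.shape[0]
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0 or n < 2:
        return _relabel(labels)
    m = two_m / 2.0
    labels = _relabel(labels)
    while True:
        work = labels.copy()
        n_comm = int(work.max()) + 1
        # columns 0..n_comm-1: existing communities; column n_comm: fresh one
        onehot = np.zeros((n, n_comm + 1))
        onehot[np.arange(n), work] = 1.0
        e = a @ onehot                    # e[i, c]: edges from i into c
        kc = k @ onehot                   # community degree totals
        moved = np.zeros(n, dtype=bool)
        cum = 0.0
        best_cum = 0.0
        best_state = labels.copy()
        for _ in range(n):
            cur = e[np.arange(n), work]
            kc_cur = kc[work]
            remove = -cur / m + k * (kc_cur - k) / (2.0 * m * m)
            gains = remove[:, None] + e / m - np.outer(k, kc) / (2.0 * m * m)
            gains[np.arange(n), work] = -np.inf
            gains[moved, :] = -np.inf
            i, c = np.unravel_index(np.argmax(gains), gains.shape)
            if not np.isfinite(gains[i, c]):
                break
            cum += gains[i, c]
            old = work[i]
            work[i] = c
            moved[i] = True
            kc[old] -= k[i]
            kc[c] += k[i]
            e[:, old] -= a[:, i]
            e[:, c] += a[:, i]
            if c == n_comm and kc[n_comm] > 0:
                # the fresh community is now occupied; open another column
                onehot = np.pad(onehot, ((0, 0), (0, 1)))
                e = np.pad(e, ((0, 0), (0, 1)))
                kc = np.pad(kc, (0, 1))
                n_comm += 1
            if cum > best_cum + _EPS:
                best_cum = cum
                best_state = work.copy()
        if best_cum > _EPS:
            labels = _relabel(best_state)
        else:
            return labels


def modularity(g, seed: int | None = None) -> tuple[np.ndarray, float]:
    """Maximize Newman modularity by recursive leading-eigenvector
    bipartitioning with Kernighan–Lin fine-tuning.

    The algorithm is fully deterministic (dense symmetric eigensolver,
    lowest-index tie-breaks); ``seed`` is accepted for interface symmetry
    with stochastic optimizers and ignored.  Returns (community labels
    0..c-1 in order of first node occurrence, Q of that partition).
    """
    a = _adjacency(g)
    n = a.shape[0]
    k = a.sum(axis=1)
    two_m = k.sum()
    if n == 0 or two_m == 0:
        return np.zeros(n, dtype=int), 0.0
    b = a - np.outer(k, k) / two_m
    final: list[np.ndarray] = []
    stack: list[np.ndarray] = [np.arange(n)]
    while stack:
        grp = stack.pop()
        if grp.size < 2:
            final.append(grp)
            continue
        bg = b[np.ix_(grp, grp)]
        bh = bg - np.diag(bg.sum(axis=1))
        eigvals, eigvecs = np.linalg.eigh(bh)
        if eigvals[-1] <= _EPS:
            final.append(grp)
            continue
        # multi-start: KL-refine sign splits seeded by each of the leading
        # eigenvectors with positive eigenvalue (up to 3); keep the best dQ.
        # Deterministic: fixed candidate order, first-best wins ties.
        n_cand = min(3, int(np.sum(eigvals > _EPS)))
        best_s, best_dq = None, 0.0
        for c in range(1, n_cand + 1):
            s = np.where(eigvecs[:, -c] >= 0, 1.0, -1.0)
            s = _kl_refine(bh, s)
            dq = s @ bh @ s / (2.0 * two_m)  # / (4m) with two_m = 2m
            if dq > best_dq + _EPS and not (np.all(s > 0) or np.all(s < 0)):
                best_s, best_dq = s, dq
        if best_s is None:
            final.append(grp)
            continue
        s = best_s
        stack.append(grp[s < 0])
        stack.append(grp[s > 0])
    labels = np.empty(n, dtype=int)
    for c, grp in enumerate(sorted(final, key=lambda x: x.min())):
        labels[grp] = c
    # final polish: greedy node moves / merges over the whole partition
    labels = _greedy_refine_partition(a, labels)
    return labels, partition_quality(a, labels)


def modularity_q(g, seed: int | None = None) -> float:
    return modularity(g, seed)[1]


#: global metric registry: name -> callable(BinaryGraph) -> float.
#: gamma / lambda / sigma are null-normalized and live in strucnet.nulls.
GLOBAL_METRICS = {
    "clustering_coefficient": lambda g: clustering(g)[1],
    "char_path_length": char_path_length,
    "global_efficiency": global_efficiency,
    "local_efficiency": lambda g: local_efficiency(g)[1],
    "modularity_q": modularity_q,
    "assortativity_r": assortativity,
    "mean_betweenness": mean_betweenness,
}

#: nodal metric registry: name -> callable(BinaryGraph) -> length-n vector
NODAL_METRICS = {
    "degree": lambda g: degree(g).astype(float),
    "local_efficiency": lambda g: local_efficiency(g)[0],
    "clustering": lambda g: clustering(g)[0],
    "betweenness": betweenness,
}
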