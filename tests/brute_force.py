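"""Independent brute-force graph-metric implementations used as test oracles.

Everything here is written for clarity at tiny n, deliberately avoiding the
package's own code paths and the libraries it delegates to: explicit
triangle enumeration, hand Floyd-Warshall distances, explicit shortest-path
enumeration for betweenness, the naive covariance formula for assortativity
and exhaustive set-partition search for modularity.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

INF = math.inf


def distances_floyd_warshall(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    d = [[0 if i == j else (1 if a[i][j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return np.array(d)


def clustering_by_triangles(a: np.ndarray) -> tuple[np.ndarray, float]:
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if a[i][j]]
        k = len(nb)
        if k < 2:
            continue
        t = sum(1 for x, y in itertools.combinations(nb, 2) if a[x][y])
        c[i] = 2.0 * t / (k * (k - 1))
    return c, float(c.mean())


def char_path_length(a: np.ndarray) -> float:
    d = distances_floyd_warshall(a)
    n = a.shape[0]
    vals = [d[i][j] for i in range(n) for j in range(n) if i != j]
    assert all(v < INF for v in vals), "disconnected"
    return float(np.mean(vals))


def global_efficiency(a: np.ndarray) -> float:
    d = distances_floyd_warshall(a)
    n = a.shape[0]
    if n < 2:
        return 0.0
    vals = [0.0 if d[i][j] == INF else 1.0 / d[i][j]
            for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def local_efficiency(a: np.ndarray) -> tuple[np.ndarray, float]:
    n = a.shape[0]
    vals = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if a[i][j]]
        if len(nb) < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        vals[i] = global_efficiency(sub)
    return vals, float(vals.mean())


def _all_shortest_paths(a: np.ndarray, s: int, t: int) -> list[list[int]]:
    """All geodesics from s to t by exhaustive simple-path enumeration."""
    n = a.shape[0]
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for j in range(n):
            if a[last][j] and j not in path:
                path.append(j)
                extend(path)
                path.pop()

    extend([s])
    if not paths:
        return []
    shortest = min(len(p) for p in paths)
    return [p for p in paths if len(p) == shortest]


def betweenness(a: np.ndarray) -> np.ndarray:
    """Fractional geodesic counts through each node, endpoints excluded,
    unnormalized (each unordered pair counted once)."""
    n = a.shape[0]
    b = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        geodesics = _all_shortest_paths(a, s, t)
        if not geodesics:
            continue
        for p in geodesics:
            for v in p[1:-1]:
                b[v] += 1.0 / len(geodesics)
    return b


def assortativity_covariance(a: np.ndarray) -> float:
    """Naive covariance-formula degree assortativity over the doubly-oriented
    edge list; NaN when the variance vanishes."""
    n = a.shape[0]
    k = a.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(n):
            if i != j and a[i][j]:
                xs.append(k[i])
                ys.append(k[j])
    if len(xs) < 2:
        return float("nan")
    x, y = np.array(xs, dtype=float), np.array(ys, dtype=float)
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    den = x.std() * y.std()
    return float("nan") if den == 0 else float(cov / den)


def modularity_of_partition(a: np.ndarray, labels) -> float:
    labels = np.asarray(labels)
    m = a.sum() / 2.0
    if m == 0:
        return 0.0
    q = 0.0
    for c in set(labels.tolist()):
        idx = np.flatnonzero(labels == c)
        e_cc = a[np.ix_(idx, idx)].sum() / 2.0
        deg_c = a[idx].sum()
        q += e_cc / m - (deg_c / (2 * m)) ** 2
    return float(q)


def set_partitions(n: int):
    """All set partitions of range(n) as canonical label tuples."""

    def rec(i, labels, k):
        if i == n:
            yield tuple(labels)
            return
        for c in range(k):
            labels[i] = c
            yield from rec(i + 1, labels, k)
        labels[i] = k
        yield from rec(i + 1, labels, k + 1)
        labels[i] = 0

    yield from rec(0, [0] * n, 0)


def exhaustive_max_modularity(a: np.ndarray) -> float:
    return max(modularity_of_partition(a, lab) for lab in set_partitions(a.shape[0]))


def mixed_anova_sums_of_squares(groups: dict) -> dict:
    """Balanced mixed-design ANOVA by direct cell-mean decomposition.

    ``groups`` maps arm label -> (n_subjects, n_times) array.  Returns
    F statistics and dfs for the between factor, time, and the interaction.
    Valid for equal n per arm.
    """
    arms = sorted(groups)
    a = len(arms)
    n = {g: groups[g].shape[0] for g in arms}
    t = groups[arms[0]].shape[1]
    all_vals = np.concatenate([groups[g].ravel() for g in arms])
    grand = all_vals.mean()
    n_tot = sum(n.values())

    ss_between = sum(t * n[g] * (groups[g].mean() - grand) ** 2 for g in arms)
    ss_subj_within = sum(t * ((groups[g].mean(axis=1) - groups[g].mean()) ** 2).sum()
                         for g in arms)
    time_mean = {j: np.mean([groups[g][:, j].mean() for g in arms]) for j in range(t)}
    ss_time = sum(n_tot * (time_mean[j] - grand) ** 2 for j in range(t))
    ss_cells = sum(n[g] * ((groups[g][:, j].mean()
                            - groups[g].mean() - time_mean[j] + grand) ** 2)
                   for g in arms for j in range(t))
    ss_err_within = sum(((groups[g]
                          - groups[g].mean(axis=1, keepdims=True)
                          - groups[g].mean(axis=0, keepdims=True)
                          + groups[g].mean()) ** 2).sum() for g in arms)

    df_b, df_sw = a - 1, n_tot - a
    df_t, df_i, df_e = t - 1, (a - 1) * (t - 1), (t - 1) * (n_tot - a)

    def f(ss_eff, df_eff, ss_err, df_err):
        if ss_eff == 0:
            return 0.0
        return (ss_eff / df_eff) / (ss_err / df_err)

    return {
        "order": (f(ss_between, df_b, ss_subj_within, df_sw), df_b, df_sw),
        "time": (f(ss_time, df_t, ss_err_within, df_e), df_t, df_e),
        "order*time": (f(ss_cells, df_i, ss_err_within, df_e), df_i, df_e),
    }
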