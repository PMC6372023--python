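"""Synthetic cohort generator.

Emulates the statistical structure of a two-group structural-connectome
study: 60 controls and 46 treatment-resistant-depression patients, 89-node
weighted networks with planted modular structure and a minority of
high-degree hub nodes, heavy-tailed (log-normal) edge weights standing in
for tractography streamline densities, patient-specific topological
deficits (lower degree assortativity, shorter path length), a crossover
two-arm longitudinal design in which only the active-first arm shows a
modularity reduction from baseline to the first follow-up, and declining
Hamilton depression (HDRS) trajectories identical across arms.

Everything is driven by one seed through per-subject spawned random
streams, so a cohort is byte-identical given the same configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as gm
from .io import ConnectivityMatrix, write_manifest, write_matrix
from .thresholding import edge_count_at_density, threshold_at_density

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "apply_patient_effects",
    "generate_base_network",
    "generate_clinical_scores",
    "generate_cohort",
    "generate_longitudinal_series",
    "planted_modules",
    "planted_hubs",
    "write_cohort",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters of the synthetic cohort.

    Default cohort sizes and HDRS trajectory match the emulated study design
    (60 controls, 46 patients, HDRS means 21.76 -> 17.79 -> 14.56); network
    and effect parameters are chosen so the planted deficits are clear at
    cohort scale (see docs/methods.md).
    """

    n_controls: int = 60
    n_patients: int = 46
    n_nodes: int = 89
    module_count: int = 4
    within_module_p: float = 0.60
    between_module_p: float = 0.06
    hub_count: int = 8
    hub_boost: float = 3.0
    weight_scale: float = 1.0
    weight_sigma: float = 0.6
    #: fraction of hub-hub edges swapped toward hub-leaf pairs in patients
    effect_assortativity: float = 0.8
    #: number of long-range between-module shortcut edges added in patients
    effect_integration: int = 30
    #: increment to the between-module edge probability applied by the
    #: stimulation-linked perturbation (within-module edges are relocated)
    effect_modularity_drop: float = 0.03
    noise_sigma: float = 0.05
    hdrs_means: tuple[float, float, float] = (21.76, 17.79, 14.56)
    hdrs_sd: float = 6.26
    age_mean: float = 40.0
    age_sd: float = 12.0
    age_range: tuple[float, float] = (18.0, 65.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_module_p", "between_module_p"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_controls", "n_patients", "n_nodes", "module_count", "hub_count"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.effect_assortativity <= 1):
            raise ValueError("effect_assortativity must be in [0, 1]")
        if self.effect_integration < 0 or self.effect_modularity_drop < 0:
            raise ValueError("effect sizes must be nonnegative")
        if self.hdrs_sd < 0 or self.noise_sigma < 0:
            raise ValueError("standard deviations must be nonnegative")


def planted_modules(config: SimulationConfig) -> np.ndarray:
    """Deterministic contiguous near-equal module assignment (labels 0..m-1)."""
    return (np.arange(config.n_nodes) * config.module_count) // config.n_nodes


def planted_hubs(config: SimulationConfig) -> np.ndarray:
    """Hub node indices, spread evenly across the node range (and thus modules)."""
    return np.unique(
        np.linspace(0, config.n_nodes - 1, config.hub_count).round().astype(int)
    )


def _edge_probabilities(config: SimulationConfig) -> np.ndarray:
    labels = planted_modules(config)
    same = labels[:, None] == labels[None, :]
    p = np.where(same, config.within_module_p, config.between_module_p)
    hubs = planted_hubs(config)
    is_hub = np.zeros(config.n_nodes, dtype=bool)
    is_hub[hubs] = True
    boost = np.ones_like(p)
    boost[is_hub, :] *= config.hub_boost
    boost[:, is_hub] *= config.hub_boost
    p = np.minimum(p * boost, 1.0)
    np.fill_diagonal(p, 0.0)
    return p


def generate_base_network(config: SimulationConfig, rng: np.random.Generator,
                          subject_id: str = "sim", timepoint: str = "T1",
                          max_retries: int = 20) -> ConnectivityMatrix:
    """Sample a control-like weighted network with planted modules and hubs.

    Edges follow a stochastic-block pattern with multiplicatively boosted
    probabilities on hub rows; present edges carry log-normal weights.
    Resamples (bounded retries) until the network supports the full density
    grid and its 0.10-density thresholding is a single connected component.
    """
    n = config.n_nodes
    p = _edge_probabilities(config)
    iu, ju = np.triu_indices(n, 1)
    k_needed = edge_count_at_density(n, 0.20)
    for _ in range(max_retries):
        present = rng.random(iu.size) < p[iu, ju]
        if present.sum() < k_needed:
            continue
        w = np.zeros((n, n))
        vals = np.zeros(iu.size)
        vals[present] = rng.lognormal(mean=np.log(config.weight_scale),
                                      sigma=config.weight_sigma,
                                      size=int(present.sum()))
        w[iu, ju] = vals
        w += w.T
        if gm.is_connected(threshold_at_density(w, 0.10)):
            return ConnectivityMatrix(subject_id=subject_id, timepoint=timepoint,
                                      weights=w)
    raise SimulationError(
        f"could not generate a network connected at density 0.10 in {max_retries} tries"
    )


def _support_edges(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.nonzero(np.triu(w, 1) > 0)


def apply_patient_effects(cm: ConnectivityMatrix, config: SimulationConfig,
                          rng: np.random.Generator) -> ConnectivityMatrix:
    """Plant the patient-group deficits into a control-like baseline network.

    Two degree-respecting manipulations: (1) a fraction of hub-hub edges is
    swapped against leaf-leaf edges into hub-leaf pairs (degree-sequence
    preserving; lowers assortativity); (2) ``effect_integration`` between-
    module shortcut edges with strong weights are added and the total weight
    mass rescaled back to the original sum (shortens path length).  With both
    effect sizes zero the input is returned unchanged.
    """
    if config.effect_assortativity == 0 and config.effect_integration == 0:
        return ConnectivityMatrix(cm.subject_id, cm.timepoint, cm.weights.copy())
    # resample the random manipulations until the result still supports the
    # sparsest analysis density (bounded retries)
    for _ in range(20):
        out = _apply_patient_effects_once(cm, config, rng)
        if gm.is_connected(threshold_at_density(out.weights, 0.10)):
            return out
    raise SimulationError("patient effects fragment the network at density 0.10")


def _apply_patient_effects_once(cm: ConnectivityMatrix, config: SimulationConfig,
                                rng: np.random.Generator) -> ConnectivityMatrix:
    w = cm.weights.copy()
    total_before = w.sum()
    adj = w > 0
    deg = adj.sum(axis=1)
    order = np.lexsort((np.arange(len(deg)), -deg))
    # "hub side" of the rewiring: top-quartile degree nodes (contains the
    # planted hubs); "leaf side": bottom half of the degree distribution
    n_hub_side = max(config.hub_count, len(deg) // 4)
    hub_set = set(order[:n_hub_side].tolist())
    leaf_set = set(order[len(deg) // 2:].tolist())

    ii, jj = _support_edges(w)
    hub_edges = [(a, b) for a, b in zip(ii, jj) if a in hub_set and b in hub_set]
    leaf_edges = [(a, b) for a, b in zip(ii, jj) if a in leaf_set and b in leaf_set]
    n_swap = int(round(config.effect_assortativity * len(hub_edges)))
    if config.effect_assortativity > 0 and (not hub_edges or not leaf_edges):
        raise SimulationError("assortativity effect infeasible: no eligible edge pairs")
    swapped = 0
    attempts = 0
    hub_pool = [tuple(e) for e in rng.permuted(np.array(hub_edges)) ] if hub_edges else []
    while swapped < n_swap and hub_pool and attempts < 50 * max(n_swap, 1):
        attempts += 1
        a, b = hub_pool[-1]
        c, d = leaf_edges[int(rng.integers(len(leaf_edges)))]
        # (a,b),(c,d) -> (a,c),(b,d): two hub-leaf edges, degrees preserved
        if len({a, b, c, d}) < 4 or w[a, c] > 0 or w[b, d] > 0:
            continue
        hub_pool.pop()
        w_ab, w_cd = w[a, b], w[c, d]
        for (x, y) in ((a, b), (c, d)):
            w[x, y] = w[y, x] = 0.0
        w[a, c] = w[c, a] = w_ab
        w[b, d] = w[d, b] = w_cd
        leaf_edges.remove((c, d) if c < d else (c, d))
        swapped += 1

    if config.effect_integration > 0:
        labels = planted_modules(config)
        strong = float(np.quantile(w[w > 0], 0.8))
        added = 0
        attempts = 0
        while added < config.effect_integration and attempts < 200 * config.effect_integration:
            attempts += 1
            a, b = rng.integers(config.n_nodes, size=2)
            if a == b or labels[a] == labels[b] or w[a, b] > 0:
                continue
            w[a, b] = w[b, a] = strong * float(rng.uniform(0.9, 1.1))
            added += 1
        if added < config.effect_integration:
            raise SimulationError("integration effect infeasible: not enough absent "
                                  "between-module pairs")
    # conserve total weight mass exactly (rank-preserving global rescale)
    w *= total_before / w.sum()
    return ConnectivityMatrix(cm.subject_id, cm.timepoint, w)


def _modularity_perturbation(w: np.ndarray, config: SimulationConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """Relocate within-module edges to between-module pairs, emulating an
    increment of the between-module edge probability."""
    labels = planted_modules(config)
    same = labels[:, None] == labels[None, :]
    n_between_pairs = int((~same[np.triu_indices_from(same, 1)]).sum())
    n_move = int(round(config.effect_modularity_drop * n_between_pairs))
    if n_move == 0:
        return w.copy()
    w = w.copy()
    ii, jj = _support_edges(w)
    within = [(a, b) for a, b in zip(ii, jj) if same[a, b]]
    n_move = min(n_move, len(within))
    chosen = rng.permutation(len(within))[:n_move]
    for idx in chosen:
        a, b = within[idx]
        weight = w[a, b]
        w[a, b] = w[b, a] = 0.0
        for _ in range(1000):
            x, y = rng.integers(config.n_nodes, size=2)
            if x != y and labels[x] != labels[y] and w[x, y] == 0:
                w[x, y] = w[y, x] = weight
                break
        else:  # pragma: no cover - pathological saturation
            w[a, b] = w[b, a] = weight
    return w


def _edge_noise(w: np.ndarray, config: SimulationConfig,
                rng: np.random.Generator) -> np.ndarray:
    """Independent multiplicative log-normal noise on present edges."""
    if config.noise_sigma == 0:
        return w.copy()
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    factors = np.exp(rng.normal(0.0, config.noise_sigma, size=iu.size))
    out = np.zeros_like(w)
    out[iu, ju] = w[iu, ju] * factors
    out += out.T
    return out


def generate_longitudinal_series(cm_t1: ConnectivityMatrix, order: str,
                                 config: SimulationConfig,
                                 rng: np.random.Generator
                                 ) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Produce T2 and T3 networks for one patient.

    The active-first arm (order1) receives the modularity-reducing
    perturbation at T2 and retains it at T3; the sham-first arm (order0)
    receives measurement noise only at T2 and the perturbation at T3.
    Independent multiplicative edge noise is applied at every timepoint.
    """
    if order not in ("order0", "order1"):
        raise ValueError(f"unknown order arm {order!r}")
    w1 = cm_t1.weights

    def _connected_variant(build) -> np.ndarray:
        for _ in range(20):
            w = build()
            if gm.is_connected(threshold_at_density(w, 0.10)):
                return w
        raise SimulationError("follow-up network fragments at density 0.10")

    if order == "order1":
        perturbed = _connected_variant(
            lambda: _modularity_perturbation(w1, config, rng))
        w2 = _connected_variant(lambda: _edge_noise(perturbed, config, rng))
        w3 = _connected_variant(lambda: _edge_noise(perturbed, config, rng))
    else:
        w2 = _connected_variant(lambda: _edge_noise(w1, config, rng))
        perturbed = _connected_variant(
            lambda: _modularity_perturbation(w1, config, rng))
        w3 = _connected_variant(lambda: _edge_noise(perturbed, config, rng))
    return (ConnectivityMatrix(cm_t1.subject_id, "T2", w2),
            ConnectivityMatrix(cm_t1.subject_id, "T3", w3))


def generate_clinical_scores(order: str, config: SimulationConfig,
                             rng: np.random.Generator) -> tuple[int, int, int]:
    """Three HDRS scores from zero-truncated normals with the configured
    declining means, identical across arms, rounded to integers."""
    scores = []
    for mean in config.hdrs_means:
        if config.hdrs_sd == 0:
            v = float(mean)
        else:
            v = float(rng.normal(mean, config.hdrs_sd))
            while v < 0:
                v = float(rng.normal(mean, config.hdrs_sd))
        scores.append(int(np.rint(max(v, 0.0))))
    return tuple(scores)


def _draw_age(config: SimulationConfig, rng: np.random.Generator) -> float:
    lo, hi = config.age_range
    a = float(rng.normal(config.age_mean, config.age_sd))
    while not (lo <= a <= hi):
        a = float(rng.normal(config.age_mean, config.age_sd))
    return round(a, 1)


def generate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, dict[tuple[str, str], ConnectivityMatrix]]:
    """Generate the full synthetic cohort: manifest plus all matrices.

    Controls get one baseline network; patients get baseline networks with
    planted deficits plus T2/T3 follow-ups and HDRS trajectories.  Age is
    weakly coupled to a global weight attenuation so the age-adjustment code
    path is exercised.  Fully deterministic given ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s)
               for s in root.spawn(config.n_controls + config.n_patients + 1)]
    arm_rng = streams[-1]
    arms = np.array(["order0"] * (config.n_patients // 2)
                    + ["order1"] * (config.n_patients - config.n_patients // 2))
    arms = arm_rng.permuted(arms)

    rows = []
    matrices: dict[tuple[str, str], ConnectivityMatrix] = {}

    def _attenuate(w: np.ndarray, age: float) -> np.ndarray:
        return w * max(0.2, 1.0 - 0.003 * (age - config.age_mean))

    for i in range(config.n_controls):
        rng = streams[i]
        sid = f"c{i + 1:03d}"
        age = _draw_age(config, rng)
        sex = "M" if rng.random() < 0.5 else "F"
        cm = generate_base_network(config, rng, subject_id=sid)
        cm = ConnectivityMatrix(sid, "T1", _attenuate(cm.weights, age))
        matrices[(sid, "T1")] = cm
        rows.append((sid, "control", age, sex, "none", None, None, None))

    for j in range(config.n_patients):
        rng = streams[config.n_controls + j]
        sid = f"p{j + 1:03d}"
        age = _draw_age(config, rng)
        sex = "M" if rng.random() < 0.5 else "F"
        order = arms[j]
        base = generate_base_network(config, rng, subject_id=sid)
        t1 = apply_patient_effects(base, config, rng)
        t1 = ConnectivityMatrix(sid, "T1", _attenuate(t1.weights, age))
        t2, t3 = generate_longitudinal_series(t1, order, config, rng)
        matrices[(sid, "T1")] = t1
        matrices[(sid, "T2")] = t2
        matrices[(sid, "T3")] = t3
        h1, h2, h3 = generate_clinical_scores(order, config, rng)
        rows.append((sid, "patient", age, sex, order, h1, h2, h3))

    manifest = pd.DataFrame(rows, columns=["subject_id", "group", "age", "sex",
                                           "order", "hdrs_t1", "hdrs_t2", "hdrs_t3"])
    from .io import validate_manifest

    return validate_manifest(manifest), matrices


def write_cohort(outdir, manifest: pd.DataFrame,
                 matrices: dict[tuple[str, str], ConnectivityMatrix],
                 config: SimulationConfig | None = None) -> None:
    """Write manifest, matrices and the resolved configuration to a directory."""
    import yaml

    outdir = Path(outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    write_manifest(manifest, outdir / "manifest.csv")
    for (sid, tp), cm in matrices.items():
        write_matrix(cm, outdir / "matrices" / f"{sid}_{tp}.csv")
    if config is not None:
        with open(outdir / "simulation_config.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
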