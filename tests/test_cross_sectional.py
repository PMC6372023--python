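"""AUC summarization, age adjustment, permutation inference, hubs."""

import numpy as np
import pandas as pd
import pytest

import strucnet as sn
from strucnet.cross_sectional import (auc, age_adjust, identify_hubs,
                                      nodal_metric_curves,
                                      permutation_test_global,
                                      permutation_test_nodal)
from strucnet.thresholding import DensityGrid

GRID = DensityGrid()
D = GRID.densities


def test_auc_constant_linear_and_riemann_oracle():
    assert auc(np.ones(11), D) == pytest.approx(0.1)
    # trapezoid is exact on linear curves: integral of d over [.1,.2] = 0.015
    assert auc(D, D) == pytest.approx(0.015)
    rng = np.random.default_rng(0)
    curve = rng.random(11)
    # trapezoid == mean-of-endpoints Riemann sum at grid resolution
    riemann = sum((curve[i] + curve[i + 1]) / 2 * (D[i + 1] - D[i])
                  for i in range(10))
    assert auc(curve, D) == pytest.approx(riemann)
    with pytest.raises(ValueError):
        auc([1.0], [0.1])


def test_age_adjust_cases():
    ages = np.array([30.0, 40.0, 50.0, 60.0])
    with pytest.raises(ValueError):
        age_adjust(np.ones(4), np.full(4, 40.0))  # zero age variance
    # slope-0 construction (values orthogonal to age): adjustment is a no-op
    vals = np.array([1.0, 2.0, 2.0, 1.0])
    adj = age_adjust(vals, ages)
    assert adj == pytest.approx(vals)
    # exact linear dependence: everything collapses to the grand mean
    adj = age_adjust(2.0 * ages, ages)
    assert adj == pytest.approx(np.full(4, (2.0 * ages).mean()))


def test_permutation_p_is_one_for_zero_observed_difference():
    # identical (value, age) compositions in both groups -> exact zero contrast
    vals = np.concatenate([[1.0, 2.0, 3.0, 4.0, 2.5, 0.5]] * 2)
    labels = np.array([True] * 6 + [False] * 6)
    ages = np.concatenate([[30.0, 35, 40, 45, 50, 55]] * 2)
    res = permutation_test_global(vals, labels, ages, n_perm=200, seed=0)
    assert res.observed_diff == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_permutation_detects_planted_separation():
    rng = np.random.default_rng(2)
    vals = np.concatenate([rng.normal(0, 0.1, 15), rng.normal(10, 0.1, 15)])
    labels = np.array([False] * 15 + [True] * 15)
    ages = rng.uniform(20, 60, 30)
    res = permutation_test_global(vals, labels, ages, n_perm=999, seed=1)
    assert res.p_value == pytest.approx(1.0 / 1000)  # minimal attainable
    assert len(res.null_diffs) == 999


def test_permutation_symmetric_under_label_swap():
    rng = np.random.default_rng(3)
    vals = rng.normal(size=20)
    labels = np.array([True] * 8 + [False] * 12)
    ages = rng.uniform(20, 60, 20)
    r1 = permutation_test_global(vals, labels, ages, n_perm=500, seed=4)
    r2 = permutation_test_global(vals, ~labels, ages, n_perm=500, seed=4)
    assert r1.observed_diff == pytest.approx(-r2.observed_diff)
    # two-tailed statistic: same p up to the permutation-orientation noise
    assert abs(r1.p_value - r2.p_value) < 0.05


def test_permutation_calibration_under_null():
    """Identically-drawn groups: p below alpha in ~5% of repetitions."""
    rng = np.random.default_rng(5)
    rejections = 0
    n_rep = 200
    for i in range(n_rep):
        vals = rng.normal(size=24)
        labels = np.array([True] * 12 + [False] * 12)
        ages = rng.uniform(20, 60, 24)
        res = permutation_test_global(vals, labels, ages, n_perm=199, seed=i)
        rejections += res.p_value < 0.05
    # 95% binomial interval around 0.05 for 200 draws: [4, 17]
    assert 4 <= rejections <= 17


def test_nodal_tests_identical_node_has_p_one_and_fdr_calibrates():
    rng = np.random.default_rng(6)
    n_sub, n_nodes = 24, 30
    y = rng.normal(size=(n_sub, n_nodes))
    y[:12, 0] = y[12:, 0] = np.arange(12.0)  # node 0 identical across groups
    labels = np.array([True] * 12 + [False] * 12)
    ages = np.tile(rng.uniform(20, 60, 12), 2)  # ages mirrored across groups
    out = permutation_test_nodal(y, labels, ages, n_perm=199, seed=0)
    assert out.loc[0, "p_value"] == 1.0
    # all-null nodes: expected count of FDR-significant nodes ~ 0
    assert out["significant_fdr"].sum() <= 1


def test_bh_adjustment_matches_hand_computation():
    """The FDR step applied to p = (.001, .02, .5) must give (.003, .03, .5)."""
    from scipy.stats import false_discovery_control
    adj = false_discovery_control([0.001, 0.02, 0.5], method="bh")
    assert adj == pytest.approx([0.003, 0.03, 0.5])


def test_identify_hubs_edge_cases():
    with pytest.raises(ValueError):
        identify_hubs(np.ones(89))  # zero SD
    v = np.ones(89)
    v[42] = 100.0
    hubs = identify_hubs(v)
    assert hubs.hub_indices == [42]


def test_hub_recovery_overlaps_planted_hubs():
    """Betweenness-AUC hubs (mean + 2 SD rule) recover the implanted
    high-degree nodes with Jaccard >= 0.5 on average over 20 seeds."""
    from strucnet.simulate import planted_hubs

    cfg = sn.SimulationConfig()
    planted = set(planted_hubs(cfg).tolist())
    jaccards = []
    for seed in range(20):
        cm = sn.generate_base_network(cfg, np.random.default_rng(seed))
        bc = nodal_metric_curves(cm, GRID, ["betweenness"])["betweenness"]
        bc_auc = np.trapezoid(bc, D, axis=0)
        found = set(identify_hubs(bc_auc).hub_indices)
        jaccards.append(len(found & planted) / len(found | planted))
    assert np.mean(jaccards) >= 0.5


def test_cross_sectional_analysis_end_to_end(small_cohort_config):
    """Full orchestration on a small cohort: tables well-formed, planted
    deficits carry the right sign, missing subjects excluded listwise."""
    cfg = small_cohort_config
    manifest, matrices = sn.generate_cohort(cfg)
    baseline = {sid: cm for (sid, tp), cm in matrices.items() if tp == "T1"}
    dropped = manifest["subject_id"].iloc[0]
    del baseline[dropped]
    run = sn.RunConfig(n_perm=200, n_null=3, seed=1,
                       global_metrics=["assortativity_r", "lambda",
                                       "clustering_coefficient"])
    res = sn.cross_sectional_analysis(baseline, manifest, run)
    assert res.excluded == [dropped]
    assert set(res.global_tests["metric"]) == set(run.global_metrics)
    assert ((res.global_tests["p_auc"] > 0) & (res.global_tests["p_auc"] <= 1)).all()
    lam_diff = res.global_tests.set_index("metric").loc["lambda", "observed_diff"]
    assert lam_diff < 0  # planted shorter normalized path length in patients
    assert set(res.nodal_tests["metric"]) == set(run.nodal_metrics)
    assert len(res.nodal_tests) == 4 * 89
    assert set(res.hubs["group"]) <= {"control", "patient"}
    assert len(res.null_distributions) == 200
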