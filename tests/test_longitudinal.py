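"""Strength normalization, mixed ANOVA, responders, correlations."""

import numpy as np
import pandas as pd
import pytest

import strucnet as sn
from strucnet.io import ConnectivityMatrix
from strucnet.longitudinal import (classify_responders, delta_correlation,
                                   longitudinal_metrics, mixed_anova,
                                   posthoc_paired_t, responder_anova)
from strucnet.thresholding import DensityGrid
import brute_force as bf


def _cm(weights, sid="s", tp="T1"):
    return ConnectivityMatrix(sid, tp, weights)


def test_normalize_by_mean_strength_properties(base_network):
    out = sn.normalize_by_mean_strength(base_network)
    assert out.weights.sum(axis=1).mean() == pytest.approx(1.0, abs=1e-12)
    # idempotent
    again = sn.normalize_by_mean_strength(out)
    assert again.weights == pytest.approx(out.weights)
    # scale invariance: multiplying the input by 7 changes nothing
    scaled = sn.normalize_by_mean_strength(_cm(base_network.weights * 7.0))
    assert scaled.weights == pytest.approx(out.weights)
    with pytest.raises(ValueError):
        sn.normalize_by_mean_strength(_cm(np.zeros((89, 89))))


def test_longitudinal_metrics_identical_timepoints(base_network):
    series = {"p1": {tp: _cm(base_network.weights.copy(), "p1", tp)
                     for tp in ("T1", "T2", "T3")}}
    table = longitudinal_metrics(series, DensityGrid(),
                                 ["modularity_q", "global_efficiency"],
                                 seed=0)
    for _, row in table.iterrows():
        assert row["t1"] == pytest.approx(row["t2"])
        assert row["t2"] == pytest.approx(row["t3"])


def test_longitudinal_metrics_excludes_incomplete_series(base_network):
    series = {
        "p1": {tp: _cm(base_network.weights, "p1", tp) for tp in ("T1", "T2", "T3")},
        "p2": {"T1": _cm(base_network.weights, "p2", "T1")},
    }
    table = longitudinal_metrics(series, DensityGrid(), ["global_efficiency"], seed=0)
    assert set(table["subject_id"]) == {"p1"}


def _wide(groups):
    rows = []
    for arm, arr in groups.items():
        for i, vals in enumerate(arr):
            rows.append({"subject_id": f"{arm}_{i}", "order": arm,
                         "t1": vals[0], "t2": vals[1], "t3": vals[2]})
    return pd.DataFrame(rows)


def test_mixed_anova_matches_sums_of_squares_oracle():
    rng = np.random.default_rng(7)
    groups = {"order0": rng.normal(size=(4, 3)), "order1": rng.normal(size=(4, 3))}
    aov = mixed_anova(_wide(groups)).set_index("effect")
    oracle = bf.mixed_anova_sums_of_squares(groups)
    for effect, (f, df1, df2) in oracle.items():
        assert aov.loc[effect, "F"] == pytest.approx(f, abs=1e-10)
        assert aov.loc[effect, "df_num"] == df1
        assert aov.loc[effect, "df_den"] == df2


def test_mixed_anova_degenerate_and_structured_cases():
    flat = {"order0": np.full((4, 3), 2.0), "order1": np.full((4, 3), 2.0)}
    aov = mixed_anova(_wide(flat))
    assert (aov["F"] == 0.0).all()  # all responses equal

    rng = np.random.default_rng(8)
    trend = np.array([0.0, 1.0, 2.0])
    groups = {"order0": trend + rng.normal(0, 0.01, (6, 3)),
              "order1": trend + rng.normal(0, 0.01, (6, 3))}
    aov = mixed_anova(_wide(groups)).set_index("effect")
    assert aov.loc["time", "F"] > 100
    assert aov.loc["time", "p"] < 1e-6
    assert aov.loc["order", "p"] > 0.05
    assert aov.loc["order*time", "p"] > 0.05
    # df as implied by the design: time and interaction carry (2, 2(N-a))
    assert aov.loc["time", "df_num"] == 2
    assert aov.loc["time", "df_den"] == 2 * (12 - 2)

    with pytest.raises(ValueError):
        mixed_anova(_wide({"order0": rng.normal(size=(4, 3))}))


def test_posthoc_paired_t():
    a = np.array([20.0, 18, 25, 22, 19])
    b = np.array([15.0, 16, 18, 15, 15])
    t, df, p = posthoc_paired_t(a, b)
    d = a - b
    t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    assert t == pytest.approx(t_hand)
    assert df == 4
    assert 0 < p < 1
    with pytest.raises(ValueError):
        posthoc_paired_t(a, a)  # identical vectors: zero-variance differences
    with pytest.raises(ValueError):
        posthoc_paired_t(a, a - 1.0)  # constant difference, zero variance


@pytest.mark.parametrize("t1,t3,expected", [
    (20, 10, True),    # exactly 50%
    (20, 11, False),
    (22, 10, True),    # 54.5%
])
def test_classify_responders(t1, t3, expected):
    manifest = pd.DataFrame({
        "subject_id": ["p1"], "group": ["patient"], "age": [40], "sex": ["M"],
        "order": ["order0"], "hdrs_t1": [t1], "hdrs_t2": [15], "hdrs_t3": [t3],
    })
    out = classify_responders(manifest)
    assert bool(out.loc[0, "responder"]) is expected


def test_classify_responders_zero_baseline_errors():
    manifest = pd.DataFrame({
        "subject_id": ["p1"], "group": ["patient"], "age": [40], "sex": ["M"],
        "order": ["order0"], "hdrs_t1": [0], "hdrs_t2": [0], "hdrs_t3": [0],
    })
    with pytest.raises(ValueError):
        classify_responders(manifest)


def test_responder_anova_requires_both_strata_and_detects_planted_boost():
    rng = np.random.default_rng(9)
    base = rng.normal(size=(12, 3))
    table = _wide({"True": base[:6], "False": base[6:]}).rename(
        columns={"order": "responder"})
    all_resp = table[table["responder"] == "True"]
    with pytest.raises(ValueError):
        responder_anova(all_resp)
    # planted T3 boost in responders: interaction detected
    boosted = table.copy()
    boosted.loc[boosted["responder"] == "True", "t3"] += 5.0
    aov = responder_anova(boosted).set_index("effect")
    assert aov.loc["responder*time", "p"] < 0.05


def test_responder_interaction_calibrated_under_null():
    rng = np.random.default_rng(10)
    ps = []
    for _ in range(100):
        vals = rng.normal(size=(12, 3))
        table = _wide({"True": vals[:5], "False": vals[5:]}).rename(
            columns={"order": "responder"})
        aov = responder_anova(table).set_index("effect")
        ps.append(aov.loc["responder*time", "p"])
    assert 0 <= np.mean(np.array(ps) < 0.05) <= 0.12  # nominal rate band


def test_delta_correlation_exact_and_null_cases():
    rng = np.random.default_rng(11)
    dh = rng.normal(size=10)
    arms = np.array(["order0"] * 5 + ["order1"] * 5)
    out = delta_correlation(2.0 * dh, dh, arms).set_index("order")
    assert out.loc["order0", "r"] == pytest.approx(1.0)
    assert out.loc["order1", "r"] == pytest.approx(1.0)
    out = delta_correlation(-3.0 * dh, dh, arms).set_index("order")
    assert out.loc["order0", "r"] == pytest.approx(-1.0)
    # independent deltas: r distribution centred at zero
    rs = []
    for _ in range(100):
        rs.append(delta_correlation(rng.normal(size=8), rng.normal(size=8),
                                    np.array(["a"] * 8)).loc[0, "r"])
    assert abs(np.mean(rs)) < 0.1
    with pytest.raises(ValueError):
        delta_correlation(np.ones(6), rng.normal(size=6), np.array(["a"] * 6))


def test_longitudinal_analysis_end_to_end(small_cohort_config):
    """Planted crossover effect: the order x time interaction for modularity
    is recovered from the generated cohort, with the T1->T2 drop in the
    active-first arm only; responder and correlation tables well-formed."""
    cfg = sn.SimulationConfig(n_controls=2, n_patients=12, seed=11)
    manifest, matrices = sn.generate_cohort(cfg)
    run = sn.RunConfig(n_perm=100, n_null=2, seed=2,
                       longitudinal_metrics=["modularity_q", "global_efficiency"])
    res = sn.longitudinal_analysis(matrices, manifest, run)
    aov = res.anova_tables.set_index(["metric", "effect"])
    assert aov.loc[("modularity_q", "order*time"), "p"] < 0.05
    ph = res.posthoc.set_index(["metric", "order", "contrast"])
    assert ph.loc[("modularity_q", "order1", "t1-t2"), "p"] < 0.05
    assert ph.loc[("modularity_q", "order0", "t1-t2"), "p"] > 0.05
    assert res.responders["responder"].isin([True, False]).all()
    assert set(res.delta_correlations["order"]) == {"order0", "order1"}
    assert res.delta_correlations["r"].between(-1, 1).all()
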