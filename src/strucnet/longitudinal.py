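"""Patient-only three-timepoint crossover analysis.

Each patient's T1-T3 networks are normalized by mean network strength,
pushed through the density-threshold + AUC machinery, and the resulting
per-timepoint metric scalars analyzed with a mixed-design repeated-measures
ANOVA (crossover order between subjects, time within), post hoc paired t
tests, a responder (>= 50% HDRS reduction from baseline) analysis, and
per-arm Pearson correlations between metric change and symptom change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ConnectivityMatrix, RunConfig, TIMEPOINTS
from .thresholding import DensityGrid, metric_curves
from .cross_sectional import auc, _subject_rng

__all__ = [
    "classify_responders",
    "delta_correlation",
    "longitudinal_metrics",
    "mixed_anova",
    "normalize_by_mean_strength",
    "posthoc_paired_t",
    "responder_anova",
    "longitudinal_analysis",
]

log = logging.getLogger(__name__)


def normalize_by_mean_strength(cm: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide every weight by the mean nodal strength.

    Nodal strength is a node's summed edge weights; after normalization the
    mean nodal strength is exactly 1.  Idempotent and scale-invariant.
    """
    s = cm.weights.sum(axis=1)
    mean_strength = s.mean()
    if mean_strength == 0:
        raise ValueError("all-zero matrix: mean strength undefined")
    return ConnectivityMatrix(cm.subject_id, cm.timepoint,
                              cm.weights / mean_strength)


def longitudinal_metrics(series: dict[str, dict[str, ConnectivityMatrix]],
                         grid: DensityGrid, metric_set, *, n_null: int = 20,
                         swaps_per_edge: int = 10, seed: int = 0,
                         orders: dict[str, str] | None = None) -> pd.DataFrame:
    """Strength-normalize each timepoint's network and compute metric AUCs.

    ``series`` maps subject_id -> {"T1": cm, "T2": cm, "T3": cm}.  Returns a
    long table with one row per subject and metric, columns t1/t2/t3.
    Subjects missing any timepoint are excluded listwise and logged.
    """
    rows = []
    for idx, (sid, tps) in enumerate(sorted(series.items())):
        if any(tp not in tps for tp in TIMEPOINTS):
            log.warning("excluding %s: incomplete timepoint series", sid)
            continue
        rng = _subject_rng(seed, idx)
        per_tp = {}
        for tp in TIMEPOINTS:
            w = normalize_by_mean_strength(tps[tp])
            curves = metric_curves(w, grid, metric_set, n_null=n_null,
                                   swaps_per_edge=swaps_per_edge, rng=rng)
            per_tp[tp] = {m: auc(curves[m].to_numpy(), grid.densities)
                          for m in curves.columns}
        for m in per_tp["T1"]:
            row = {"subject_id": sid, "metric": m,
                   "t1": per_tp["T1"][m], "t2": per_tp["T2"][m],
                   "t3": per_tp["T3"][m]}
            if orders is not None:
                row["order"] = orders[sid]
            rows.append(row)
    return pd.DataFrame(rows)


def mixed_anova(table: pd.DataFrame, between: str = "order",
                value_cols: tuple[str, str, str] = ("t1", "t2", "t3")
                ) -> pd.DataFrame:
    """Mixed-design repeated-measures ANOVA on a wide subject x time table.

    ``table`` needs one row per subject with columns ``subject_id``, the
    between factor, and the three timepoint values.  Within effects (time,
    interaction) are tested against the time x subject-within-group mean
    square; no sphericity correction is applied, so the time and interaction
    effects carry 2 and 2(N - a) degrees of freedom.  Unbalanced arms are
    supported.  Returns rows (effect, F, df_num, df_den, p).
    """
    import pingouin as pg

    df = table.dropna(subset=[between, *value_cols]).copy()
    arms = df[between].unique()
    if len(arms) < 2 or df.groupby(between)["subject_id"].nunique().min() < 2:
        raise ValueError("need >= 2 subjects in each of >= 2 arms")
    n_sub = df["subject_id"].nunique()
    t = len(value_cols)
    dfs = {between: (len(arms) - 1, n_sub - len(arms)),
           "time": (t - 1, (t - 1) * (n_sub - len(arms))),
           f"{between}*time": ((len(arms) - 1) * (t - 1),
                               (t - 1) * (n_sub - len(arms)))}
    values = df[list(value_cols)].to_numpy(dtype=float)
    if np.ptp(values) == 0:  # all responses equal: every effect SS is zero
        return pd.DataFrame([{"effect": e, "F": 0.0, "df_num": d1,
                              "df_den": d2, "p": 1.0}
                             for e, (d1, d2) in dfs.items()])
    long = df.melt(id_vars=["subject_id", between], value_vars=list(value_cols),
                   var_name="time", value_name="value")
    aov = pg.mixed_anova(data=long, dv="value", within="time",
                         subject="subject_id", between=between, correction=False)
    name_map = {str(between): between, "time": "time",
                "Interaction": f"{between}*time"}
    rows = []
    for _, r in aov.iterrows():
        f = r["F"]
        p = r["p_unc"] if "p_unc" in aov.columns else r["p-unc"]
        if not np.isfinite(f):  # zero effect SS against zero error SS
            f, p = 0.0, 1.0
        rows.append({"effect": name_map.get(r["Source"], r["Source"]),
                     "F": float(f), "df_num": int(r["DF1"]),
                     "df_den": int(r["DF2"]), "p": float(p)})
    return pd.DataFrame(rows)


def posthoc_paired_t(values_a, values_b) -> tuple[float, int, float]:
    """Classical paired-samples t test (two-tailed)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired vectors of length >= 2 required")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1), float(res.pvalue)


def classify_responders(manifest: pd.DataFrame) -> pd.DataFrame:
    """Flag patients with >= 50% HDRS reduction from baseline at T3.

    percent_change = (HDRS_T1 - HDRS_T3) / HDRS_T1 * 100.  Patients with
    missing scores are excluded listwise (logged); a zero baseline is an
    error.
    """
    pats = manifest[manifest["group"] == "patient"].copy()
    missing = pats["hdrs_t1"].isna() | pats["hdrs_t3"].isna()
    if missing.any():
        log.warning("excluding %d patients with missing HDRS from responder "
                    "analysis", int(missing.sum()))
        pats = pats[~missing]
    if (pats["hdrs_t1"] == 0).any():
        bad = pats.loc[pats["hdrs_t1"] == 0, "subject_id"].tolist()
        raise ValueError(f"zero baseline HDRS, percent change undefined: {bad}")
    pct = (pats["hdrs_t1"] - pats["hdrs_t3"]) / pats["hdrs_t1"] * 100.0
    return pd.DataFrame({
        "subject_id": pats["subject_id"].to_numpy(),
        "percent_change": pct.astype(float).to_numpy(),
        "responder": (pct >= 50.0).to_numpy(),
    })


def responder_anova(table: pd.DataFrame) -> pd.DataFrame:
    """2 (responder vs non-responder) x 3 (time) repeated-measures ANOVA.

    ``table`` is wide per subject with a boolean ``responder`` column.
    """
    if table["responder"].nunique() < 2:
        raise ValueError("responder ANOVA needs both responders and non-responders")
    return mixed_anova(table, between="responder")


def delta_correlation(delta_metric, delta_hdrs, arms) -> pd.DataFrame:
    """Per-arm Pearson correlation between metric change and HDRS change.

    Both deltas are T2 - T1 differences; p-values are two-tailed and
    uncorrected.  Requires >= 3 complete pairs and nonzero variance per arm.
    """
    dm = np.asarray(delta_metric, dtype=float)
    dh = np.asarray(delta_hdrs, dtype=float)
    arms = np.asarray(arms)
    rows = []
    for arm in sorted(set(arms.tolist())):
        sel = arms == arm
        x, y = dm[sel], dh[sel]
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if len(x) < 3:
            raise ValueError(f"arm {arm}: fewer than 3 complete pairs")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"arm {arm}: zero variance in a delta vector")
        r, p = stats.pearsonr(x, y)
        rows.append({"order": arm, "r": float(r), "p": float(p), "n": len(x)})
    return pd.DataFrame(rows)


@dataclass
class LongitudinalResult:
    metric_table: pd.DataFrame
    anova_tables: pd.DataFrame
    posthoc: pd.DataFrame
    responders: pd.DataFrame
    responder_anova_tables: pd.DataFrame
    delta_correlations: pd.DataFrame


def longitudinal_analysis(matrices: dict[tuple[str, str], ConnectivityMatrix],
                          manifest: pd.DataFrame, config: RunConfig
                          ) -> LongitudinalResult:
    """Full longitudinal pipeline over all patients with complete T1-T3 data."""
    pats = manifest[manifest["group"] == "patient"]
    orders = dict(zip(pats["subject_id"], pats["order"]))
    series = {}
    for sid in pats["subject_id"]:
        tps = {tp: matrices[(sid, tp)] for tp in TIMEPOINTS if (sid, tp) in matrices}
        if len(tps) == 3:
            series[sid] = tps
    grid = DensityGrid(config.d_min, config.d_max, config.d_step)
    table = longitudinal_metrics(series, grid, config.longitudinal_metrics,
                                 n_null=config.n_null,
                                 swaps_per_edge=config.swaps_per_edge,
                                 seed=config.seed, orders=orders)

    anova_frames = []
    posthoc_rows = []
    for m, sub in table.groupby("metric"):
        aov = mixed_anova(sub, between="order")
        aov.insert(0, "metric", m)
        anova_frames.append(aov)
        interaction_p = aov.loc[aov["effect"] == "order*time", "p"].iloc[0]
        if interaction_p < 0.05:
            for arm, arm_sub in sub.groupby("order"):
                for (ta, tb) in (("t1", "t2"), ("t2", "t3")):
                    t, dof, p = posthoc_paired_t(arm_sub[ta], arm_sub[tb])
                    posthoc_rows.append({"metric": m, "order": arm,
                                         "contrast": f"{ta}-{tb}", "t": t,
                                         "df": dof, "p": p})
    anova_tables = pd.concat(anova_frames, ignore_index=True)
    posthoc = pd.DataFrame(posthoc_rows,
                           columns=["metric", "order", "contrast", "t", "df", "p"])

    responders = classify_responders(manifest)
    resp_map = dict(zip(responders["subject_id"], responders["responder"]))
    resp_frames = []
    for m, sub in table.groupby("metric"):
        sub = sub[sub["subject_id"].isin(resp_map)].copy()
        sub["responder"] = sub["subject_id"].map(resp_map)
        try:
            aov = responder_anova(sub)
        except ValueError as exc:
            log.warning("responder ANOVA skipped for %s: %s", m, exc)
            continue
        aov.insert(0, "metric", m)
        resp_frames.append(aov)
    responder_tables = (pd.concat(resp_frames, ignore_index=True)
                        if resp_frames else pd.DataFrame(
                            columns=["metric", "effect", "F", "df_num", "df_den", "p"]))

    mod = table[table["metric"] == "modularity_q"]
    if len(mod):
        merged = mod.merge(manifest[["subject_id", "hdrs_t1", "hdrs_t2"]],
                           on="subject_id")
        delta_q = merged["t2"] - merged["t1"]
        delta_h = (merged["hdrs_t2"] - merged["hdrs_t1"]).astype(float)
        deltas = delta_correlation(delta_q, delta_h, merged["order"])
    else:
        deltas = pd.DataFrame(columns=["order", "r", "p", "n"])

    return LongitudinalResult(metric_table=table, anova_tables=anova_tables,
                              posthoc=posthoc, responders=responders,
                              responder_anova_tables=responder_tables,
                              delta_correlations=deltas)
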