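"""Baseline patients-versus-controls comparison with permutation inference.

Simulates a small cohort, computes AUC-summarized global metrics, runs the
age-adjusted label-permutation tests and prints the group contrast table
plus the betweenness-centrality hubs of each group.
"""

import strucnet as sn

config = sn.SimulationConfig(n_controls=12, n_patients=12, seed=5)
manifest, matrices = sn.generate_cohort(config)
baseline = {sid: cm for (sid, tp), cm in matrices.items() if tp == "T1"}

run = sn.RunConfig(n_perm=1000, n_null=5, seed=5,
                   global_metrics=["assortativity_r", "lambda", "gamma",
                                   "sigma", "global_efficiency"])
result = sn.cross_sectional_analysis(baseline, manifest, run)

print(result.global_tests.round(4).to_string(index=False))
print("\nhubs (betweenness AUC > mean + 2 SD):")
print(result.hubs.to_string(index=False))
# observed_diff is the patient-minus-control difference of age-adjusted
# AUCs; the planted deficits make assortativity_r and lambda negative with
# small p_auc, while the untouched metrics stay near chance.
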