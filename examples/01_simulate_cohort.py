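"""Generate a synthetic connectome cohort and look at its manifest.

Builds a small version of the default study design: healthy controls with
one baseline scan, patients with planted network deficits, three timepoints
in a two-arm crossover, and declining HDRS depression scores.
"""

import strucnet as sn

config = sn.SimulationConfig(n_controls=8, n_patients=8, seed=42)
manifest, matrices = sn.generate_cohort(config)

print(manifest.to_string(index=False))
print(f"\n{len(matrices)} matrices generated "
      f"({config.n_controls} controls x 1 timepoint, "
      f"{config.n_patients} patients x 3 timepoints).")
w = matrices[(manifest['subject_id'].iloc[0], 'T1')].weights
print(f"each matrix is {w.shape[0]}x{w.shape[1]}, "
      f"{(w > 0).sum() // 2} weighted connections, "
      f"symmetric with zero diagonal.")
# The hdrs_t1..t3 columns show the declining depression-severity trajectory;
# 'order' records which crossover arm received active stimulation first.
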