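"""Small-world normalization against degree-preserving null networks.

gamma = C/C_rand, lambda = L/L_rand and sigma = gamma/lambda, with null
averages over 20 Maslov-Sneppen rewirings that keep every node's degree.
A brain-like network shows gamma > 1, lambda ~ 1, sigma > 1.
"""

import numpy as np

import strucnet as sn

rng = np.random.default_rng(1)
cm = sn.generate_base_network(sn.SimulationConfig(), rng)

for d in (0.10, 0.15, 0.20):
    g = sn.threshold_at_density(cm, d)
    nm = sn.normalized_metrics(g, n_null=20, rng=rng)
    print(f"density {d:.2f}: gamma={nm.gamma:.3f} lambda={nm.lam:.3f} "
          f"sigma={nm.sigma:.3f}")
# gamma well above 1 with lambda near 1 means the network is much more
# clustered than degree-matched random graphs while keeping short paths --
# the small-world signature reported for both patient and control groups.
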