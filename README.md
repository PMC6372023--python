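# strucnet

Graph-theoretic analysis of structural brain connectomes for group studies
of treatment-resistant depression and noninvasive brain stimulation — and,
more generally, for any design built on density-thresholded binary network
metrics with AUC-based permutation inference.

Structural connectivity studies represent each brain as an 89×89 symmetric
matrix of tractography-derived connection densities. `strucnet` implements
the full analysis chain such studies use:

- **Density thresholding**: binarize each matrix at every density d in
  0.10:0.01:0.20 by keeping the k = round(d·n(n−1)/2) strongest
  connections, with deterministic tie-breaks.
- **Graph metrics** (binary, undirected): clustering coefficient C,
  characteristic path length L, global/local efficiency, degree,
  betweenness centrality, degree assortativity r, and Newman modularity
  Q = Σ_c [e_cc/m − (Σ_{i∈c} k_i/2m)²] maximized by a deterministic
  leading-eigenvector optimizer with Kernighan–Lin refinement.
- **Small-world normalization**: gamma = C/C_rand, lambda = L/L_rand,
  sigma = gamma/lambda, against the average of 20 degree-preserving
  Maslov–Sneppen rewirings per graph.
- **Group inference**: each metric curve is reduced to its area under the
  curve (AUC) over the density grid; group differences of age-adjusted
  AUCs are tested with label-permutation tests (5,000 repetitions,
  two-tailed); regional tests add Benjamini–Hochberg FDR correction
  across the 89 nodes. Hubs are nodes with betweenness AUC more than 2 SD
  above the network mean.
- **Crossover longitudinal analysis**: strength-normalized networks at
  three timepoints, order × time mixed-design repeated-measures ANOVA,
  post hoc paired t tests, responder (≥ 50% HDRS reduction) analysis, and
  per-arm Pearson correlations between modularity change and symptom
  change.
- **Synthetic cohort generator**: modular, hub-bearing weighted networks
  with planted patient deficits (lower assortativity, shorter normalized
  path length), a planted modularity drop confined to the active-first
  crossover arm, and declining HDRS trajectories — so the entire pipeline
  is testable end to end without any data download.

See `docs/methods.md` for the model conventions and design choices, and
`examples/` for one narrative script per capability.

## Worked example

Small-world structure of a synthetic brain-like network
(`examples/03_small_world.py`):

```
density 0.10: gamma=1.882 lambda=1.032 sigma=1.823
density 0.15: gamma=1.760 lambda=1.042 sigma=1.689
density 0.20: gamma=1.711 lambda=1.030 sigma=1.661
```

gamma ≫ 1 with lambda ≈ 1 means the network is far more clustered than
degree-matched random graphs while keeping equally short paths — the
small-world signature expected of real structural connectomes.

Baseline group comparison on a simulated cohort of 12 patients and 12
controls (`examples/04_baseline_comparison.py`):

```
           metric  observed_diff  p_auc  n_perm  n_patients  n_controls
  assortativity_r        -0.0021 0.1469    1000          12          12
           lambda        -0.0011 0.0010    1000          12          12
            gamma        -0.0136 0.0010    1000          12          12
            sigma        -0.0113 0.0010    1000          12          12
global_efficiency         0.0003 0.0020    1000          12          12
```

`observed_diff` is the patient-minus-control difference in age-adjusted
metric AUC and `p_auc` its permutation p-value. The planted integration
deficit drives lambda sharply down (p = 0.001); the assortativity deficit
points the right way but, at this small demonstration size, does not reach
significance on every seed — the acceptance suite shows it is detected in
well over 80% of cohorts at realistic group sizes.

A command-line interface mirrors the library:

```sh
strucnet simulate --out cohort/ --seed 1
strucnet cross-sectional --matrices cohort/matrices --manifest cohort/manifest.csv --out results/
strucnet longitudinal   --matrices cohort/matrices --manifest cohort/manifest.csv --out results/
```

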