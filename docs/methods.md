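# Methods

`strucnet` implements a density-thresholded graph analysis of structural
brain connectomes, the inference machinery around it, and a synthetic
cohort generator that reproduces the statistical structure such an analysis
assumes. This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not show.

## The connectome representation

A subject's structural network is an 89×89 symmetric nonnegative weight
matrix with zero diagonal, in dimensionless "connection density" units
(tractography streamline counts normalized by region surface and fiber
length). Node order is fixed by the packaged atlas table: 34
Desikan–Killiany cortical labels per hemisphere, nine bilateral
subcortical/cerebellar structures, bilateral cerebellum white matter and
the brainstem. The exact cortical composition of the original 89-region
parcellation is not publicly distributed; the packaged table is a
documented stand-in with the correct node count, and no analysis depends on
anatomical identity — only on the fixed order.

Validation on read is strict: square shape, symmetry within 1e-10,
nonnegative weights, diagonal zero within 1e-10. Sub-tolerance asymmetry is
averaged out; anything larger is an error, never silently repaired.

## Density thresholding and AUC summarization

Weighted matrices are binarized by keeping the k = round(d·n(n−1)/2)
strongest upper-triangle weights at each density d of the grid
0.10:0.01:0.20 (11 densities). Rounding is half-up; ties among equal
weights are broken by ascending (row, column) index so the retained edge
set is identical across platforms and runs. Edge sets are nested across
densities by construction.

Binary (not weighted) metrics are computed after thresholding: the
degree-preserving null model that anchors the normalized metrics is defined
on binary graphs, and the density-grid + AUC strategy comes from the binary
graph-analysis lineage. Every analysis requires each subject's graph to be
connected at every grid density — characteristic path length is undefined
on fragmented graphs, and the minimum usable density (`find_dmin`) is
defined as the smallest grid density at which every subject's network forms
a single component. Because edge sets are nested this equals the maximum
over subjects of each subject's own first connected density.

Each metric-versus-density curve is reduced to a trapezoidal area under
the curve (AUC), giving one threshold-independent scalar per subject and
metric. The trapezoid rule is exact for curves linear in density (a
constant curve c over [0.10, 0.20] gives 0.1·c).

## Graph metrics

Standard binary-undirected conventions:

- clustering C_i = 2t_i/(k_i(k_i−1)), zero for degree < 2 (Watts–Strogatz);
- characteristic path length L = mean shortest-path length over ordered
  pairs (error when fragmented);
- global efficiency = mean of 1/d_ij with 1/∞ = 0 (finite when fragmented);
- local efficiency of node i = global efficiency of the subgraph induced by
  its neighbors, zero for degree < 2;
- betweenness = unnormalized Brandes shortest-path betweenness with
  fractional sharing over equal-length geodesics, endpoints excluded
  (computed via igraph); the hub rule uses a z-score, so normalization
  cancels;
- assortativity r = Pearson correlation of end-point degrees over the
  doubly-oriented edge list. On degree-regular graphs the variance
  vanishes and r is returned as an explicit NaN, never a silent 0;
  subjects with an undefined AUC are excluded from that metric's test with
  a logged warning;
- modularity Q is maximized by deterministic leading-eigenvector
  bipartitioning with Kernighan–Lin-style single-node fine-tuning, recursed
  with the generalized modularity matrix. The dense symmetric eigensolver
  and lowest-index tie-breaks make the optimizer fully deterministic, so
  longitudinal Q differences carry no optimizer noise. On small two-block
  graphs it attains the exhaustive set-partition optimum (verified in the
  acceptance suite).

Distances are computed with `scipy.sparse.csgraph`; clustering,
efficiencies, degree and assortativity are direct numpy formulas. The test
suite checks every metric against independent brute-force implementations
(triangle enumeration, Floyd–Warshall, explicit geodesic enumeration,
covariance formula, exhaustive partitions) on all 996 non-isomorphic
connected graphs with up to 7 nodes.

## Degree-preserving null models

Normalized metrics compare each graph with Maslov–Sneppen rewirings that
preserve the exact degree sequence: gamma = C/C_rand, lambda = L/L_rand,
sigma = gamma/lambda, with null means taken as arithmetic averages over
n_null = 20 rewired networks. The rewiring performs 10 *accepted*
double-edge swaps per edge (proposals creating self-loops or multi-edges
are rejected); the swap loop is numba-compiled for throughput. Nulls are
required to be connected (otherwise L_rand is infinite); a whole rewiring
is resampled up to 50 times if fragmented. Null streams are derived per
subject from the master seed, so results are reproducible and independent
of evaluation order.

## Cross-sectional inference

Group contrasts are tested on age-adjusted AUCs. Age adjustment is pooled
OLS residualization (both groups in one regression), re-adding the grand
mean. The group statistic is the difference of group means of adjusted
AUCs (patients − controls); the null distribution reassigns subjects to
groups at random, preserving group sizes, with 5,000 permutations by
default; p = (1 + #{|null| ≥ |observed|})/(n_perm + 1), two-tailed, never
zero. Because the AUC spans the full density range, no per-density p-values
exist and no correction across densities is needed. Regional tests run the
same engine per node — one joint subject shuffle per permutation across all
nodes — with Benjamini–Hochberg FDR correction across the 89 nodes within
each metric. Nodal tests are age-adjusted exactly like global ones.

Hubs are nodes whose group-mean betweenness AUC exceeds the network mean by
more than 2 standard deviations; the SD is the population (n-denominator)
SD over the 89 values.

## Longitudinal analysis

Patient networks at T1–T3 are first normalized by mean network strength
(every weight divided by the mean over nodes of summed weights; the result
has mean nodal strength exactly 1, and the operation is idempotent and
scale-invariant). Normalized networks then pass through the same
threshold + AUC machinery, one scalar per metric per timepoint. Thresholded
binary metrics (rather than weighted ones) are used for internal
consistency with the baseline analysis; "betweenness centrality" as a
global longitudinal metric is the network mean of nodal values.

The crossover model is a mixed-design repeated-measures ANOVA (order arm
between subjects, time within; pingouin backend) without sphericity
correction, so time and interaction effects carry (2, 2(N−a)) degrees of
freedom. Fully degenerate inputs (all responses equal) return F = 0 rather
than 0/0. Post hoc paired t tests are run per arm when the interaction is
significant. Treatment response is a ≥ 50% HDRS reduction from baseline
((T1 − T3)/T1; zero baselines are an error); the responder × time ANOVA
uses the same engine. Brain–behavior coupling is the per-arm Pearson
correlation between ΔQ (T2 − T1) and ΔHDRS (T2 − T1), two-tailed,
uncorrected.

Subjects missing any required matrix or score are excluded listwise from
the affected analysis and reported.

## The synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline is validated.

Base networks are stochastic-block graphs on 89 nodes with four contiguous
near-equal modules (within-module edge probability 0.60, between 0.06) and
eight planted hub nodes spread across modules whose edge probabilities are
multiplied by 3 (capped at 1). Present edges carry log-normal weights
(σ = 0.6), the standard heavy-tailed shape of streamline-density
distributions. Networks are resampled until they support the full density
grid and are connected at density 0.10. These parameters were fixed by a
design-phase simulation: they give clearly small-world group networks
(gamma ≈ 1.8–1.9 at the sparsest density) with recoverable planted
modules (adjusted Rand index ≈ 0.99 for the pipeline's own optimizer).

Patient deficits: (1) a fraction (default 0.8) of edges between
top-quartile-degree nodes is swapped against leaf–leaf edges into hub–leaf
pairs — a degree-sequence-preserving manipulation that lowers
assortativity; (2) 30 strong between-module shortcut edges are added and
total weight mass rescaled back to the original sum (conserved exactly),
shortening (normalized) path length. With both effects zero the input is
returned unchanged. Effect sizes were chosen once, by simulation, to give
AUC-level standardized effects of about −1.1 (assortativity) and −2.9
(lambda) — deficits as salient at cohort scale as the empirical ones the
design emulates.

Longitudinal change: the stimulation-linked perturbation relocates
within-module edges to absent between-module pairs (count =
`effect_modularity_drop` × number of between-module pairs, default 0.03,
a Q drop of ≈ 0.10 against within-subject measurement noise of ≈ 0.003).
The active-first arm receives it at T2 and retains it at T3; the sham-first
arm receives measurement noise only at T2 and the perturbation at T3.
Every timepoint adds independent multiplicative log-normal edge noise
(σ = 0.05). All randomized manipulations are resampled (bounded retries)
if they fragment the 0.10-density graph.

Clinical scores are zero-truncated normals rounded to integers with means
(21.76, 17.79, 14.56) and SD 6.26, identical across arms (the emulated
study found no order effect on symptoms); with this geometry roughly 30% of
patients cross the 50% responder threshold. Ages are normal (40, 12)
truncated to 18–65 and weakly coupled to a global weight attenuation; the
attenuation is rank-preserving, so it exercises the age-adjustment code
path without confounding binary metrics.

Determinism: one master seed drives per-subject spawned `SeedSequence`
streams; the same configuration reproduces a byte-identical cohort.

### What the generator does not emulate

No diffusion signal, tractography geometry, anatomically realistic edge
placement, spatial autocorrelation of nodal measures, test–retest scanner
effects, or any true coupling between network change and symptom change
(HDRS and network trajectories are independent by construction). Passing
the planted-effect tests therefore shows that the pipeline detects effects
of the planted kind at realistic scale — not that the empirical findings
would replicate on new patient data.

## Validation problem sizes

The slow acceptance checks use deliberately scaled designs: calibration
runs 500 null cohorts of 20 subjects per group with 1,000 permutations;
planted-deficit recovery runs 50 cohorts of 20 subjects per group
(3 nulls per density, 500 permutations) against 30 zero-effect cohorts;
crossover recovery runs 50 cohorts of 10 patients (and 30 null cohorts).
These sizes keep each check minutes-long while leaving the detection
probabilities (~95% per cohort for the baseline deficits, higher for the
crossover interaction) comfortably above the acceptance margins.

## Known limitations

- The mixed ANOVA uses classical cell-mean sums of squares (via pingouin);
  multilevel models, sphericity corrections and carryover-effect modeling
  are out of scope by design.
- Weighted, directed or signed metric variants are not implemented.
- The modularity optimizer is deterministic but, like all leading-
  eigenvector methods, heuristic on large graphs; optimality is verified
  exhaustively only at small n.
- Assortativity is undefined on degree-regular thresholded graphs; such
  subjects are excluded from that metric's test rather than imputed.
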