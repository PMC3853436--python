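# Methods

## The procedure

`mirhubnet` nominates disease-subtype-related miRNAs from dual
(miRNA + mRNA) expression profiling of the same samples. The reasoning:
a miRNA that matters for a subtype should be a topological hub both in a
network built from its *own* expression and in a network built from the
behaviour of its *targets*. The pipeline:

1. **Differential filter.** A SAM-style moderated statistic
   `d_i = (mean_A - mean_B) / (s_i + s0)` with `s_i` the pooled standard
   error of the mean difference and `s0` the median of the `s_i`.
   Significance by class-label permutation with a pooled null (all
   features' permuted statistics form one reference distribution), FDR by
   Benjamini–Hochberg. Features with `p < 0.05` and `FDR < 0.1` form the
   working panel; a stricter `p < 0.001`, `FDR < 0.05` rule plus a strict
   class-mean inequality assigns each miRNA a subtype *trend* label.
2. **Expression network.** All-pairs mutual information between miRNA
   profiles with the Kraskov–Stögbauer–Grassberger (KSG) estimator
   (algorithm 1): for each sample the Chebyshev distance to its k-th
   neighbour in the joint space sets a box, and
   `MI = psi(k) + psi(N) - mean[psi(n_x+1) + psi(n_y+1)]` over the strict
   marginal counts inside the box, in nats, clamped at 0. Defaults
   `k = 3`; a seeded uniform jitter of amplitude 1e-10 breaks ties, which
   the estimator's continuity assumption does not tolerate. The complete
   MI graph is pruned by the ARACNE data-processing-inequality rule:
   edge (i,j) is dropped when some third node k satisfies
   `MI(i;j) < MI(j;k) - eps` and `MI(i;j) < MI(i;k) - eps`, with
   `eps = 0.05`; all triples are judged against the original matrix and
   marked edges removed at once, so the result is order-independent.
3. **Activity network.** Each miRNA's mapped target genes are pulled from
   the mRNA matrix, centred gene-wise, and summarised by the first
   principal component *across samples*; the score's sign is fixed to
   correlate non-negatively with the mean centred target profile, and the
   explained-variance fraction is recorded (profiles under 40% can be
   flagged, never dropped). The same KSG + DPI machinery then yields a
   second miRNA-miRNA network over the activity matrix.
4. **Topology and hubs.** Per-node degree, unnormalised Brandes
   betweenness, component-normalised closeness `(n_c - 1)/sum d`, local
   clustering; whole-network density, Freeman degree centralization,
   degree heterogeneity `sd/mean`, characteristic path length over
   connected pairs, diameter/radius on the largest component. Hubs are
   nodes with degree at or above a threshold; a Poisson degree null
   (`lambda` = observed average degree) quantifies how rare a given degree
   is under random wiring, and `suggest_threshold` returns the smallest
   degree with tail probability below alpha. Hubs called in both networks
   are intersected into the common-hub report with averaged centralities.
5. **Validation battery.** Stratified 5-fold cross-validated accuracy for
   Gaussian naive Bayes, kNN (k = 3), RBF-kernel SVM and a 5,000-tree
   random forest; a random-set test comparing the candidate set's mean
   pairwise Pearson correlation with equally sized random draws from a
   reference pool; a permutation global test with score statistic
   `Q = sum_j (x_j' y)^2 / m` (standardized features, centred class
   indicator); and a survival comparison — K-means (k = 2) on the
   candidate features, clusters named by their majority subtype, and the
   standard observed-minus-expected two-group log-rank test with
   Kaplan–Meier curves.

## Noise edges and the permutation MI floor

The raw KSG estimate for a truly independent pair is approximately
unbiased around zero, so in any all-pairs scan roughly half of the null
pairs receive a small positive weight. DPI cannot remove them: pruning an
edge requires a third node strongly tied to *both* endpoints, which noise
edges essentially never have. Left alone they form a dense carpet of
near-zero-weight edges in which degree-based hub calling is meaningless.
The pipeline therefore applies, by default, a maxT-style significance
floor before pruning: the maximum KSG MI over B = 2000 seeded
shuffled-pair draws (shuffling one profile of a random pair destroys
dependence while keeping both marginals). Edges below the floor are
zeroed. `build_network(mi_floor=None)` gives the literal floor-free
behaviour; a fixed numeric floor is also accepted.

## The synthetic generator

The generator emulates a two-subtype tumour cohort with a planted,
recoverable answer key. Defaults are the study conditions and stay fixed:

| parameter | default | meaning |
|---|---|---|
| n_class_a / n_class_b | 15 / 41 | subtype sample counts (basal-like / luminal-A regime) |
| n_mirna | 200 | miRNA panel size |
| n_hubs, module_size | 10, 5 | planted regulators and partners per regulator |
| rho | 0.9 | member loading on the hub profile |
| de_fraction, effect_size | 0.25, 1.0 | fraction of miRNAs with a class mean shift, shift in SD units |
| hub_effect_boost | 1.0 | multiplier on shifts landing on hub miRNAs |
| targets_per_mirna, n_genes | 10, 2000 | target map density and gene universe |
| coupling | -0.8 | miRNA -> target linear coefficient (repression) |
| noise_sd | 0.5 | residual SD of targeted genes |
| baseline_hazard, hazard_ratio | 0.1, 1.0 | exponential survival; class-B hazard multiplier |

Modules use a latent-factor construction that is positive-definite at any
size: the hub *carries* the factor (unit loading) and each member loads
`rho` on it with noise scaled to unit marginal variance. Hence
`corr(hub, member) = rho` while `corr(member, member') = rho^2` — member
pairs are indirectly associated exactly as the data-processing inequality
expects, so DPI resolves each module into a hub-centred star and hub
recovery is a well-posed question. (Giving all module miRNAs an equal
loading on a shared factor would make hub and members exchangeable and
hub identification impossible in principle.) Class shifts: each selected
miRNA gets `effect_size` added in one randomly chosen class.
`de_on_hubs=True` concentrates the shifted features on hubs and module
members and lets a shifted member inherit its hub's shift direction
(co-regulated modules trend together); `hub_effect_boost > 1` makes
regulator shifts larger. Together these emulate cohorts where the subtype
signal lives in compact co-regulated regulator modules inside a much
broader weakly-differential panel — the regime in which hub intersection
beats plain differential expression. Targets are drawn
without replacement per miRNA; a gene hit by several miRNAs sums their
couplings. Survival times are exponential with administrative censoring
at the 75th percentile of the uncensored draws (~25% censoring).
Negative default coupling reflects repression; the sign is configurable.

What the generator does **not** emulate: array normalisation artefacts,
heavy-tailed or discrete expression marginals, batch effects, correlated
censoring, or realistic target-map error (false/missing target
annotations). Passing tests therefore demonstrate correctness of the
machinery and recoverability under a clean, favourable data-generating
process — not performance on real microarray cohorts.

## Numerical and design choices

* **KSG variant**: algorithm 1, Chebyshev norm, natural log. k = 3.
  Estimates clamped at 0. Jitter amplitude 1e-10, seeded; in
  `ksg_mutual_information` the jitter streams attach to the
  lexicographically smaller input so symmetry is exact.
* **DPI**: simultaneous removal judged on the original matrix; strict
  inequalities; `eps = 0.05`. Edges with non-positive (clamped) MI are
  never reported, which is what makes "three noise features give a sparse
  or empty network" true.
* **SAM p-values**: pooled null of `n_perm x n_features` permuted
  statistics, `p = (1 + #{|d*| >= |d|}) / (1 + pooled size)` — a valid,
  high-resolution permutation p at modest permutation counts.
* **Closeness normalisation**: per-component `(n_c - 1)/sum d`. On
  connected graphs this makes avg closeness ~ 1/characteristic path
  length; the unnormalised reciprocal-sum variant would be ~two orders of
  magnitude smaller on a 200-node network. Betweenness is unnormalised
  (pair counts). Path computations ignore MI weights (hop counts).
* **Degenerate inputs**: constant vectors give MI 0 with a warning;
  constant features contribute 0 to the global test; a single-cluster
  K-means outcome reports log-rank p = 1 with a warning; centralization
  is 0 with a warning below 3 nodes; an empty hub intersection is a valid
  empty report.
* **Hub threshold**: the operational default stays degree >= 15, the
  disease-network convention appropriate to networks whose average degree
  is ~14. On the synthetic study (average degree ~1 after the MI floor)
  the analysis uses degree >= 4 = module_size - 1: a planted regulator
  keeps at least that many spokes under estimation noise, and
  `suggest_threshold(1.0, 0.05) = 4` marks the same point as the Poisson
  rare-event cut. All thresholds are explicit arguments.
* **Problem sizes**: the acceptance studies use n = 2000 samples for the
  Gaussian estimator check, 200-sample/100-miRNA cohorts for hub
  recovery (5 seeds), 200 null datasets for type-I rates, and the
  15+41-sample, 200-miRNA default regime for the end-to-end study —
  sizes at which every planted property is comfortably measurable.

## Known limitations

* A class mean shift shared by two module members adds mutual information
  between them while diluting their hub legs; with strong, widespread
  differential effects DPI can then occasionally resolve a module around
  a member instead of its hub. This is inherent to MI networks on
  subtype-structured data, and is the main source of the residual
  hub-recovery error measured by the acceptance study.
* The permutation MI floor controls the familywise rate of false edges
  but is conservative; very weak true interactions (MI below ~0.15 nats
  at n = 200) are not recoverable.
* The global test uses label permutation rather than the asymptotic
  distribution: exact finite-sample validity, but p-values are bounded
  below by 1/(n_perm + 1).
* Survival grouping inherits K-means' sensitivity to feature scaling;
  features are used on their native scale.
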