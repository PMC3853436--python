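# mirhubnet

Identify disease-subtype-related miRNAs from **dual expression profiling**
(miRNA and mRNA measured on the same samples) by building two miRNA–miRNA
interaction networks and intersecting their topological hubs.

**Who it is for.** Computational biologists with a two-class cohort (e.g.
basal-like vs luminal-A breast tumours), a miRNA expression matrix, an mRNA
expression matrix and a miRNA→target map, who want candidate subtype-related
miRNAs ranked by network centrality rather than by differential expression
alone — plus a validation battery (classifiers, correlation null, global
test, survival) to interrogate the candidates. A synthetic generator with a
planted answer key lets the whole pipeline run and be scored without any
external data.

## The method

1. **Differential panel** — SAM-style moderated statistic
   d = (x̄_A − x̄_B)/(s + s₀) with permutation p-values (pooled null) and
   Benjamini–Hochberg FDR; keep miRNAs with p < 0.05, FDR < 0.1, and label
   subtype *trends* at p < 0.001, FDR < 0.05.
2. **Expression network** — all-pairs mutual information with the
   Kraskov–Stögbauer–Grassberger kNN estimator (algorithm 1, k = 3,
   Chebyshev norm, nats):
   MI = ψ(k) + ψ(N) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩,
   then ARACNE data-processing-inequality pruning: drop edge (i,j) when
   MI(i;j) < MI(j;k) − ε and MI(i;j) < MI(i;k) − ε for some k (ε = 0.05).
   A seeded permutation MI floor removes the carpet of near-zero noise
   edges that DPI cannot touch.
3. **Activity network** — each miRNA's *activity* is the first principal
   component of its target genes' (centred) mRNA expression across samples;
   the same MI + DPI machinery builds a second network from activities.
4. **Hubs** — degree, betweenness, closeness and clustering per node;
   hub = degree ≥ threshold, with a Poisson degree null
   P(deg ≥ t | λ = avg degree) quantifying rarity; hubs present in **both**
   networks form the candidate report with averaged centralities.
5. **Validation** — stratified 5-fold CV with naive Bayes / kNN(3) /
   RBF-SVM / 5,000-tree random forest; random-set correlation test;
   permutation global test Q = Σ_j (x_jᵀy)²/m; K-means(2) grouping +
   log-rank survival comparison with Kaplan–Meier curves.

See `docs/methods.md` for assumptions, parameter meanings and limitations.

## Worked example

```python
from mirhubnet import SyntheticConfig, generate_dual_dataset, DualNetworkModel

# a 15+41-sample two-subtype cohort, 200 miRNAs, 10 planted hub regulators,
# subtype shifts concentrated on the regulator modules
data = generate_dual_dataset(SyntheticConfig(de_on_hubs=True, seed=1))
model = DualNetworkModel(data.mirna, data.mrna, data.targets, data.survival)
results = model.fit(degree_threshold=4, seed=1)
print(results.summary())
```

```text
Dual miRNA interaction network summary
======================================================
                              expression    activity
nodes                                 39          39
edges                                 29          34
density                            0.039       0.046
avg degree                          1.49        1.74
avg betweenness                     1.36        1.23
avg closeness                      0.589       0.571
centralization                     0.097       0.090
heterogeneity                      0.912       0.671
char path length                   1.671       1.649
------------------------------------------------------
differential miRNAs selected: 39 of 200
hub degree threshold: 4 (hubs: 5 expression, 2 activity)
common hubs: 2
top common hubs (avg degree):
  miR-0118       deg=5.0    btw=10.000    clo=1.0000  trend=luminal_A
  miR-0121       deg=4.5    btw=8.250     clo=0.9167  trend=luminal_A
```

Reading it: 39 of 200 miRNAs pass the differential filter; the two MI
networks are sparse (the permutation floor removes noise edges) and the
hub intersection at degree ≥ 4 returns two candidates. Both are planted
regulators (`data.truth.hub_ids`) — at this 56-sample regime the
intersection trades recall for precision, the same behaviour the degree
threshold discussion in the method is about. At 200 samples the same
pipeline recovers the planted hubs with precision and recall around 0.8
(see the acceptance study). The validation battery is one call away:

```python
report = results.evaluate(seed=1)   # classifiers, random-set, global test, survival
```

The same pipeline runs from the shell:

```bash
mirhubnet simulate --out data/ --seed 1
mirhubnet run-all --mirna data/mirna_expression.tsv --mrna data/mrna_expression.tsv \
    --targets data/targets.tsv --labels data/labels.tsv \
    --survival data/survival.tsv --out results/ --degree-threshold 4 --seed 1
```

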