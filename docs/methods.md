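# Methods

`gutnet` quantifies the *organization* of a gut microbial community — how its
genera co-vary across biological replicates — rather than only its
composition.  The package grew out of the analysis design used in three-arm
rodent hypertension studies (control / hypertensive / anti-hypertensive
treatment, with genus-level 16S amplicon counts per animal), but every stage
operates on generic count tables with group labels.

## Co-occurrence networks

For each experimental group the genus relative abundances are correlated
pairwise with Spearman's rank correlation.  rho is the Pearson correlation of
midranks (ties receive average ranks); the two-sided p-value uses the
t-approximation `t = rho * sqrt((n-2)/(1-rho^2))` with `n-2` degrees of
freedom.  The t-approximation is the standard choice at the sample sizes this
design produces (n = 8–24 per group); an exact permutation p-value would add
little and is not implemented.  Pairs with raw `p < alpha` (default 0.05,
deliberately uncorrected — the within-group network is an exploratory object,
and the downstream bootstrap inference concerns global summaries, not
individual edges) become undirected edges weighted by `|rho|`.  Only the
magnitude of association enters the graph; sign is kept as an edge attribute.
Constant taxa are dropped with a logged warning because rank correlation is
undefined for them; isolated nodes remain in the node set.

Whether to correlate raw counts or relative abundances is a genuine free
choice (rank correlations differ between the two only through per-sample
depth variation); the default is relative abundance, switchable via
`use_relative`.

### Spectral clustering

Nodes are partitioned by spectral clustering of the weighted adjacency:
symmetric normalized Laplacian, the first k eigenvectors, row normalization,
then k-means with a fixed seed.  Isolated nodes are embedded at the origin so
their assignment is deterministic.  k defaults to the eigengap heuristic
(largest gap among the smallest Laplacian eigenvalues, k >= 2, capped at
`k_max = 10`), because the number of modules genuinely differs between groups
and no single k is privileged.

### Global topology parameters

Five scalars summarize a group's network, all on the unweighted edge
skeleton (the classical definitions of these measures are unweighted, and an
edge's presence — not its strength — is what the significance filter
decides):

| parameter | definition | range |
|---|---|---|
| density | `2m / (n(n-1))` | [0, 1] |
| Shannon entropy | `-sum f_d ln f_d` over the empirical degree distribution | >= 0, 0 iff regular |
| centralization | Freeman degree centralization `sum(d_max - d_i)/((n-1)(n-2))` | [0, 1], 1 for a star |
| heterogeneity | coefficient of variation of degrees (population sd / mean) | >= 0, 0 iff regular |
| clustering coefficient | global transitivity, `3 x triangles / connected triples` | [0, 1] |

"Network entropy" and "network centrality/heterogeneity" have no single
canonical definition; the choices above are the common graph-level readings
(degree-distribution entropy; one-number degree centralization; degree CV),
and the tests verify them against brute-force enumeration, not against any
published panel.  Degenerate cases: a graph with no edges reports
heterogeneity 0 with a warning; no connected triples gives transitivity 0;
fewer than 2 nodes is an error.

### Bootstrap inference and group comparison

The sampling unit is the biological replicate (the animal), so bootstrap
resampling draws samples within a group with replacement (same n), rebuilds
the network at the same threshold, and recomputes the five parameters;
B = 1000 replicates by default.  Replicates whose resample leaves fewer than
two non-constant taxa are redrawn (counted; > 50% redraw rate is an error).
Groups are compared per parameter by one-way ANOVA on the replicate vectors
with Tukey-HSD post hoc pairs.  `MicrobiomeNetworkModel.fit()` packages the
whole chain and its `summary()` reports point estimates with bootstrap
replicate 2.5–97.5% ranges (see Known limitations for how to read them).

## Community-level statistics

Bray–Curtis dissimilarity on relative abundances feeds PERMANOVA with
Anderson's partitioning: `SS_total = sum d^2 / n` over all pairs, `SS_within`
from within-group pairs scaled by group size, and
`pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g))`.  The permutation p-value
includes the observed labeling, `p = (hits + 1)/(n_perm + 1)` with
`n_perm = 999` by default, giving the standard bias-free discrete p with
floor `1/(n_perm+1)`; `exhaustive=True` enumerates all distinct label
arrangements instead.  Pairwise Adonis repeats the test per group pair and
adjusts across pairs with Benjamini–Hochberg (Benjamini–Yekutieli
selectable).  The distance is configurable; Euclidean distances on univariate
data make pseudo-F collapse to the classical ANOVA F, which the tests check.

Mann–Whitney U (used for richness contrasts) is exact when the pooled sample
is tie-free and `n_x * n_y <= 400`, otherwise normal approximation with tie
and continuity corrections.

## Differential features

The selection engine is deliberately nonparametric: per-feature
Kruskal–Wallis across groups on relative abundances (depth-invariant),
Benjamini–Hochberg across features, selected iff adjusted p < alpha.  It is a
behavioral replacement for negative-binomial GLM machinery: its contract is
FDR control and reasonable power on planted effects, not numerical agreement
with any count-model fit.  Constant features get p = 1 by convention.  Note
that with 3 x 8 samples and ~200 genera this test has little power after FDR
correction even for four-fold planted effects — small-n studies that report
many differential taxa are using parametric shrinkage this engine
intentionally avoids.  Group-pair log2 fold changes are computed on
pseudocounted mean relative abundances (`pc = 0.5` by default, so
displayed fold changes are compressed toward zero; lower the pseudocount for
quantitative use).  Selected features can be projected on their first two
principal components (SVD on centered, optionally standardized data; rank-1
data legitimately puts all variance on PC1; PC signs are arbitrary).

## Multi-omics integration

Feature blocks — genus abundances, pathway abundances, bone phenotypes,
blood pressure — are inner-joined on sample IDs (dropped samples reported,
fewer than 4 shared samples is an error), min-max rescaled to [0, 1], and
pooled into one Spearman matrix.  All `n(n-1)/2` pairwise p-values are
adjusted jointly by Benjamini–Yekutieli — valid under arbitrary dependence,
which these features certainly exhibit — and pairs with adjusted p < 0.05
become edges weighted by `|rho|`.  Because Spearman is rank-based, the
rescaling provably changes no edge; it is retained as the display convention
of the merged table and tested to be edge-neutral.  A flag restricts the
testing universe to between-block pairs.  Pooling all groups into one
network is the default; per-group integration is available by subsetting.

## The synthetic-data generator

No public data accompanies the study design this package emulates, so the
generator is first-class, tested code.  It draws counts from a
logistic-normal/multinomial model: per-taxon latent baselines
`mu ~ N(0, baseline_log_sd^2)` (default 2.0, giving the few-dominant-genera,
long-tail shape real genus tables show), group-specific block-structured
latent correlation (compound-symmetric blocks, validated positive
semi-definite), planted effects added as `ln(2) * log2_effect` on the latent
scale, softmax to a composition, multinomial at fixed depth (default 20 000
reads/sample, equal per sample — the design states no library-size model, so
none is imposed).  Phenotypes are linear in the clr abundance of a linked
taxon plus group shifts and Gaussian noise; pathways are non-negative
mixtures of taxon subsets with lognormal noise.  One global seed splits into
fixed per-operation streams, so each operation is individually reproducible.

The default `study_config()` mirrors the emulated design: 3 groups x 8
samples, 200 genera; one large (12-genus) correlation block in the control
group, the same genera fragmented into four 3-genus blocks under
hypertension, two 6-genus blocks under treatment; four planted differential
genera (one enriched and rebalanced by treatment, one enriched and not
restored, two suppressed and not restored); blood pressure and trabecular
bone phenotypes linked to planted taxa.

**What the generator does not emulate.**  Real amplicon data carry
overdispersion beyond multinomial sampling, spatial/temporal structure,
taxonomic misassignment and variable library sizes.  Passing tests therefore
demonstrate that the *analysis machinery* is correct and well-calibrated
under a known compositional model, not that any biological conclusion
transfers.

**Compositional closure.**  Because compositions are closed, a latent
correlation block spanning *all* taxa cancels exactly in relative abundances
(the shared factor is absorbed by the softmax normalization), and with few
taxa or heavy abundance skew the closure induces spurious negative
correlations between blocks.  Two consequences are built into the test
design: planted-block recovery checks embed blocks among unstructured
background taxa, and the fragmented-versus-single-block contrast
(12 taxa, mild skew `baseline_log_sd = 0.25`, depth 10 000, n = 40) is run
where the planted signal, not the closure, dominates.  This is also a real
caveat of plain-Spearman co-occurrence networks on compositions, which this
package implements by design rather than replacing with
compositionality-aware estimators.

## Numerical and reproducibility choices

* Simulation sizes in the test suite: oracle equivalences at 50–1000 random
  instances; permutation-validity at 500 simulated studies with 199
  permutations; planted-structure, power and multi-omic recovery at 100
  repetitions; the end-to-end determinism check runs the pipeline at B = 100
  on a 60-genus table.  These sizes give Monte-Carlo error comfortably below
  the tested margins.
* All permutation/bootstrap procedures take explicit seeds;
  `run_pipeline` derives stage seeds from one top-level seed and writes a
  manifest of SHA-256 artifact hashes, so a rerun with the same
  configuration is verifiably bit-identical.
* Ties in ranks always use midranks; p-values are clipped to [0, 1]; rho is
  clipped to [-1, 1] before the t-transform; `|rho| = 1` maps to p = 0.
* Shannon quantities are in nats (log2 selectable for sample diversity).

## Known limitations

* Edge-level inference in the per-group networks is uncorrected by design;
  only the bootstrap summaries support between-group claims.
* The Kruskal–Wallis stand-in is conservative at n = 8/group (see above).
* Spearman on compositions is subject to closure-induced negative
  correlation; interpret negative edges cautiously.
* The bootstrap treats taxa as fixed and resamples animals; it does not
  propagate uncertainty from sequencing depth or taxonomic assignment.
* Bootstrap replicate distributions of the topology parameters are shifted
  upward relative to the point estimate: resampling with replacement
  duplicates samples, and duplicated rows add rank co-movement that inflates
  |rho| and hence edge counts.  Between-group comparisons remain meaningful
  because every group carries the same resampling bias, but the replicate
  quantiles should not be read as confidence intervals around the point
  estimate.
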