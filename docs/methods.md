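# Methods

This document records the statistical model, the default parameters and why
they were chosen, and the numerical conventions that make runs exactly
reproducible. Notation: *T* timepoints (default four: E14.5, 1mo, 6mo,
12mo), two genotypes (WT, MUT), *n* replicates per genotype × age cell.

## 1. Count model (simdata)

Counts are negative binomial with the standard RNA-seq mean–variance
relation Var = μ + αμ². For gene *g*, sample *s* at age *t(s)*:

```
mu_gs = sf_s * 2^( b_g + batch_s + I[MUT(s)] * effect_scale * delta_{g,t(s)} )
```

- `b_g` — baseline log2 mean, uniform on `baseline_log2_mean_range`
  (default (3, 10)): mean counts from ~8 to ~1000, the range left after
  typical low-count filtering of bulk RNA-seq.
- `batch_s` — per-processing-batch log2 shift, Normal(0, 0.25); batches are
  balanced *within* every genotype × age cell so the genotype contrast is
  never confounded (the DE stage refuses confounded designs).
- `sf_s` — library size factor, log-uniform on (0.7, 1.4).
- `alpha` (`nb_dispersion`) — default 0.05, a typical bulk RNA-seq
  dispersion for moderately expressed genes; `alpha = 0` falls back to
  Poisson.
- `delta_{g,t}` — zero for null genes, otherwise one of five archetypal
  temporal profiles. A seeded shuffle followed by round-robin assignment
  makes the non-null count exact (`floor((1 - frac_null) * n_genes)`),
  not binomial.

### Default archetypes and their geometry

```
down_early_equalize   (-1.5,  0.75,  0.75,  0.0)
down_1mo_transient    ( 0.75, -1.5,  0.75,  0.0)
down_6mo_transient    ( 0.75,  0.75, -1.5,  0.0)
up_12mo               ( 0.0,   0.05, 0.0,   1.1)
down_12mo             ( 0.05,  0.0,  0.05, -1.1)
```

The shapes are age-localized genotype effects — an early deficit that
equalizes (with mild compensatory overshoot), transient mid-life deficits,
and late-onset changes — with peak |log2FC| at 1.5, small-magnitude effects
as expected of a heterozygous model yet detectable at n = 6.

Their arrangement is deliberate. Under 1 − Pearson distance with a fixed
cut, groups of noisy standardized profiles stay separate only if their
template correlations are near zero or negative: for complete linkage at
cut height *h*, two groups merge unless some cross-group *pair* reaches
distance ≥ *h*, so at the default cut 1.6 the broad noise clouds around two
templates must be able to produce pairs at correlation ≤ −0.6. Centered
4-point profiles live in a 3-dimensional space, where five unit vectors
cannot be made pairwise strongly negative (a Gram-matrix positivity bound
caps the *average* pairwise correlation of five vectors at −0.25). The
defaults therefore use a triangular-bipyramid configuration: the three
"equatorial" transient shapes at mutual correlation −0.5, and two
near-antipodal late-onset "poles" essentially uncorrelated with the
equatorials. The pole peak is 1.1 rather than 1.5 so that, after
standardization, the pole clouds are broad enough for extreme pairs to
reach the separating correlations. Measured recovery at the default
configuration: ARI ≥ 0.9 against the planted labels in ~19/20 seeds
(complete linkage, cut 1.6) and 20/20 (average linkage, cut 0.8; see §3).

### Simulated gene sets

`simulate_gene_sets` emits, per archetype, sets drawing ≥ 80% of their
members from that archetype's genes (rest uniform), plus uniform background
sets, so enrichment recovery is testable: linked sets should be significant
for the matching recovered cluster, background sets should not.

## 2. Differential expression (dge)

- **Size factors** — median-of-ratios: per sample, the median over
  all-positive genes of count / geometric-mean(count across samples). This
  assumes most genes are unchanged; a majority of one-directional DE genes
  biases it (documented failure mode, exercised in tests). If no gene is
  positive in all samples, an explicit `fallback_total_count` switch uses
  library totals scaled to geometric mean 1.
- **VST-like transform** — `log2(count / sf + 1)`. A deliberate stand-in
  for a model-based variance-stabilizing transform: simple, monotone,
  exactly reproducible.
- **Per-age test** — OLS of VST on intercept + MUT indicator + batch
  dummies, vectorized over genes via (XᵀX)⁻¹Xᵀ; two-sided t-test on the
  genotype coefficient (the log2FC). Conventions: constant genes get
  coefficient 0 and p = 1; zero-residual perfect fits get p = 0 when the
  coefficient is nonzero. BH adjustment is applied within each age; the DE
  call is adjp < 0.1 (strict inequality).
- **Estimator precision** — with n = 6 and α = 0.05 the irreducible sd of
  the log2FC estimate from dispersion alone is √(2·(α/ln²2)/6) ≈ 0.19,
  rising toward ~0.25 for low-expression genes; tests assert near-zero bias
  and ≥ 90% coverage of a planted unit effect within ±0.5 (~2.4 sd).

## 3. Temporal clustering (timecluster)

1. **Union** — genes with adjp < `adjp_threshold` (0.1) at ≥ 1 age; their
   profiles keep the fold-changes at *all* ages.
2. **Standardization** — divide each profile by its max |log2FC|; every row
   attains ±1 and shape, not magnitude, drives similarity. All-zero rows
   (degenerate input only) are dropped with a warning.
3. **Distance** — d = 1 − Pearson r, range [0, 2]. Zero-variance
   conventions: a constant profile has correlation 0 with any non-constant
   profile, and 1 with another constant profile of the same sign (else 0).
   The matrix is symmetrized and clipped to remove float round-off.
4. **Tree** — `scipy.cluster.hierarchy.linkage` on the condensed distances;
   `complete` (default), `average`, `single`, `ward`.
5. **Cut** — merges strictly *below* the cut height are applied (a merge at
   exactly the height is not; implementations differ here and the strict
   rule is fixed for reproducibility). Cut 0 yields singletons; cut above
   the maximum merge height yields one cluster. Cluster ids are 1..k by
   decreasing size, ties by smallest member index.
6. **Centroid filter** — single pass: each preliminary cluster's centroid
   is the per-age mean of its members' standardized profiles (computed once
   from the unfiltered membership, not recomputed after removals); members
   with r < `min_centroid_corr` (0.5) are removed. Singletons equal their
   centroid (r = 1 by convention).
7. **Size filter** — clusters left with fewer than `min_cluster_size` (30)
   genes are dropped; exactly 30 is retained. Survivors are renumbered by
   decreasing size.

Default cut height 1.6 matches classic fixed-height hclust practice for
correlation distances. For **average** linkage the same cut cannot separate
five groups: average linkage merges unless the *mean* cross-group distance
reaches the cut, and five centered 4-point templates cannot be mutually
anticorrelated at −0.6 (the Gram bound above). When using average linkage,
a cut of 0.8 — midway between the observed within-group merge heights
(~0.2–0.4) and between-group heights (~1.0) — recovers the planted
structure; the package treats the cut as a free parameter and documents
this pairing rather than silently rescaling.

**Recovery scoring.** ARI is computed over retained genes that carry a
planted template. Retained null genes (BH at 0.1 admits ~10% of them,
biased toward spike-like shapes) are contamination of the recovered
clusters, not a sixth class; including them caps ARI near 0.83 regardless
of clustering quality.

## 4. Gene sets (genesets)

- **GMT** — name TAB description TAB members; malformed lines and duplicate
  names rejected with line numbers; members deduplicated preserving order.
- **ORA** — upper-tail hypergeometric P(X ≥ k) for overlap k between an
  n-gene query and a K-gene set in an N-gene universe (sets are clipped to
  the universe first; queries must be inside it). BH within each query;
  significance is adjp < 0.05.
- **Cross-study overlap** — each list is queried against the others
  treated as a custom GMT, same machinery.
- **UpSet counts** — exclusive intersections (elements in *exactly* a
  combination); they partition the union.
- **Pathway aggregation** — per sample, the mean VST over a pathway's
  genes, keyed by genotype × age × replicate; absent genes are dropped with
  a warning, fully absent pathways are an error.

## 5. Reproducibility conventions

- Every stochastic step takes an explicit seed; identical configs give
  byte-identical output files.
- Array extraction uses contiguous copies before reductions so results do
  not depend on the caller's memory layout, and DE tables are re-read with
  round-trip float parsing, so the file-contract CLI path (`de` then
  `cluster`) is byte-identical to the in-memory `all` path.
- Strict inequalities throughout (adjp < threshold, merge height < cut,
  r < min corr ⇒ removed, size < min ⇒ dropped).

## 6. What the simulator does and does not emulate

It reproduces the *design* (2 genotypes × 4 ages × 6 replicates, batches,
library-size variation, NB noise) and plants idealized temporal archetypes;
problem sizes (1000 genes, ~100 genes per archetype) are the package's own
choices, selected so cluster sizes are comparable to what such studies
report while keeping tests fast. It does not emulate gene–gene correlation,
expression-dependent dispersion trends, transcript-length effects, or any
real biological pathway structure; cross-study overlap and enrichment are
validated on synthetic sets only. The VST and the per-age OLS are stand-ins
for model-based count methods (e.g. shrinkage dispersion estimation); they
are calibrated (see null results in the acceptance report) but less
powerful than dedicated DE packages, and median-of-ratios normalization
inherits the usual minority-DE assumption.
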