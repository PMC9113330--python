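# Methods

## Model and procedure

A phosphosite is *stably phosphorylated* if it is (i) identified in most
datasets of a large heterogeneous collection and (ii) essentially unresponsive
to the perturbations those datasets probe. The two properties are quantified
separately and combined into a single significance.

**Recurrence (X₁).** The count of datasets whose site list contains the site;
an integer in [1, D]. It depends only on detection, never on the fold-change
values.

**Phosphorylation change (X₂).** Per dataset, the maximum |log2FC| over all
non-missing conditions — the worst-case excursion, chosen because a site may
respond to only one of many treatments and in either direction. Sites
identified in strictly more than 20% of datasets (with D = 53 the threshold
10.6 keeps recurrence ≥ 11) are retained; their per-dataset maxima are
quantile-normalized across datasets and averaged over the datasets where the
site was observed.

**Gamma tails and Fisher combination.** Both features are non-negative and
right-skewed; each marginal over the filtered sites is fitted with a gamma
distribution by maximum likelihood (method-of-moments start α₀ = m²/v,
β₀ = m/v; `scipy.stats.gamma.fit` with location fixed at 0). Stability
p-values are p₁ = P(X₁ > x₁) (upper tail) and p₂ = P(X₂ ≤ x₂) (lower tail);
the combined statistic is Fisher's −2(ln p₁ + ln p₂) referred to χ²₄, i.e.
for two components p_combined = p₁p₂(1 − ln p₁p₂). Sites with
p_combined < 0.01 (strict) are called SPSs. No multiple-testing correction is
applied by default; the CLI can append a Benjamini–Hochberg column as a
diagnostic.

Both marginals are fitted on the *filtered* site set — the set on which X₂
exists — so the two p-values refer to the same population. The recurrence
marginal is discrete but modelled continuously, with the upper tail evaluated
at the integer value without continuity correction; at typical collection
sizes the discretization is coarse relative to the fitted scale and this
choice only makes recurrence p-values slightly conservative near the
boundary.

The framework combines the two tails with Fisher's method, which formally
assumes independent components, yet the features are negatively correlated by
construction (frequently detected sites tend to move less). The pipeline
therefore reports the Pearson correlation between X₁ and X₂ as a diagnostic
(−0.35 on the default synthetic study) rather than attempting a dependence
correction; the combined p-value is used as a ranking statistic with a fixed
conservative threshold, not as a calibrated error rate.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `fraction` | 0.20 | recurrence filter: keep sites seen in > fraction·D datasets (strict) |
| `threshold` | 0.01 | SPS call: combined p strictly below this |
| `keep_fraction` | 0.8 | dataset fraction per subsampling repeat (floor(0.8·D), min 2) |
| `repeats` | 10 | subsampling repeats; concordance is Pearson r of −log10 p over shared sites |
| `linkage` | average | hierarchical clustering linkage (Euclidean distance) in the held-out evaluation |

All log2 fold-changes are dimensionless log2 units relative to each dataset's
own control.

## Numerical choices

* **Quantile normalization with unequal dataset sizes.** The reference is the
  pointwise mean of all datasets' empirical quantile functions evaluated on
  the grid (i − 0.5)/G, i = 1..G, with G the largest dataset size; a value of
  rank r among n maps to the reference interpolated at (r − 0.5)/n. This
  reduces exactly to classical quantile normalization when sizes are equal.
  Tied values receive the mean of the reference values their rank range
  spans, so equal inputs stay equal. Datasets contributing fewer than two
  filtered sites are dropped from normalization with a warning.
* **Averaging denominator.** X₂ averages over the datasets where the site was
  observed, not over all D: treating non-detection as zero change would
  conflate missingness with stability and double-count the recurrence signal.
  `n_contributing` is reported so the alternative is recoverable.
* **Zero changes.** A site whose maximum |log2FC| is exactly 0 everywhere
  lies outside the gamma support; such values are replaced by half the
  smallest positive observed value for fitting and evaluation (count logged)
  rather than dropping perfectly stable sites.
* **p-value floors.** Component and combined p-values are floored at 1e−300
  so logarithms stay finite.
* **Duplicate site rows** within one dataset are collapsed by keeping, per
  condition, the value of maximum absolute magnitude — conservative for a
  maximum-change feature.
* **Missing values in clustering.** The held-out evaluation clusters samples
  with average-linkage hierarchical clustering on pairwise-complete Euclidean
  distance scaled by √(total/observed dimensions), avoiding imputation while
  keeping distances comparable across sample pairs with different overlap.
* **Concordance metrics** (ARI, Fowlkes–Mallows, NMI with arithmetic-mean
  normalization, purity, pair-counting Jaccard) are computed directly from
  the partition contingency table. Degenerate conventions: when a normalizer
  vanishes the partitions involved are necessarily identical and the metric
  is 1. Purity is 1 for an all-singleton clustering by construction — it is
  monotone under refinement and is reported alongside the chance-adjusted
  metrics, never alone.
* **Odds ratios** use ad/bc with the Woolf log-scale normal approximation
  (SE = √(1/a+1/b+1/c+1/d)); zero cells receive the Haldane–Anscombe +0.5
  correction (logged), and tables with two zeros in one row or column are
  rejected as undefined. Enrichment tests are one-sided ("greater") by
  default with the foreground excluded from the background side of the
  table.

## The synthetic-data generator

`generate_collection` emulates the structure the framework assumes: 20
datasets over 5,000 sites; a 5% stable core detected in each dataset with
probability 0.95 whose fold-changes are technical noise, Normal(0, 0.1);
background sites detected with probability 0.4, which in any given dataset
respond to the perturbation with probability 0.5, drawing the affected
conditions' fold-changes from Normal(0, 1.0). Condition counts are uniform
on 2–6 per dataset, matching a realistic average of ~4 conditions per study.
Responder conditions *replace* the baseline noise draw rather than adding to
it; with effect SD ≫ noise SD the two constructions are statistically
indistinguishable, and replacement makes the no-signal configuration (equal
SDs, equal detection probabilities) exactly exchangeable between planted and
background sites, giving a clean null for calibration tests.

`generate_eval_dataset` produces a held-out replicated design (default 4
conditions × 4 replicates): background responder sites carry a
condition-specific mean shared across that condition's replicates, so samples
separate by condition on the full matrix, while stable-core sites are pure
noise and carry no sample structure.

What the generator deliberately does **not** emulate: intensity-dependent
(non-random) missingness, peptide-level rollup and localization ambiguity,
correlated co-regulation along pathways, and between-dataset scale
heterogeneity beyond what quantile normalization removes. Passing tests
therefore demonstrate the statistical machinery's correctness and its
behavior under the assumed data-generating structure — not performance on
real mass-spectrometry data, where detection is biased and effects are
correlated.

## Problem sizes and determinism

Tests and the acceptance script run the default study (20 × 5,000, ten 80%
subsamples) — small enough to complete in seconds while leaving ~4,800 sites
after filtering, which is ample for stable gamma fits. Feature computation
and clustering are fully deterministic; all randomness (generator,
subsampling, random site subsets) flows from a single integer seed through
`numpy.random.default_rng`.

## Known limitations

* The gamma/Fisher construction treats the two features as independent; the
  reported combined p is a stability *score* with a fixed threshold, and its
  nominal uniformity holds only under that assumption (verified under the
  simulated null, where detection and effect distributions are exchangeable).
* Recurrence is sensitive to the composition of the collection: datasets that
  share acquisition platforms or cell types inflate recurrence for their
  common sites. The subsampling concordance quantifies, but does not remove,
  this dependence.
* Site identifiers are treated as opaque protein strings plus residue and
  position; isoform reconciliation and ortholog mapping are out of scope.
* The quantile-normalization reference depends on which datasets survive the
  ≥2-observation rule; with very sparse collections the reference can be
  dominated by a few large datasets.
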