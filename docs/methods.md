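# Methods

## The model: qualitative signatures from relative expression orderings

Within one sample, any two genes i and j stand in a binary relation
E_i > E_j or E_i < E_j (the *relative expression ordering*, REO).  The REO
depends only on a within-sample comparison, so it is unchanged by any
strictly increasing transform applied to that sample — scaling, shifting,
power/log warps, and therefore most batch and normalisation effects.  That
invariance is the reason rank-based pair signatures can classify a single
sample measured in a different laboratory without renormalisation or a
cohort-derived cutoff.

A pair is *highly stable* within a class when its REO direction is the same
in at least a threshold fraction of that class's samples (default 0.85,
compared inclusively).  Pairs stable in both classes with *opposite*
directions — reversed pairs — are the candidate signatures.  Discovery
restricts mining to a user-supplied gene panel (e.g. a T-cell-related gene
list in the autoimmune application this package generalises), intersects the
per-class stable sets, and orients each surviving pair as
(gene_low_in_case, gene_high_in_case).  Classification of one sample is a
winner-takes-all vote: a pair votes "case" iff E(low) < E(high) strictly;
with a single pair this is exactly the rule "call the sample a case when the
first gene's expression falls below the second's".

Two readings of "overlap of the two pairwise sets" are possible; this
package uses the opposite-direction (reversed) overlap as the signature and
exposes the same-direction overlap separately for diagnostics, since
same-direction stable pairs carry no between-class information.

### Tie and missing-value policy

Ties (E_i = E_j) vote for no direction but count in the evaluable
denominator when mining — ties erode stability rather than inflate it.  In
classification a tied pair votes control (the case rule requires strict
inequality), and an exact vote tie in a multi-pair signature is labelled
control for the same reason.  Samples missing either gene of a pair are
excluded from the mining denominator, guarded by `min_evaluable`
(default: half the class size, rounded up); a sample in which *no* signature
pair is evaluable receives the distinct label `unclassifiable`, which the
evaluation stage counts as an error against the sample's true class so that
n stays fixed.

### The continuous score

`score_sample` returns log2(E(high)/E(low)) (falling back to the difference,
flagged, when a value is non-positive).  It underlies ROC curves and the
fold-change summaries, never the label.  Unlike the binary rule it is *not*
invariant to per-sample monotone transforms; this asymmetry is deliberate
and tested.

## Evaluation

Confusion metrics are exact integer counts with derived fractions.  A
label-only predictor has a one-point ROC, so its AUC is
(sensitivity + specificity)/2 and is reported as `binary_auc`.  Continuous
scores get the Mann–Whitney AUC (ties contribute 1/2) with a DeLong
95% confidence interval (asymptotic, tie-corrected via midranks); the
implementation agrees with `pROC::ci.auc(method = "delong")` on fixed
fixtures.  The DeLong choice is a package decision — standard and
deterministic — where bootstrap intervals would introduce simulation noise.

## Downstream statistics

**ssGSEA.**  Per sample, genes are ranked by expression (average ranks at
ties; the walking order among tied genes follows stable gene order, which a
monotone transform cannot alter).  The set score is the sum over the
descending-expression walk of P_in − P_out, where P_in accumulates
rank^alpha weight over in-set genes (alpha = 0.25, the community default;
the method's originators' weighting) and P_out accumulates uniformly over
out-of-set genes.  Raw scores can be range-normalised over the whole matrix
or z-scored per set across samples (the usual heat-map display).  Scores are
invariant to per-sample monotone transforms and match gseapy's ssGSEA (rank
sample-norm) to numerical precision, which serves as an independent
cross-check in the tests, not as the implementation.

**Class comparisons.**  One-sided Wilcoxon rank-sum via
`scipy.stats.mannwhitneyu`: exact enumeration when both groups are ≤ 25 and
tie-free, otherwise the tie-corrected normal approximation with continuity
correction.  A constant feature reports p = 1 with a warning rather than an
error.

**Differential expression.**  Two-sided Wilcoxon rank-sum per gene,
Benjamini–Hochberg across all tested genes, significance at FDR < 0.01.
Direction comes from class medians; a median tie gives direction "none" and
such genes cannot be "consistent DEGs", since consistency across two cohorts
requires the same sign in both.

**Co-expression network.**  Spearman correlation from seed genes (signature
genes and, typically, inflammation-related genes) to candidate genes (the
significant DEGs), one BH family over all seed × candidate tests (a global
family rather than per-seed — one screen, one FDR), edges requiring both
|rho| > 0.6 strictly and FDR < 0.01.  By default the matrix is first reduced
to within-sample ranks: Spearman on raw values is *not* invariant to
per-sample monotone distortion (a sample-wide inflation lifts all genes
together and manufactures positive cross-sample correlation), whereas
within-sample ranks restore exact invariance and are the natural scale for a
pipeline that never normalises across samples.  Raw-value correlation
remains available (`within_sample_ranks=False`) and is how the vectorised
implementation is cross-checked against `scipy.stats.spearmanr`.  The
gene-versus-cell-score correlation table, by contrast, correlates raw gene
expression with ssGSEA scores and is documented as not distortion-invariant.

**Over-representation.**  Upper-tail hypergeometric P(X ≥ overlap) per
gene set against a user-supplied universe, BH across sets.  Ontology
databases are not bundled; sets arrive as GMT files.

## Input handling

Matrices are plain genes × samples TSV; the GEO series-matrix dialect
(envelope lines and quoted identifiers) is read-only.  No normalisation or
log transform is ever applied.  Probe-level matrices collapse to gene level
by dropping probes mapping to zero or multiple genes and averaging the
rest per gene; missing probe values are excluded from the mean (the
averaging convention is silent on this; exclusion is the least-surprise
choice and is documented here).  Averaging happens on values as stored, with
no unlogging.  Gene identifiers are opaque, case-sensitive strings; missing
values are empty cells or `NA`.

## The synthetic cohort generator

The generator produces the structure the pipeline assumes, with planted
truth for validation:

- **Baseline**: log-normal per gene — meanlog ~ Uniform(1, 4), sdlog =
  `noise_sd` (default 0.5) — positive and right-skewed like microarray
  intensities.
- **Reversed pairs**: per sample, a Bernoulli(stability) draw decides
  whether the sample conforms to its class direction; the two genes' values
  are swapped when the realised ordering disagrees.  This controls the
  ordering frequency exactly and independently of the marginals; the two
  genes share a common meanlog so swapping is distribution-neutral.
- **Differential expression**: selected genes multiplied by
  2^(±`de_log_fold_change`) in case samples, random signs recorded in the
  truth.
- **Correlated modules**: a latent Gaussian factor mixed into member genes'
  log-scale noise at the configured correlation.
- **Monotone distortion**: per sample x → a·x^c + b with a, c > 0 sampled
  from the configured ranges (identity by default; distortion is opt-in),
  applied *after* planting so orderings are preserved by construction; the
  shift is lifted when it would make values non-positive.
- **Missingness**: last, completely at random.

Planted pairs, stable pairs, DE genes and modules occupy disjoint gene
blocks, so no DE constraint can contradict a planted direction; a config
that cannot honour that disjointness is rejected with a diagnostic.  All
randomness flows through one seeded generator: identical config, identical
cohort, bit for bit.

Default cohort sizes are 53 controls and 112 cases, the scale of a typical
discovery cohort for this kind of study; recovery sweeps in the tests plant
one pair at per-class stability 0.95 among ~200 background genes, and the
reproduction script evaluates the discovered rule on cohorts planted at the
per-class consistencies such a signature shows in practice (≈0.87 in a
training cohort; ≈0.94/0.91 in a larger validation cohort).

What the generator does *not* emulate: probe-level structure, platform-
specific noise, realistic immune-cell mixtures, or gene–gene dependence
beyond the planted modules.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated generative
assumptions, not clinical performance on real cohorts.

## Numerical choices

- Stable-pair threshold comparison uses `support + 1e-9 ≥ threshold ·
  evaluable` so exact boundary fractions such as 17/20 = 0.85 pass the
  inclusive rule despite floating-point division.
- Mining accumulates pairwise comparison counts sample by sample into
  genes × genes integer matrices (O(g²) memory); all pairs of 2,000 genes ×
  200 samples mine in well under a minute on one CPU.
- Thresholds ≤ 0.5 are rejected at mining time (direction would be
  ambiguous).
- BH adjustment and Spearman p-values come from statsmodels and the standard
  t approximation respectively; both are cross-checked against brute-force
  oracles in the tests.
- Manifests record SHA-256 digests of every input and output; scientific
  outputs are byte-identical across reruns, and the manifest additionally
  carries a wall-clock timestamp as run metadata.

## Problem sizes used in the test suite

Unit fixtures stay at ≤ 12 genes × ≤ 10 samples where brute-force oracles
are exhaustive; cohort-scale checks use 200–2,000 genes and 80–280 samples,
sizes at which the planted-signal recovery and null calibration properties
are sharp while the whole suite runs in well under a minute.

## Known limitations

- Multi-pair signatures are a majority-vote generalisation beyond the
  single-pair rule the design centres on; they are flagged in provenance.
- The score-based ROC is computed on as-measured values and is not
  batch-invariant; compare score AUCs across platforms with caution.
- The hypergeometric test treats gene sets as fixed and genes as
  exchangeable; it inherits all the usual over-representation caveats.
- `gene_cell_correlations` uses raw expression and is sensitive to
  per-sample distortion (see above).
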