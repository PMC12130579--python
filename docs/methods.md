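# Methods

`agingatlas` re-implements, as a tested pipeline, a cross-tissue multi-omics
analysis of aging: per-tissue proteome and metabolome quality control and
differential calling between a young and an aged group, tissue-specificity
classification of proteins, a four-criterion screen linking circulating
(plasma) proteins to tissue changes, aging-related change scores for feature
classes, weighted co-expression modules with cross-omics eigenfeature
correlation, and a metagenomic stage (diversity, ordination, LDA effect
sizes, KO/pathway aggregation, Procrustes concordance).  Everything is
exercised against a bundled synthetic-study generator with planted ground
truth, so the whole pipeline is testable offline.

## Statistical procedures

**Group tests and differential calls.** The default two-group test is the
equal-variance two-sided Student t-test (Welch and the exact Wilcoxon
rank-sum test are selectable). p-values are BH-adjusted within each tissue.
A feature is called up (down) when p < `alpha` (default 0.05) and the log2
fold change is at least `log2(fc_cutoff)` (default fold 1.5, so 0.585 log2
units); a q-based mode is available. These cutoffs are package defaults, not
field constants: typical tandem-mass-tag studies at n = 4 per group do not
support much stricter rules. Degenerate features (zero variance in both
groups) get stat 0 / p 1 when the means agree and a flagged limiting p of 0
otherwise.

**Change score.** For a class of features in one tissue,
`score = (N_increase − N_decrease) / N_total`, where increase/decrease count
significant up/down calls and N_total counts all detected classed features.
A positive score means the class tends to accumulate with age. Counting
*calls* rather than raw signs is deliberate: raw signs make the score a
coin-flip aggregate at realistic noise.

**Tissue-specificity (TS) score.** For each protein, tissue means of log2
abundance are centred on their cross-tissue median and scaled by
1.4826 × MAD. The scale is floored at max(0.1, 5% of the cross-tissue
range), and each tissue's denominator is additionally floored at
`ts_sem_mult` (default 2.0) × that tissue's standard error of the mean,
where the per-tissue SEM is first shrunk toward the protein's median SEM
across tissues. The two extra floor terms are this package's own robust
design and matter greatly in practice:

* with only ~9 tissues the MAD is estimated from a handful of points and
  collapses by chance ~1% of the time, which would hand organ-specific
  labels to perfectly flat proteins;
* an 8-sample variance estimate is itself unreliable downward (chi-square
  tails), so the raw per-tissue SEM occasionally underestimates the noise
  several-fold — shrinking toward the feature's median SEM removes those
  events;
* a tissue whose within-tissue scatter is large (for example an age-driven
  bimodal distribution) cannot claim specificity on a mean deviation
  comparable to its own measurement error.

With a single observation per tissue the SEM terms vanish and the score
reduces to the plain robust z. Classification follows the printed rules:
organ-specific needs TS ≥ 4 in one tissue plus a margin of 1.5 over the
runner-up (additive margin by default — TS scores can be ≤ 0, which makes
ratio margins ill-defined; a fold mode exists), and organ-enriched covers
TS inside the open interval (2.5, 4) for proteins not specific anywhere.
No equivalence with the adaptive robust-regression tool used for this
purpose elsewhere is claimed; scores are computed on tissue means.

**Spearman correlation.** rho is Pearson on mid-ranks. The two-sided
p-value uses the exact permutation null — all n! orderings, cached per rank
multiset — for n ≤ 9, and the t transform `t = rho·sqrt((n−2)/(1−rho²))`
with n − 2 df above that; |rho| = 1 falls back to the exact tail 2/n!. At
the study's n = 8 matched samples the exact 5% critical value is
|rho| ≈ 0.738, which is what actually gates the pair screen.

**Plasma–tissue screen.** Four criteria applied in order: (1) protein
measured in both plasma and the tissue; (2) plasma up/down call; (3)
|Spearman rho| ≥ `rho_cutoff` (0.6) with p < alpha across subject-matched
samples, young and aged pooled; (4) up/down call in that tissue. Correlation
magnitude is used (negative couplings are biologically real) and the sign
is kept. Pairs with fewer than 4 matched samples are skipped and audited.
Pooling the two age groups means a shared group shift itself induces rank
correlation; that is intrinsic to the published rule and is visible in the
benchmark as occasional spurious pairs among noise-driven double false
calls.

**Longitudinal window.** Subjects qualify with ≥ 5 healthy visits whose
first-to-last span lies in [700, 731] days ("2 years" read as an inclusive
leap-year bound); per kept subject, protein level is rank-correlated with
visit day.

**Weighted co-expression modules.** Unsigned adjacency `|cor|^β` (Pearson),
β chosen as the smallest scanned power whose scale-free topology fit R²
reaches 0.90, else the argmax with a warning flag. The fit discretises
connectivity into 10 equal-width bins and regresses log10 p(k) on log10
mean k, zeroed for non-negative slopes (equal-width, not equal-count: with
equal-count bins the response is constant by construction and the fit is
meaningless). Topological overlap
`ω_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij)` feeds average-linkage
clustering of 1 − ω with a static cut that starts at 99% of the tallest
merge and descends by 0.01 (floor 0.90) until at least two clusters of the
minimum size (30) exist — a documented simplification of dynamic tree
cutting; on well-separated blocks the two agree. Sub-minimum clusters go to
module 0. Module eigenfeatures are the first principal component of the
standardised module submatrix, unit variance, oriented to correlate
positively with the module mean profile; labels (PM1…, MM1…) descend by
module size. Cross-omics module correlation uses Spearman on shared samples
with the t-transform p (Fisher-z selectable) and BH across all pairs.

**Microbiome stage.** Reads are trimmed at the first 4-base window with
mean quality < 20 and dropped below 100 bp or above 5% N (strict).
Shannon H′ is in nats; Chao1 uses the bias-corrected form
`S_obs + F1(F1−1)/(2(F2+1))` unconditionally. Bray–Curtis runs on closed
relative abundances; PCoA Gower-centres and reports the negative-inertia
fraction. The LDA effect-size stage mirrors the LEfSe recipe for two
classes: abundances scaled to 1e6 per sample, Kruskal–Wallis screen at
p < 0.05, 30 bootstrap rounds sampling ⌈2/3⌉ of each class, a regularised
Fisher discriminant (ridge 0.1 × mean within-class variance) whose
per-feature effect is `0.5(|w_f·Δ_proj| + |Δ_f|)`, and
`score = log10(max(mean effect, 1))` thresholded at 3.0. The two-class
design makes the subclass (within-class Wilcoxon) stage degenerate, so it
is omitted; this is a documented variant, not a re-implementation of the
original tool. KO abundance sums member-gene TPM; genes without a KO count
in the TPM denominator only; pathway abundance sums member KOs. Procrustes
centres and unit-norms both configurations, takes the optimal
rotation/scaling from the SVD of the cross-product (m² in [0, 1]) and a
plus-one-corrected permutation p over row permutations.

**Enrichment.** Over-representation is the hypergeometric upper tail with
the printed significance rule: p < 0.05 *and* at least 2 molecules in the
intersection. Preranked enrichment uses the canonical weighted
Kolmogorov–Smirnov running sum (hit weight |score|^1, unweighted mode
available), gene-label permutations, NES = ES / mean |ES_perm| of the same
sign, and BH per sign. Gene sets always come from user GMT files; no
database content is bundled.

## The synthetic study and what it does (not) show

`SimConfig` defaults define the study conditions: 8 tissues + plasma, 4
mice per age group (samples are subject-matched across tissues and plasma),
1200 proteins, 800 metabolites with 8 superclass labels, 120 taxa and 200
KOs in a fecal cohort of 12 mice per group, residual log2 noise 0.4, and a
longitudinal plasma series. Planted truth:

* per-tissue differential features (10% of features, ±1.5 log2) plus 12
  tissue-universal up-features (immunoglobulin-like accumulation);
* 15 tissue-specific proteins per tissue (+6 log2 in the home tissue);
* 20 plasma–tissue pairs sharing a per-subject latent factor whose loading
  is set from the Gaussian rank-correlation identity
  `ρ_S = (6/π)·arcsin(ρ/2)` so the expected Spearman is `pair_rho` (0.9);
  the latent variance is taken *inside* the noise budget
  (`a² = ρ_P·noise_sd²`), so marginal noise and test calibration are
  untouched. Pair proteins carry their own age shift of 2.5 log2 units —
  strong circulating aging markers — because the screen requires an
  unambiguous differential call in both compartments at n = 4 + 4;
* three disjoint equicorrelated module blocks of 60 features per omics
  (within-module correlation 0.8, i.i.d. per-sample factors shared between
  the proteome and metabolome so PM/MM eigenfeatures couple);
* 10 differential taxa (8-fold, half up half down) drawn from the
  upper-middle abundance band — on the 1e6 scale the LDA cutoff 3.0 equals
  an absolute shift of 1e3, i.e. ~0.1% of the community, so rarer taxa
  cannot carry a detectable fold change — plus a 2 + 2 antagonist taxon
  pair driven by one latent factor with opposite loadings (target Spearman
  −0.8), KO profiles as incidence-weighted sums of taxa abundances
  realised through a Poisson gene-count layer, and taxa→metabolite
  couplings with planted signs;
* library sizes uniform in [0.8, 1.2] × depth, counts multinomial.

Null proteins share one cross-tissue baseline (drawn once per feature);
tissue-level deviations come only from planted effects, and planted sets
are mutually disjoint (per-tissue differential sets are also disjoint from
the plasma set), so every recovered signal has exactly one planted cause.
Dual-tissue organ-enriched features are opt-in (`n_enriched`): landing
scores inside the open (2.5, 4) window reliably needs a quieter assay than
the default noise, so the default study plants none and the enriched path
is exercised with a dedicated low-noise configuration.

What passing recovery tests shows: the implemented rules detect exactly the
structures they are defined for, at realistic effect sizes, without
systematic false calls. What they do not show: robustness to features real
data have and the generator does not — batch effects, missing-not-at-random
values, heavy-tailed noise, compositional overdispersion, phylogenetic
correlation among taxa, or shared-cause correlations between compartments.
The one realistic pathology the generator does reproduce is pooled-group
correlation inflation in the pair screen (see above).

## Numerical and degenerate-input choices

Missing values are NaN, never 0. kNN imputation works in feature space
(rows), Euclidean over mutually observed per-feature-standardised columns,
1/distance weights, k clamped with a warning; sample-space neighbours are
pointless at 4 samples per group. The CV filter runs on the linear scale
(CV is scale-dependent; the QC rule was stated for intensities).
Normalisation is log2 + per-sample median centring — an explicit artifact
decision. PCA fixes each component's sign so its largest-magnitude loading
is positive. Strict-vs-inclusive bounds follow the printed wording
everywhere: presence < 80% drops, CV ≥ 0.3 drops, peptide thresholds are
inclusive, organ-community edges need rho strictly > 0.60 (with a 1e-12
float guard), N-fraction strictly > 5% drops, the enriched TS interval is
open. Exact permutation nulls are cached per rank multiset; k-means uses
50 k-means++ restarts at a fixed seed, and module/ME computations are
deterministic given (inputs, config, seed).

## Problem sizes

Multi-seed benchmarks run the full default study per seed: 100 seeds in the
test suite's recovery check and 30 in the acceptance script, 20 replicates
for type-I calibration (3 tissues × 400 features), 99–199 permutations for
permutation p-values in loops, 999 as the single-run default. These sizes
give the rates quoted above binomial standard errors of ~2–5 points while
keeping a full run in minutes on one core.

## Known limitations

Sample-level TS scoring, dynamic tree cutting, module preservation
statistics, signed networks as default, paired/longitudinal differential
designs, batch correction, NMDS, and BIOM/mzML parsing are out of scope.
The LDA effect-size variant and the static dendrogram cut are documented
simplifications; their agreement with the original tools is only claimed on
well-separated planted structure, which is exactly what the recovery tests
exercise.
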