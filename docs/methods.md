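# Methods

This note documents the models, parameters and design choices behind
`radsignet`, in the order the pipeline runs them.

## Data model

A cohort is a wide numeric `FeatureTable` (patients × radiomic features)
with per-column metadata parsed from the pyRadiomics naming dialect
(`original_…`, `log-sigma-<σ>-mm-3D_…`, `wavelet-<XYZ>_…`), plus a
categorical `ClinicalTable`, a binary tumor label and a binary
acquisition-center label. Feature columns are categorized by modality
(CE T1-w, T2-w), filter class (Original / LoG / Wavelet) and feature
family (shape, first-order, GLCM, GLRLM, GLSZM, NGTDM, GLDM). Names
outside the dialect are treated as clinical variables; parsing is total
and round-trips through `canonical_name`.

Two standardization schemes are used. **Z-scoring** subtracts the mean
and divides by the *population* standard deviation (the classifier
pipelines); **robust scaling** subtracts the median and divides by the
interquartile range (the unsupervised audit). Quantiles use linear
interpolation, and IQR = Q3 − Q1; after scaling, non-constant columns
have median 0 and IQR 1 to 1e-9. Constant columns map to zeros with a
warning rather than an error so CV folds never crash. Fitted
`ScalingParams` re-apply bit-identically and serialize to JSON.

Categorical clinical variables are integer-coded when binary and one-hot
encoded at ≥3 levels (Side, Epicenter). Missing codes are imputed with
the mode of the fitting split and logged. Association screening instead
uses per-variable complete cases: listwise deletion would discard
patients that are complete for the variable under test.

## Synthetic cohort generator

The generator's defaults encode the emulated study conditions: 145
patients, 52% positive (the positive count is the ceiling of n·balance,
so 145 × 0.52 → 76), an 82/18 center split, and per modality 107
Original + 4×93 LoG + 8×93 Wavelet features (1223 per modality).

* **Radiomic blocks** are equicorrelated Gaussians: within a (modality,
  filter-class) block, `x = sqrt(ρ)·g + sqrt(1−ρ)·ε` with a shared
  per-patient factor g; default ρ = 0.5. This is the simplest structure
  that reproduces the strong collinearity of radiomic tables.
* **Planted effects**: the first `n_informative` columns of a block
  (default 5) receive a constant shift d for positive patients; d is a
  standardized mean difference because the marginal variance is 1.
  Default d = 0.8, a moderate effect consistent with the cross-validated
  MCC range (~0.5–0.6) such a study reports.
* **Redundant pairs** (default 10 per large block) overwrite a column
  with `0.98·x + sqrt(1−0.98²)·ε` of its neighbor, giving empirical
  |r| ≥ 0.9 at n = 145 — the "same information, two names" pattern of
  real extractors.
* **Clinical associations** are calibrated exactly: class-conditional
  level distributions are solved so the *population* Cramér's V hits the
  target (closed form for binary variables; a one-parameter exponential
  tilt of the marginal, rooted by Brent's method, for ≥3 levels) while
  preserving the observed marginal frequencies. Targets: 0.41 for
  symptoms, 0.38 for tumor size and gross adjacent involvement, 0.1 for
  all other variables (no stronger anchor exists for them). Because the
  bias-corrected estimator is near-unbiased for the population value,
  the empirical corrected V matches the target in the mean (checked by
  Monte-Carlo at n = 500).
* **Batch effect**: a constant `batch_shift` (default 0.5 SD; a mild,
  detectable-but-not-dominant shift) is added to every radiomic feature
  of center-B patients. Centers are assigned *stratified by outcome*, so
  the joint center × tumor Fisher test is null by construction — batch
  structure can never masquerade as biological signal, mirroring the
  balanced two-center design being emulated.
* Missing clinical codes (rate 0.01) are planted on the five variables
  recorded as incomplete in the emulated cohort.

What the generator does **not** emulate: non-Gaussian marginals and
heavy tails of real radiomic features, feature-family-specific
correlation structure, interaction (XOR-like) effects, scanner-specific
variance changes (the batch effect is a pure location shift), and any
image-level provenance. Passing tests therefore demonstrate correctness
of the machinery and calibrated operating characteristics under this
generative model, not performance claims about patient data.

## Clinical association screening

Plain Cramér's V is `sqrt((χ²/n)/min(k−1, r−1))` (no continuity
correction); the bias-corrected version subtracts `(k−1)(r−1)/(n−1)`
from φ² (clamped at 0) and shrinks k and r accordingly. The corrected
statistic never exceeds the plain one and is reported per variable on
that variable's complete cases, sorted descending. Zero-margin rows or
columns are dropped with a warning. Degenerate corrected denominators
(possible only at n ≤ 2) return 0. No significance threshold is applied
— the report is an effect-size ranking.

## Batch-effect audit

The audit chain is robust-scale → 2D embedding → HDBSCAN → pairwise
Fisher enrichment. The embedding backend is UMAP (n_neighbors clamped to
n−2, random_state pinned: runs are bit-deterministic); the stage is
swappable — any deterministic map to 2D satisfies the downstream
contracts, and the clustering/enrichment stages never look at the
embedding parameters. HDBSCAN runs with `min_cluster_size = 5` (~3% of
145 patients); noise points (label −1) are excluded from all tests. For
every unordered pair of clusters a 2×2 table (cluster membership ×
binary label) is built *from the two clusters' members only* and tested
with a two-sided Fisher exact test; Benjamini–Hochberg-adjusted p-values
are reported alongside raw ones, per label type. A fully degenerate
embedding (all points identical) is one cluster by convention. The audit
detects batch structure; it does not correct it.

## DNetPRO signature extraction

Couple scoring fits a linear SVM (`LinearSVC`, C = 1, squared hinge) on
every unordered feature pair within stratified 5-fold inner CV (3 folds
in the fast configurations) and records the mean out-of-fold MCC; the
metric is configurable to accuracy. All pairs share one fold draw, so a
single seed fixes the whole scoring. Inputs are standardized within the
enclosing training split. A guard refuses p > 2000 features (couple
scoring is quadratic); the intended workflow pre-reduces to one radiomic
category first, which is what the benchmark's argmax-category rule does.

The network keeps the top `keep_fraction` (default 0.05) of couples —
ties broken by (score, lower i, lower j), making retention a
deterministic prefix that is monotone in `keep_fraction` — or, with
`score_threshold` set, all couples at or above a hard cut. Connected
components are candidate signatures; each is evaluated by the mean
out-of-fold MCC of an L2-penalized logistic model (λ = 1 on standardized
inputs; "penalized logistic" and "ridge classifier" denote this same
model throughout).

**Procedure A** (outer stratified k-fold, default 10): inside each
training split — score couples, build the network, evaluate every
component, refit the winner, score the outer test fold. The consensus
signature is the component winning most outer splits (ties: higher mean
evaluation score, then lexicographic feature names). **Procedure B**
(three-way hold-out): three stratified thirds rotate through
train/validation/test; couples and network come from the training third,
components are ranked by validation MCC, the winner is refit on
train+validation and scored on test; the reported signature is the best
across the three rotations *by validation score*, never by test score.
Requiring ≥3 samples per class guarantees each third holds both classes.
An alternative mode re-partitions independently per iteration.
Degenerate inner folds (a training fold losing one class, possible only
at extreme sizes) are skipped with a warning.

Signatures export as GraphML plus edge and node CSVs; node importance is
normalized degree centrality (degree/(n−1)), and max-centrality nodes
are flagged as hubs.

## Benchmark harness

`repeated_stratified_cv` redraws stratified folds each repeat (sub-seed
= f(seed, repeat)) and fits the entire pipeline — scaler, SVM-coefficient
selector, logistic classifier — inside each training fold only. The
SVM selector keeps features whose |coefficient| exceeds the mean
|coefficient| (or a top-k), never returning an empty set. MCC uses the
0-on-zero-denominator convention. Distributions are summarized as median
± IQR (linear-interpolation quantiles, matching the scaling module).
Wilcoxon comparisons are paired signed-rank (midranks, zeros dropped,
p = 1 when all differences vanish) when two results share seed and fold
structure, and rank-sum otherwise. The benchmark grid spans
{clinical, radiomic, combined} × {CE T1-w, T2-w, both} ×
{Original, LoG, Wavelet}; failed cells are recorded with their error
message rather than aborting the grid, and per modality the radiomic
category maximizing the median MCC is flagged — the reduction rule that
feeds DNetPRO.

## Orchestration and determinism

Every stage derives a named sub-seed from the one global seed
(SeedSequence over a CRC of the stage name, kept below 2³¹); no hidden
global randomness exists, so re-running any stage — or the whole study —
is bit-identical, which the manifest records via SHA-256 digests of all
artifacts. The bundled default study configuration shrinks each feature
block to one tenth and restricts DNetPRO to the argmax category so a
complete run finishes in minutes on one CPU; the generator's class
defaults remain at full study scale.

## Validation experiment sizes

The self-validation suite (tests and `scripts/acceptance.py`) uses these
problem sizes, chosen to give stable rates at desk-scale runtimes:
planted-signature recovery at d = 1.5, n = 150, p = 50 over 25 cohorts
(3 inner / 3 outer folds); the effect-size sweep d ∈ {0.5, 1, 1.5, 2} at
p = 30 with common random numbers across d; null calibration at n = 150
with 10×10-fold CV for the SVM variant and repeated runs of both DNetPRO
procedures; complementarity and argmax-category recovery over 25 cohorts
each; batch-audit power at a 2-SD shift and false-alarm rate at zero
shift over 30–50 cohorts. Oracle checks are exhaustive where feasible
(all confusion tables with total ≤ 20; all 2×2 Fisher tables on an even
grid with total ≤ 30) and randomized otherwise.

## Known limitations

* Couple scoring is O(p²·folds) SVM fits; beyond ~2000 features it is
  deliberately refused rather than silently slow.
* The consensus rule of procedure A (majority across outer splits) is
  one of several defensible aggregations; the winning component per
  split is exposed so users can apply their own.
* Corrected Cramér's V is clamped at zero, so its sampling mean sits
  slightly below a weak target (≈0.09 for a 0.1 target at n = 145–500).
* UMAP determinism holds per environment; coordinates may differ across
  library versions, though cluster-level conclusions are stable.
* The generator's location-shift batch effect is easier to detect than
  realistic scanner effects that also change covariance; audit power on
  real data will be lower at equal shift size.
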