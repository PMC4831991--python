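# Methods

This note documents the models and procedures `peakproc` implements, the
parameter choices that matter, what the synthetic benchmark does and does
not emulate, and the numerical decisions taken where the standard method
descriptions leave room.

## Data model

A peak table is a samples × features matrix of non-negative intensities
with an explicit boolean missing mask (missing cells are stored as NaN but
the mask is authoritative), per-feature m/z and retention time, and
per-sample class label and QC flag. Keeping missingness as a mask rather
than a sentinel value keeps "no imputation" pipelines well defined all the
way into the statistics: every engine here operates on observed cells only.
The on-disk convention is the XCMS one (features as rows); zeros are read
as missing by default because peak pickers report unfilled peaks as zero or
empty depending on settings (flag-controlled).

## Processing stages

Pipelines apply, in fixed order: normalisation → imputation →
transformation → scaling, each stage optional where the grid allows
(`none`). The full default grid is 2 × 7 × 4 × 5 = 280 permutations.

**Normalisation** (row-wise). SUM divides each sample by its observed-cell
total and multiplies by 100, so rows are in %. PQN builds a reference
profile as the per-feature mean over QC injections (falling back to the
per-feature median over all samples when no QCs exist), forms the quotients
sample/reference over features observed in both, and divides the sample by
the median quotient. Quotient medians use jointly-observed features only;
QC samples are themselves normalised the same way. PQN's output is
invariant to rescaling the reference (tested).

**Imputation** (the six standard methods).
*SV*: every missing cell ← 0.5 × the global minimum observed intensity.
*MN*/*MD*: per-feature mean/median over observed cells.
*KNN*: neighbours are *features*; distance between two features is the
Euclidean distance of their responses over jointly observed samples,
rescaled by √(n/n_joint) so sparsely co-observed pairs are not favoured; a
missing cell takes the unweighted mean of the k = 10 nearest features'
values at that sample (features observed there; per-feature mean as
fallback).
*BPCA*: variational Bayes probabilistic PCA with automatic-relevance
(ARD) priors on the loading axes. Scores are inferred per sample from its
observed coordinates only — a missing cell never predicts itself — and the
loading posterior keeps a shared row covariance that (a) enters the score
precision and the noise update, so the noise variance cannot collapse to
zero on near-interpolating fits, and (b) feeds the ARD precisions, letting
the model switch superfluous axes off. Initialisation is the
eigendecomposition of the mean-imputed matrix (deterministic); the default
axis count is min(n_samples, n_features) − 1 and the ARD prunes from
there; convergence is a 10⁻⁴ maximum relative change of imputed cells,
200 sweeps cap. On exactly rank-1 data with one masked cell the imputed
value is recovered to ≈10⁻⁵ relative error (tested).
*RF*: the missForest scheme — initialise with feature means, visit features
in ascending missing count, regress each on all others with a 100-tree
random forest (√p features per split) fitted on its observed rows, replace
its missing cells with predictions, and sweep until the normalised squared
difference between successive imputations first rises (previous iterate
returned) or 10 sweeps. Seeded and reproducible.

Imputation quality is assessed by masking `floor(0.10 × cells)` of a
complete (SUM-normalised) matrix completely at random, imputing, and
reporting NRMSE = RMSE over the masked cells ÷ mean of the complete matrix.
NRMSE is computed over masked cells only: averaging over all cells would
dilute every method's error toward zero.

**Transformation** (element-wise, observed cells; missing stays missing).
glog `z = ln(y + √(y² + λ))`; natural log (requires positive values — in a
grid run a violation marks the permutation failed rather than aborting the
grid); IHS, identical to glog at λ = 1.

The glog λ is estimated from QC technical replicates. "Minimise the
replicate variance" is degenerate as stated — the pooled within-feature SSE
of the transformed replicates tends to 0 as λ → ∞ because the transform
flattens. The objective used is the Jacobian-normalised (profile-likelihood)
form: J(λ) = SSE(λ) / GM(λ)², where GM is the geometric mean over QC cells
of dz/dy = 1/√(y² + λ); this is the maximum-likelihood treatment used by
the established glog software. λ is found by bounded scalar search on
log₁₀ λ over [min(y)²·10⁻⁴, max(y)²·10⁴]. Under the two-component
measurement-error model y = μ·exp(η) + ε (multiplicative CV at high
abundance, additive noise near zero) the variance-stabilising value is
λ* = σ²_ε/σ²_η; the estimator recovers λ* well within an order of magnitude
and is exactly scale-equivariant, λ̂(cY) = c²·λ̂(Y) (both tested). In grid
runs λ is fitted on the post-normalisation, post-imputation QC rows,
dropping features with missing QC cells.

**Scaling** (feature-wise over observed cells, sd with n − 1): auto
(x−m)/s; Pareto (x−m)/√s; range (x−m)/(max−min); VAST ((x−m)/s)·(m/s).
Zero-spread features are set to all-zero with a warning; VAST with a zero
mean is an error.

## Statistics

The univariate screen removes QC rows, tests each feature two-sided between
the two classes on observed values (Mann–Whitney with tie-corrected normal
approximation, exact for small groups; or pooled-variance Student's t),
excludes features with fewer than 3 observed values in either class from
the family, and adjusts with Benjamini–Hochberg; significance is q < 0.05.

PCA is NIPALS with all inner products restricted to observed cells and
per-component deflation on observed cells, so tables with residual missing
values remain analysable; explained variance per component is the drop in
observed sum of squares over the total centred observed sum of squares. On
complete matrices NIPALS reproduces the SVD to 10⁻⁸ (tested against the
oracle). Class separation on each component's scores is tested with a
pooled t-test when both class score vectors pass Shapiro–Wilk, otherwise
Mann–Whitney; QC samples enter the model but not the separation test.

PLS-DA is PLS1 (NIPALS) against the centred binary class indicator and
requires a complete matrix — cross-validation is ill-defined with missing
cells, so `mvi = none` permutations are reported non-evaluable. R² is the
in-model fraction of indicator variance explained; Q²(A) = 1 − PRESS/TSS
over seeded class-stratified tenfold splits; the component count maximises
Q² over 1..5. R² here is Y-variance (standard chemometrics usage).

## The spike-in benchmark

`construct_modified_dataset` ranks features by mean response over all
samples, splits them into three equal-count tertiles (a rank-based reading
of low/medium/high; a numeric-range split is available by flag), draws 32
features per tertile uniformly without replacement, and multiplies their
intensities in the target class by factors drawn without replacement from
the grid {0.1, 0.2, …, 2.0} ∪ {2.5, 3.0, …, 10.0} (36 values) — 96
ground-truth positives in total. Spiking happens on the complete table
before missingness is injected. Scoring: TP = significant ∩ spiked,
FP = significant − TP; PCA outcomes rank all features by |loading| on PC1,
PC2 and the combined norm √(l₁² + l₂²), flag a *fold-change effect* when
|ln factor| correlates positively with combined loading over the spiked set
(Spearman, p < 0.05), and an *abundance effect* when the top-10 spiked
features fail to cover all three tertiles or mean abundance correlates with
combined loading. Ranking rules: univariate by TP then FP; PCA among
fold-change-driven, non-abundance-driven rows by PC1 separation p then
PC1+PC2 variance; PLS-DA among rows with R² − Q² < 0.20 by R². Ties break
on the permutation label, making every ranking a total order.

## The synthetic generator and its defaults

`generate_null_table` draws feature log₁₀ base abundance uniformly on
[4, 8] (XCMS-like peak areas, heavy-tailed), adds a rank-3 latent Gaussian
in ln-space whose per-feature loading norm is the biological sd 0.16
(≈16 % between-subject CV, deliberately at the low end so the implanted
fold changes — not background biology — dominate the leading principal
components, as in the serum benchmark this emulates), multiplies by
per-sample scale noise (ln-sd 0.15, injection/sensitivity drift) and
technical noise at 8 % CV; QC samples are technical replicates of the
pooled profile. Defaults: 22 + 24 biological samples, 18 QCs, 3000
features, 7.8 % MCAR missingness, no MNAR.

Class labels carry no induced effect and are re-randomised (up to 500
tries) until a Mann–Whitney screen on the SUM-normalised biological samples
finds no feature with raw p < 0.05. This conditioning is what such
benchmark datasets satisfy by construction, and it is what makes zero
false-positive outcomes reproducible: with ~80 strong discoveries, BH at
q < 0.05 would otherwise tolerate a handful of false discoveries by design.
It is feasible by rejection only because the latent biology is low-rank and
shared — the same property that lets a real randomisation of correlated
serum features come out clean. The unconditioned null
(`null_condition="none"`) is used for calibration checks: on a
technical-replicate null (latent rank 0) the raw p < 0.05 rate matches the
nominal 5 % to binomial accuracy; with correlated features the *mean* rate
over seeds is 5 % but single-seed rates fluctuate widely, which is expected
under dependence.

What the generator does **not** emulate: chromatographic drift, batch
effects, heteroscedastic per-feature CVs, and adduct/isotopologue
near-duplicate features. The last omission matters for interpreting KNN
imputation: in real data the nearest feature is often another ion of the
same metabolite and KNN shines; here feature correlation is only the shared
latent biology, so KNN's advantage over mean imputation appears when
feature scales are comparable (the NRMSE fixtures use a one-decade
abundance span for this reason) and is diluted when raw intensities span
four decades, because unscaled neighbour averaging then carries an
abundance bias.

## Problem sizes used by the test and acceptance runs

Chosen as desk-scale renditions of the study conditions: the spiked
benchmark runs at its full defaults (3000 features, five seeds) for the
univariate checks; the multivariate reduced grid (2 × 7 × 2 × 2) runs at
300 features with 8 spikes per tertile (keeping the spiked fraction near
the default 3 %); NRMSE fixtures use 30 samples × 150 features; λ-recovery
uses 400 features × 8 replicates. All stochastic steps are seeded, and
fixed seeds give bit-identical outputs.

## Known limitations

- The PLS-DA R²−Q² ordering among imputation methods is not resolvable at
  desk scale: implanted fold changes up to 10× against 16 % biological CV
  make the classes almost perfectly separable, so every evaluable pipeline
  reaches Q² ≈ R² ≈ 1 and the tiny gaps are cross-validation noise. Partial
  class overlap (R² ≈ 0.6, as in real serum data) would require background
  biology strong enough to also displace the spike axis from PC1/PC2,
  defeating the PCA benchmark; the generator deliberately favours the
  latter.
- SUM normalisation is vulnerable, by construction, to heavy spikes in
  high-abundance features: in seeds where a dominant feature receives a
  large factor, class-A row totals shift and null features pick up a
  systematic apparent fold change (occasional false positives). PQN is
  robust to this in every seed tested — which is the standard argument for
  preferring PQN.
- BPCA can impute small negative values near zero; a subsequent natural-log
  stage then fails, and the grid runner records the permutation as
  non-evaluable rather than aborting (the same applies to any stage error).
- The missingness filter counts QC samples when computing missing
  fractions (a flag excludes them); the 20 % bound is strict ("more than").
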