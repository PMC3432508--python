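# Methods

This note records the model assumptions, parameter choices, numerical
conventions, and known limitations of `adhdkit`, in the order the pipeline
runs.

## Temporal preprocessing

Inputs are assumed to be motion-corrected, spatially normalized 4D BOLD
volumes; slice timing, realignment and normalization are upstream of this
toolkit and enter as files.  Dropping initial volumes and motion-based
session exclusion are treated as I/O-stage concerns (the phenotype table
carries a `failed_preproc` flag), not computations performed here.

Detrending removes the least-squares straight line per series, so output
series are zero-mean.  Band-pass filtering keeps 0.01–0.08 Hz, the
conventional resting-state band.  The reference filter is DFT-bin zeroing
(band endpoints inclusive, DC removed): it is exactly idempotent, has a
perfectly sharp transition on the analysis grid, and makes the stop-band
tests deterministic.  A zero-phase 4th-order Butterworth is available
(`design="butterworth"`) for users who prefer a smooth transition band; the
tests target the reference design.

## Regional homogeneity

ReHo is Kendall's W over a voxel's cubic neighborhood (K = 27 by default;
19 and 7 supported), computed from midranks over time.  No tie-correction
term is applied, matching the classical KCC normalization; the property
tests use continuous data where ties have probability zero.  Conventions:

- **Mask boundaries.**  By default W is computed with the K′ ≤ K neighbors
  available inside the mask, substituting K′ in the normalization
  (`boundary="shrink"`), which keeps full-brain maps; `boundary="skip"`
  yields NaN at incomplete neighborhoods instead.
- **Degenerate voxels.**  Where every in-mask neighbor is temporally
  constant, concordance is undefined and the voxel is NaN.
- The implementation ranks once and accumulates neighborhood rank sums by
  3D convolution per time point; it is algebraically identical to the
  per-voxel definition (the tests verify exact agreement with a brute-force
  per-voxel oracle).

Smoothing uses a Gaussian kernel with σ = FWHM/(2√(2 ln 2)) per axis in
voxel units, renormalized over the in-mask support so constants are
preserved at boundaries.

## Functional connectivity

FC(i, j) is the Pearson correlation of mean regional time courses.  The
input series are the detrended, band-pass-filtered ones, without spatial
smoothing (smoothing is for ReHo maps; correlations of regional means gain
nothing from it).  Pruning zeroes entries with |r| strictly below the 0.05
cutoff, so edges at exactly the threshold survive; pruning is idempotent and
never touches the diagonal.  Zero-variance regions produce NaN rows/columns
plus a warning rather than silent zeros.  Vectorization takes the strict
upper triangle in row-major order with "i-j" feature ids; with the 351-ROI
functional parcellation this gives 61 425 features per subject.

## Feature selection

The BSS/WSS ratio ranks features univariately.  Conventions: a feature with
WSS = 0 but BSS > 0 separates the classes perfectly and ranks first
(score +inf); an everywhere-constant feature scores 0.  Score ties are
broken toward the smaller feature index, making selection deterministic.
The default filter width is 2000 features (or all, if fewer); at desk scale
the tests use much smaller widths.

SVM-RFE then refines the filtered subset with the RBF kernel.  Because the
kernel is nonlinear there is no weight vector to rank by; feature i is
scored by the margin change ½(αᵀHα − αᵀH⁽⁻ⁱ⁾α), where H_jk = y_j y_k
K(x_j, x_k) over the support vectors, H⁽⁻ⁱ⁾ recomputes the kernel without
feature i, and α is held fixed from the current fit — the standard
nonlinear RFE criterion.  For the RBF kernel H⁽⁻ⁱ⁾ is obtained cheaply as
H · exp(dᵢ²/2σ²).  Each iteration removes ⌈elim_fraction · surviving⌉
lowest-scoring features (default 10%, at least one, ties to the smaller
index) and records the surviving set with its stratified inner-CV accuracy.
Stopping: surviving ≤ min_features (default 50), or inner-CV accuracy ≥ an
optional threshold (disabled by default — any fixed value is dataset
dependent, so it is exposed as configuration only).

Features are z-scored before SVM fits, with statistics from training data
only; RBF distances are meaningless across unscaled heterogeneous features.

## Classification

Grid search evaluates an exhaustive (C, σ) lattice — C ∈ 2^{−5..15},
γ = 1/(2σ²) ∈ 2^{−15..3}, step 2² — by stratified inner CV (5 folds by
default; reduced automatically when a class is smaller).  Ties prefer the
smaller C (less overfitting) and then the larger σ (smoother boundary).

Nested CV uses 10 stratified outer folds: stratification is always by
class, and additionally by site when a site column is present and every
(class, site) cell holds at least one subject per fold — multi-site
baselines otherwise leak into fold composition.  Within each outer fold the
training portion alone drives standardization, hybrid selection, grid
search and the final fit; the held-out tenth is scored once.  The
operational leakage check: under label permutation the pooled accuracy must
sit at the majority fraction within Monte-Carlo error (asserted in the
tests over 10 permutations).

The hierarchical scheme trains stage 1 on patient-vs-control and stage 2 on
the patient subtypes only (combined vs inattentive); a stage-1 control
prediction passes through, anything else is refined by stage 2.  Three-class
accuracy is reported as the exact three-class match fraction.

### Multi-kernel learning

MKL learns β_k ≥ 0, Σβ_k = 1 (L1 simplex — sparse weights, so uninformative
modalities are driven to zero) jointly with the SVM dual coefficients.  The
optimizer alternates an exact SVM solve on the combined kernel Σβ_k K_k
with a projected-gradient step on β minimizing the optimal soft-margin dual
objective (its gradient is −½ αᵀK_kα per kernel), with backtracking step
sizes and convergence on β-change below 1e−6 or no descent.  With one
kernel this reduces exactly to the plain kernel SVM (asserted to 1e−4
against the direct RBF fit).  In fused cross-validation runs the
per-modality feature subsets and (C, σ) from the single-modality folds are
reused rather than re-tuned, trading optimality for a large constant-factor
saving; full re-tuning is available by configuring MKL-specific runs.

Class imbalance is handled by optional random majority undersampling to a
target majority:minority ratio (minority untouched, ⌊ratio · n_min⌋
majority subjects kept, seeded); cost-sensitive class weights are available
on `SvmParams` but off by default.

## Evaluation

The positive class is the patient group throughout.  J = sens + spec − 1;
F1 = 2TP/(2TP + FN + FP), defined as 0 (with a warning) when the
denominator vanishes.  The ROC curve has one point per distinct threshold
plus the (0, 0) anchor; AUC is the trapezoidal area, equivalent to the
½-tie Mann–Whitney pairwise probability (asserted to 1e−12 against a
brute-force pairwise oracle).  Reported rates are rounded to 4 decimals in
serialized output; full precision is kept internally.

## Synthetic phantoms

The ROI phantom draws each subject's series from a zero-mean Gaussian with
a block correlation structure (default 30 ROIs in blocks of 5, within-block
r = 0.5, 150 time points at TR = 2 s, 15 subjects per class per site at 2
sites — small enough to iterate on a desk, large enough that Fisher-z
sampling bounds are meaningful).  The patient class adds Δr = 0.3 to 10
vertex-disjoint between-block edges; disjointness bounds the perturbation's
spectral norm by |Δr|, so positive-definiteness is guaranteed whenever
|Δr| < 1 − r_block, and the generator verifies it by Cholesky.  Site
effects are an additive baseline shift plus a multiplicative scale — the
simplest mechanism that shifts feature baselines between sites; note both
leave correlations invariant, so they stress standardization and
stratification rather than FC itself.  Low-frequency structure is a random
linear drift (slope SD 0.1) and measurement noise is white Gaussian
(SD 0.3 against unit-variance signal).

The voxel phantom places ROIs as 3×3×3 boxes on a lattice with one-voxel
gaps; every voxel carries its ROI's signal plus independent noise
(SD 0.3), so within-ROI concordance is high and regional averaging over 27
voxels recovers the generating signal (noise shrinks by √27).  The feature
table generator shifts informative features by ±δ/2 between classes with
unit within-class SD; class effects on tables are mean shifts, while class
effects on time series are correlation (edge) shifts — each matches what
the corresponding pipeline stage consumes.

What the phantoms deliberately omit: hemodynamic response shape, motion
artifacts, physiological noise spectra, realistic spatial autocorrelation,
and site-by-class confounding.  Passing tests therefore demonstrate the
statistical machinery — ranking, selection, leakage-free validation,
fusion — under the assumed generative structure, not clinical-grade
accuracy on real cohorts.

## Problem sizes and determinism

Test and example runs use desk-scale sizes (tens of subjects, hundreds of
features, ≤ 10³ voxels) chosen so sampling-error bounds stay meaningful
while the full suite completes in well under a minute per stochastic suite;
the stochastic criteria (planted-feature recovery, permutation null, MKL
weight concentration) are fixed-seed simulations with explicit success
margins.  Every source of randomness — generators, fold assignment, inner
shuffles, undersampling — takes an explicit seed, and run manifests record
the configuration hash and seeds, so pipelines rerun bit-identically.

## Known limitations

- Phenotype covariates (age, sex) are not used by the classifiers.
- Voxelwise (non-ROI) connectivity is out of scope.
- No confidence intervals on AUC; no calibration analysis.
- The MKL optimizer targets few kernels (one per modality); it is not tuned
  for large kernel dictionaries.
- Structural feature extraction (cortical thickness, gray-matter
  probability) is upstream; such modalities enter as precomputed tables.
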