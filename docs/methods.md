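# Methods

This note records the models, conventions and design choices behind
`radstrat`, in the order data flows through the package.

## Synthetic cohorts

The generator's job is to reproduce the *statistical structure* a
radiomics risk-stratification study assumes, not prostate anatomy.

**Texture fields.** Each modality image is a stationary Gaussian random
field: white noise is filtered in the frequency domain with a Gaussian
spectral envelope `exp(−2(πℓ)²‖f‖²)` of correlation length ℓ (pixels),
affine-scaled to a target mean and sd, clipped at zero and rounded to
integer gray values. The single correlation-length knob moves all four
feature families (histogram shape, co-occurrence statistics, difference
distribution, radial spectrum) smoothly, which is why this construction
was chosen over e.g. patterned or lesion-like simulators. Integer
rounding makes the 16-bit PNG on-disk representation lossless.

**Masks** are axis-aligned ellipses with half-axes drawn uniformly from
0.5–0.9 of the image half-size, so masked-GLCM pair counting and the
mask bounding-box FFT path are genuinely exercised (a rectangle would
make the mask logic trivial).

**Class contrast.** Defaults (arbitrary scanner units): T2W-like
lower-risk mean 420 / sd 60 / ℓ 2.0 px, high-risk ℓ 3.0 px (coarser
texture); ADC-like lower-risk mean 1300 / sd 150 / ℓ 3.0, high-risk mean
1180 (echoing the association of restricted diffusion with aggressive
disease; the numbers sit in the range of typical prostate ADC values in
10⁻⁶ mm²/s). A dimensionless `effect_size` interpolates the high-risk
parameters between the lower-risk values (effect 0: classes identical in
law) and the stated contrast (effect 1, the default "moderate" setting).
Per-patient jitter — mean intensity × N(1, 0.08²), correlation length ×
exp(N(0, 0.15²)) — keeps within-class variability realistic; without it
any nonzero contrast is perfectly separable. With these defaults the
downstream validation AUC lands around 0.9, comparable to a
well-performing real study, while effect 0 gives chance performance.

**Reader scores.** The ordinal 1–5 score is a rounded, clipped latent
Gaussian: class mean 4.3 (high) / 3.3 (lower) plus N(0, sd²) noise,
sd 0.8 by default — chosen so class-mean scores and their spread echo
typical reported reader-score summaries, and so the score is informative
but imperfect (AUC ≈ 0.8). As sd → ∞ the score decouples from the label.

**Seeding.** One cohort seed expands into per-patient substreams via a
counter scheme (`SeedSequence(seed, spawn_key=(patient, stream))` with
streams for T2W, ADC, reader score and parameter jitter), so extending a
cohort never perturbs earlier patients and every pixel is reproducible.

**Feature-space shortcut.** For classifier-level experiments,
`generate_feature_table` draws the 110 features directly from a
correlated Gaussian (AR(1) cross-correlation, ρ = 0.3) with a class mean
shift of `effect_size` within-class sds on the first `n_informative`
columns. `generate_xor_table` instead plants interaction-only signal:
XOR quadrant patterns in latent coordinate pairs embedded in *randomly
rotated* 2D subspaces of the feature space. The rotation matters: with
axis-aligned pairs a random forest can reach the signal through
successive axis splits, whereas after rotation no single feature or
axis-aligned split is informative, while dot-product (polynomial)
kernels — rotation-invariant by construction — are unaffected. This
makes the XOR condition a clean probe of kernel capacity.

What the generator does **not** emulate: anatomy, 3D structure, scanner
and protocol variability, feature non-normality and heavy tails,
multi-reader disagreement. Passing tests therefore demonstrate that the
*machinery* is correct and well-calibrated, not that the specific
classifier would perform comparably on real images.

## Texture features

Gray levels come from linear min–max quantization over in-mask
intensities (max maps to the top bin; a constant image maps to bin 0):
64 levels for histogram entropy/uniformity, 32 for GLCM/GLDM, both
config-overridable — common radiomics practice, and small enough for
stable matrices on small ROIs. Offsets are distance 1 at 0°/45°/90°/135°
(row-major (dy, dx), top-left origin). GLCM features are computed per
offset and averaged over the four directions (rotation-robust Haralick
convention); GLDM difference distributions are averaged before their
summary features are taken. Both pixels of a pair must be in-mask.

The 55-per-modality manifest (15 histogram + 20 GLCM + 8 GLDM + 12 FFT)
is a canonical, frozen set assembled from the standard feature
catalogues of each family; it preserves the four-family structure and
the 55/110 totals. The 12 spectral features are: total non-DC power,
spectral entropy, four radial band-energy fractions, dominant and mean
radial frequency, radial-frequency sd, spectral flatness, 45°-sector
anisotropy, and the low/high power ratio at the half-Nyquist split.
The FFT operates on the mask bounding box with out-of-mask pixels
replaced by the in-mask mean (mean-fill rather than zero-fill, to keep
mask-edge leakage from dominating the spectrum).

Degenerate-value conventions, all tested: skewness, kurtosis, GLCM
correlation are 0 when the relevant variance is 0; every spectral
feature is 0 for a constant image; homogeneity and inverse-difference
features take their maximum 1 on a constant image; the low/high power
ratio is 0 when the high band is empty. All 110 features are finite on
any valid input, including a 16-pixel mask.

## Learners

The seven algorithms run behind one fit/score contract: standardize
(training rows only; zero-variance features keep scale 1 so the manifest
never shrinks), fit, emit a calibrated high-risk probability. SVMs get a
Platt-style sigmoid calibration fitted on internal 3-fold held-out
decision values; LogReg, LDA and RF are natively probabilistic.
Hyperparameters are frozen defaults (box constraint 1, γ = 1/p, RF 100
trees, L2 LogReg with C = 1, LDA with automatic shrinkage — which also
handles the singular within-class covariance of n < p data).
Polynomial kernels are inhomogeneous, (1 + γu·v)^d, so lower-order terms
are representable; the homogeneous form is available by config.

## Evaluation measures

AUC is the rank statistic (ties 0.5), identical to trapezoidal ROC
integration; both classes' precision/recall/F1 derive from one
binarization (high iff score ≥ t, lower otherwise), so a single
threshold drives the whole confusion table. F is F1. Zero-denominator
conventions: P, R, F are 0 when undefined. The F_max sweep evaluates
every distinct score value plus the endpoints 0 and 1; ties on F break
toward the lowest threshold. A config switch allows an independently
swept lower-class threshold, but the complement rule is the default.

## Cross-validation and selection

Oversampling is applied strictly after the train/test split and only to
training folds: duplicating minority rows before splitting would leak
held-out patients into training as copies, and the leakage-free ordering
is enforced and tested. Fold seeds derive from `base_seed + run`.
Ranking: higher measure → better (lower) rank, ties averaged; every rank
row sums to k(k+1)/2. The Friedman statistic uses the general
tie-corrected form with a χ²(k−1) reference; a fully tied matrix returns
statistic 0, p 1. The Nemenyi constants are the infinite-df studentized
range critical values divided by √2, tabulated for k = 2..20 at
α ∈ {0.05, 0.10} (table variants differ in the third decimal; ours is
cross-checked against a direct studentized-range computation in the
tests). Selection requires membership in the top statistical group of
all seven measures, then lowest grand mean rank; if no algorithm is in
every top group the grand-mean-rank winner is used and flagged in
provenance. The final fit uses the oversampled full development set for
consistency with CV training (raw-set fit available by config).

The Wilcoxon signed-rank comparison (oversampling on vs off, runs
paired) is exact for n ≤ 25 nonzero differences via a sign-assignment
convolution over doubled average ranks — exact enumeration stays correct
under tied ranks — and falls back to the continuity-corrected normal
approximation for larger n.

## Validation benchmarks

The ordinal-score comparator is binarized at > 3 (scores 4–5 = high):
with class-mean scores near 3.3 and 4.3, a ≥ 3 rule would call nearly
every patient high-risk, so > 3 is the sensible reading of a
"threshold of 3"; the raw score serves as the AUC ranking score with
ties credited 0.5. The permutation null permutes labels (class counts
preserved) 100 times around the fixed classifier and threshold; its
"standard error" is sd/√100. Bootstrap comparison: 100 paired resamples
(shared between methods; replicates that lose a class are redrawn, since
AUC is undefined otherwise), then per measure a Friedman test across the
100 blocks with k = 2 methods — retained in Friedman form for continuity
with the candidate ranking; at k = 2 it is the χ² approximation of the
sign test, which the tests verify against the mid-p binomial.

## Problem sizes

Defaults used throughout the package's own experiments: 64 px images,
68/53-patient cohorts, 5 folds × 10 runs, 100 permutation and bootstrap
replicates, 10 seeds for aggregate checks. At these sizes the full
image-to-report chain runs in a few seconds and the complete multi-seed
experiment suite in a few minutes on one CPU.

## Known limitations

* The feature manifest is a canonical stand-in, not a reconstruction of
  any particular study's 55-feature list.
* Whether per-direction GLCM features should be averaged or concatenated
  is a convention; averaging was chosen (rotation robustness) and the
  manifest would change under concatenation.
* Random oversampling interacts weakly with threshold-swept (F_max)
  measures on the Gaussian synthetic family: re-optimizing the threshold
  absorbs most of the decision bias that oversampling corrects, so the
  package's oversampling comparison typically shows small, sign-variable
  R_max differences at n = 68. On real radiomic data the comparison may
  behave differently; the machinery reports whatever the data show.
* Friedman–Nemenyi at k = 2 is a coarse (sign-test-like) comparison;
  a Wilcoxon alternative is available via `wilcoxon_signed_rank`.
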