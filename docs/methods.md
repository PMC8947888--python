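# Methods

This note documents the models, parameter choices and numerical conventions
behind `pneumotex`, and what the synthetic test bed does and does not show.

## Synthetic cohort model

Each image is a 256×256 (minimum) single-channel frame, processed as real
values in [0, 1] and stored as 8-bit PNG. It is composed of:

* two axis-aligned elliptical lung fields (semi-axes 0.14 W × 0.30 H,
  centres at 0.28 W / 0.72 W, 0.52 H) at intensity 0.62 on a 0.30
  background — the bright-lung convention is deliberate for the synthetic
  images; segmentation takes a `polarity` flag for dark-lung (clinical)
  inputs;
* correlated Gaussian texture: white noise smoothed with a Gaussian kernel
  (correlation length 1 px, i.e. an effective ~5 px kernel footprint) and
  rescaled to SD 0.04. This is the simplest stationary texture the wavelet
  features respond to; the correlation length is short enough that
  equalized-image Otsu segmentation stays clean;
* for patient stages, a Poisson number of additive, cosine-tapered circular
  opacities placed uniformly inside the lung fields and clipped at the lung
  boundary. The taper avoids hard discs whose edges would unrealistically
  dominate the finest subbands.

Default stage parameters (configurable, not constants):

| stage  | expected nodules | radius (px) | peak contrast |
|--------|------------------|-------------|---------------|
| normal | 0                | –           | 0             |
| I      | 60               | 2–6         | 0.10          |
| II     | 150              | 2–6         | 0.15          |
| III    | 300              | 2–6         | 0.20          |

Counts and contrast rise monotonically with stage, mimicking the increasing
profusion/density of small shadows across staging grades. No quantitative
calibration to clinical film exists; these are stand-ins chosen so that
stage I is a subtle perturbation and stage III an obvious one.

Determinism: every render is a pure function of (spec, size, seed); cohort
generation derives one 31-bit seed per image from the master seed via
`numpy.random.SeedSequence` and records it in the manifest.

What the generator does **not** emulate: ribs, mediastinum and heart
shadows, inter-patient anatomical variation, acquisition physics (scatter,
detector noise spectra), or the large conglomerate shadows of advanced
disease. Passing tests therefore demonstrate correct and sensitive
*machinery*, not clinical performance; headline clinical metrics from real
cohorts are out of reach by construction.

## Preprocessing and segmentation

"Enhancement" is global histogram equalization (256 bins), rank-preserving,
with constant images passed through unchanged. The Otsu threshold maximizes
between-class variance over 256 histogram bins, using exact per-bin
intensity sums (not bin centres) so it agrees with a brute-force partition
scan; ties break toward the lower threshold for determinism.

Cleanup is the canonical reconstruction pair: opening-by-reconstruction
(disc structuring element, radius 5 px) to remove speckle without rounding
lung outlines, hole filling by reconstruction from the border, then the two
largest 8-connected components. An empty result raises a segmentation
error (e.g. structure-free noise input).

**Feature intensities.** Features are computed by default on the *original*
intensities inside the segmented mask, not on the equalized image.
Equalization maps intensities to global ranks, which is exactly what Otsu
thresholding wants but also renormalizes local texture amplitude: on
equalized images the nodular signal measurably vanishes from the
wavelet-entropy features (near-chance cohort separation), while on original
intensities it is recovered cleanly. `extract_features` exposes
`feature_intensities="enhanced"` for the alternative. Features default to
the masked lung fields; a full-frame mode is available.

## Wavelet-entropy features

8-level 2D DWT with db7. The 1D sequence notation of the feature definition
is mapped to 2D images by one convention: level
*i*'s coefficient sequence {S_ik} is the concatenation of the three detail
orientation subbands of that level (level 1 = finest); the level-N
approximation band belongs to no sequence, so the feature vector has
exactly N = 8 entries. Relative energies are normalized over detail levels
only.

Boundary handling defaults to periodization, which keeps the transform
orthogonal so that detail + approximation energies equal the image energy
(Parseval) to 1e−8 relative — the key internal consistency check. Symmetric
extension is available for visual fidelity. Masked images are cropped to
the mask bounding box and zero-padded (bottom/right) to a multiple of 2^N.

Entropy is in nats, H_i = −p_i ln p_i ∈ [0, 1/e]. The log features use
T_i = ln(max(H_i, 1e−12)); the ε-floor keeps blank levels finite. Note that
ln of a value in (0, 1/e] is ≤ −1, so T is always negative — published
tables showing positive patient-group values must involve an additional
unstated standardization, and no attempt is made to match them numerically.

## Feature selection

C5.0 is proprietary; the implemented tree is the C4.5-style core that
feature *selection* actually needs: binary splits on continuous attributes
at midpoints between consecutive sorted distinct values, scored by gain
ratio (bits) among splits with positive information gain, smallest
threshold and lowest feature index on ties. Stopping: purity, min leaf
size 2, max depth 10, min gain 1e−6 bits. No pruning by default — pruning
only shrinks the branch set, and the selection result is precisely the set
of features appearing at internal nodes. A leaf-only tree yields an empty
selection with a warning; the pipeline then falls back to the full set.

## SVM and calibration

The soft-margin dual is solved by most-violating-pair SMO with analytic
two-variable updates, a 1e−3 KKT-gap stopping tolerance, and fully
deterministic working-set selection (first index on ties); on 6-point toys
it matches a brute-force QP solver to 1e−4 in dual objective. The box
constraint defaults to C = 1.0 (configurable); kernel defaults are q = 3
and σ² = 0.1.

Features are standardized to train-fold mean/SD inside `fit` — a fixed
Gaussian width is meaningless without a fixed feature scale — and the
standardization constants are part of the serialized model.

Raw decision values are unbounded, so a Platt sigmoid
P = 1/(1 + exp(A·f + B)) is fitted on the training decision values by a
damped Newton iteration (the numerically stable Lin–Lin–Weng formulation)
to produce the score C ∈ (0, 1); C ≥ 0.5 is called "patient". On training
sets the classifier separates, A < 0 and the calibrated score is strictly
increasing in the decision value.

## Evaluation protocol

Stratified 5-fold CV: seeded within-class shuffle, round-robin assignment
(per-fold class counts differ by ≤ 1), per-fold retraining including
standardization, pooled held-out scores in original sample order. Metrics
come from the pooled 2×2 table at threshold 0.5; the ROC is a descending
threshold sweep whose trapezoidal area equals the Mann–Whitney concordance
probability (tie credit ½). One seeded fold assignment is reused across the
kernel × feature-set grid so rows are comparable. The decision tree is fit
once on the full table before CV (matching the single published tree); a
leakage-free per-fold selection variant is available via
`GainRatioTreeSelector` inside an sklearn `Pipeline`.

A textual inconsistency in the source protocol (folds of "7 normal + 5
patient" cannot tile a 60 + 60 cohort) is resolved in favour of general
stratified k-fold.

## Agreement statistics

Staging tables use the ordered categories {I, II, III, ND}; undetermined
(ND) is a first-class category by default because real modalities produce
no-calls, with an `nd_mode="exclude"` variant. Kappa bands: ≤ 0.4 poor,
(0.4, 0.6] general, (0.6, 0.8] high, > 0.8 good (boundaries in the lower
band). Detection rate counts ND and misstaging as failures. The paired
modality comparison is the exact McNemar test — a two-sided binomial test
on discordant pairs at rate ½ (p = 1 with no discordant pairs); with 6
one-sided discordant pairs it gives p = 2·(½)⁶ = 0.03125. Pearson
chi-square (df = 1, no continuity correction) is provided separately for
2×2 count tables. The published DR-vs-CT cross-table is not fully
machine-readable from its marginals, which do not reconcile exactly across
sections; the reference table used in `scripts/acceptance.py` reproduces
the printed concordant counts and detection rates, and its kappa (0.749) is
reported as computed, not fitted to the published 0.737.

## Problem sizes and numerical conventions

The recovery analyses use 60 + 60 cohorts (strong stage-III signal) over 5
seeds for accuracy/AUC medians, a 120-sample label-permutation null judged
against the ±3σ binomial band around 0.5, and 10 seeded 15 + 15 cohorts for
selection retention; unit tests use smaller cohorts. These sizes mirror the
study cohort while keeping the full suite fast and deterministic.

Degenerate inputs raise explicit errors rather than returning sentinels:
constant images (Otsu), blank images (relative energies), empty masks,
single-class training sets, classes smaller than k, degenerate kappa
margins, zero chi-square marginals.

## Known limitations

* Synthetic anatomy is schematic; no claim of clinical transfer.
* The stage-I default signal is subtle enough that a mixed-stage
  (40/12/8) cohort is *not* near-perfectly separable — intentionally so;
  the strong-signal cohort is the recovery benchmark.
* Cohort-level feature extraction is serial; no parallelism beyond
  determinism guarantees.
* Weighted kappa, kappa confidence intervals and DeLong AUC intervals are
  out of scope.
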