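# Methods

This note documents the models and numerical choices behind mammocad: what
each stage assumes, which parameters matter, what the phantom generator does
and does not emulate, and where the design was genuinely open.

## Intensity polarity and the threshold recursion

The whole package fixes one polarity convention: **lesions are brighter than
the background**, as in processed, display-oriented FFDM. The topographic
grower's threshold recursion, however, is naturally stated for
*low-intensity* lesion cores (raw-detector polarity, where dense tissue
absorbs photons and reads dark): there the first threshold
`T1 = I_seed + α·I_seed` sits just above the darkest core value, the region
contrast `C` (boundary minus interior) is positive, and `T_j = T_{j-1} + β·C`
raises the threshold so the region grows outward. Run literally on
bright-lesion display units this recursion is degenerate: `T1 = 1.1·I_seed`
exceeds every pixel near the seed, the first layer collapses to a singleton
whose contrast is 0 by convention, and the threshold can never move.

`segment_image` therefore evaluates the recursion in inverted intensity
space `I' = M − I` and maps back. The update `T_j = T_{j-1} + β·C_{j-1}` is
form-invariant under the inversion (both the threshold and the contrast flip
sign), so only the first threshold changes shape:
`T1 = I_seed − α·(M − I_seed)`. The reference `M` places the seed's inverted
value at its *prominence* over the background (the global median), so the
first threshold descends by α times the seed prominence — the direct
analogue of "10% of the seed value" in raw units, without tying the step to
an arbitrary detector offset. The standalone `first_threshold` and
`next_threshold` functions keep their literal contracts.

## Segmentation: parameters and robustness rules

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.1 | first-threshold step as a fraction of seed prominence |
| `beta` | 0.5 | threshold step per layer, in units of layer contrast |
| `size_growth_limit` | 2.0 | stop when a layer more than triples the area |
| `circularity_reduction_limit` | 0.5 | stop when circularity halves |
| `connectivity` | 8 | pixel adjacency for components (4 configurable) |
| `max_layers` | 20 | hard iteration cap |
| `seed_window` | 3 px | half-width for the robust seed intensity (max) |
| `min_region_size` | 300 px | defer termination ratios below this area |
| `max_region_fraction` | 0.5 | flood guard: a layer this large is a size violation |

Circularity `V` is the fraction of the region covered by the equal-area disk
centred at the region centroid — bounded in (0, 1], robust to perimeter
pixelation (unlike `4πA/P²`), and 1 for a centred disk up to rasterisation.

Three totality/robustness rules extend the two published termination
ratios, all documented and configurable:

- **Layer 1 is accepted unconditionally** (it has no predecessor); the
  ratios are evaluated from layer 2 on, and on the first violation the
  previous layer is the final region. If the violation happens at layer 2
  while layer 1 is a singleton, the final mask is that singleton and the
  result is flagged (`singleton_fallback`) so callers can reject it.
- **Ratios are deferred below `min_region_size`.** On noisy images the
  first layers are noise islands of a few dozen pixels; an area ratio on
  such regions is statistically meaningless and falsely triggers the size
  rule during island merging. 300 px is half the area of the smallest
  plausible mass at this pixel scale (~3.5 mm radius at 0.35 mm/pixel).
- **Flood guard.** On texture-free backgrounds a leaked region can expand
  with a per-layer ratio just under 2.0 and swallow the patch without ever
  violating a rule (real parenchymal structure would break circularity
  first). A layer exceeding half the growable area counts as a size
  violation.
- **No-growth** (layer identical to its predecessor) and **max-layers**
  terminations make the iteration total.

Zero-padded pixels are excluded from growth. The grower starts from the
brightest pixel inside the seed window, so the first layer reliably contains
the lesion core even when the marked centre pixel itself sits marginally
below `T1`.

## Phantom generator

Each phantom is a 150×150 16-bit patch: correlated Gaussian background
clutter (white noise low-passed at `background_correlation_sigma = 3` px,
rescaled to `background_noise_sd = 300` around `background_mean = 8000`)
plus a bright lesion of core contrast 1200–3200 and radius 12–30 px. The
lesion profile is a **parabolic dome** (peak 1 at the centre falling to
`1 − core_taper` at the core edge, `core_taper = 0.25`) with a narrow
raised-cosine skirt (width 0.15·R) and Gaussian margin blur (σ 0.5–2.5 px,
"solid" to "diffuse" margins). The dome matters: a perfectly flat-topped
lesion makes threshold descent cross the entire core in one noise-dominated
step, which no layered grower can track; a radial intensity gradient is
also what real masses have. Benign lesions are near-elliptical
(elongation 1.0–1.3) with mild boundary perturbation (3%); malignant
lesions carry a star-shaped radius perturbation (25%, random harmonics)
plus 4–10 thin radial spicules of decaying contrast. The truth mask is the
set of pixels where the noiseless (blurred) profile exceeds half the core
contrast. With probability `edge_case_fraction` (5%) the lesion centre is
placed within one radius of a zero-padded band, emulating patches cut near
the image edge.

What the phantoms do **not** emulate: X-ray physics, anatomic parenchymal
structure (ducts, vessels, overlapping tissue), calcifications, scanner
characteristics. Passing tests on phantoms therefore demonstrates that the
pipeline recovers *constructed* class structure (shape irregularity,
contrast) through segmentation, features and classifiers — not clinical
performance. Segmentation quality on default phantoms (mean Dice ≈ 0.75–0.8
with ~5% poor masks on diffuse lesions) mirrors the failure modes such
growers show on real diffuse masses.

## Radiomics battery

~50 named features in four groups, fixed order, versioned schema ("1.0"):

- **morphology** (12): area, perimeter, circularity, eccentricity,
  compactness, extent, convexity, equivalent diameter, and
  centroid-to-boundary radial statistics (mean, SD, max, CV — the CV is the
  spiculation proxy);
- **density** (10): interior mean/SD/skewness/kurtosis, histogram entropy,
  10th/90th percentiles, IQR, boundary contrast against a 5-px outer band
  (≈1.75 mm), band SD;
- **texture** (10): symmetric normalised GLCMs at offsets
  {(0,1),(1,0),(1,1),(1,−1)}, 32 grey levels quantised over the mask
  bounding box, distances 1 and 3; energy, contrast, correlation
  (0 for degenerate regions), homogeneity, entropy averaged over offsets;
- **wavelet** (14): Daubechies-4, 2 levels, periodised mode (so subband
  energies satisfy Parseval exactly); per-subband energy fraction and
  coefficient entropy, computed on the whole ROI (configurable).

Non-finite values are imputed with 0 and logged. The documented
translation-sensitive set (interior mean, percentiles, wavelet energy
fractions, approximation entropy) is asserted by a property test; all other
features are invariant to adding a constant. Offset-averaged GLCM, density
and morphology features are mirror-invariant; wavelet subbands are
orientation-sensitive by construction.

## Classifiers

**Model-I.** Per CV fold: z-score standardisation (zero-variance features
dropped), full-SVD PCA keeping the minimal leading components with
cumulative explained variance ≥ 0.95, a polynomial-kernel SVM (degree 3,
C = 1, coef0 = 1, scaled gamma), and a sigmoid (Platt-style) calibration of
the SVM margin fitted on the training folds — test folds never touch any
fitting step. Folds are label-stratified by default (the plain random split
is a toggle). Because the kernel depends only on inner products and gamma
rescales with the component variance, duplicating feature columns leaves CV
scores unchanged — a regression test for redundancy absorption.

**Model-II.** The finetuning protocol is backbone-agnostic; the shipped
surrogate is a numpy CNN (fixed 8× stem average-pool to 28×28, two 3×3
conv+ReLU stages of width 8/16, global average pooling, 2-way softmax
head). Desk-scale training differs from a full-scale run in one structural
way: with ~100 optimiser steps per fold and the conservative schedule
(1e-4 decayed ×0.4 per epoch), total parameter movement is ~2e-3, so the
head carries a fixed logit gain (300) and starts at zero (untrained output
exactly (0.5, 0.5)), and the pooled features pass through mean-only batch
normalisation with a running mean at inference — without centring, Adam's
equalised per-coordinate speeds generate a common-mode logit offset that
the single bias coordinate cannot cancel. Two further robustness choices:
initial conv filters are sign-flipped to positive weight sums (on strictly
positive inputs a negative-sum filter starts dead behind its ReLU and,
with this little training, stays dead — an unlucky fold init can otherwise
kill most of the feature channels), and after each epoch the normalisation
mean is recalibrated over the unaugmented training set, since the EMA over
augmented batches is systematically offset from clean inputs. Gradients
are verified against finite differences. Per-patch max normalisation to [0, 1] carries relative
lesion contrast; augmentation (centred crop to 0.9–1.0 of the side, flips
p = 0.5) applies to training batches only; the post-epoch training loss is
logged in evaluation mode.

The surrogate reaches held-out accuracy 1.0 on contrast-coded phantoms but
stays near chance on the default *shape*-coded population — a small
untrained CNN at ~100 steps/fold cannot learn boundary irregularity. That
is the expected desk-scale behaviour: the protocol, not a pretrained
backbone's representational power, is what this module exercises; fusion
results on default phantoms consequently track Model-I.

## Fusion and evaluation

The stacked SVM (Model-III.1) reuses the exact fold assignment that
produced S1 and S2, so no test score leaks into fusion training. The
pointwise fusions satisfy `min ≤ average ≤ max` and reproduce the input
exactly when S1 = S2.

Empirical AUC is the Mann–Whitney statistic (ties half credit) with the
DeLong structural-components variance; paired model comparison uses the
DeLong covariance and a two-sided normal test. The binormal fit bins scores
into 10 pooled-quantile categories (empty bins merged), parametrises
`(a, log b, c_1, log Δc_2..)` for monotone cutpoints, initialises from a
probit-probit regression of the empirical CDFs, optimises with Nelder–Mead
then BFGS, and reports the delta-method SD from a finite-difference observed
information. Perfect separation returns AUC 1.0 with a degeneracy flag.
Simulation at a = b = 1, n = 2000/class recovers both parameters with mean
absolute error ≈ 0.02. Accuracy uses strict `score > threshold` for a
malignant call, so a malignant case at exactly 0.5 counts as an error; both
the pooled accuracy and the per-fold mean ± SD are reported, and the AUC
SD is likewise reported from both estimators, labelled distinctly.

## Problem sizes

Defaults were chosen so a full study runs in minutes on one CPU: the test
suite's end-to-end study uses 200+200 phantoms for the radiomics branch and
60 separable phantoms (k = 3) for the deep branch; `scripts/acceptance.py`
runs 100+100 phantoms through both branches at k = 10, 20 noise-free disk
phantoms for the segmentation Dice, and one binormal simulation of
2000/class. Larger runs only tighten the same statistics.

## Known limitations

- Phantom realism is statistical, not anatomical or physical; absolute
  AUC/ACC values on phantoms do not transfer to clinical data.
- The binormal fit bins continuous scores; with < ~100 samples per class
  the information matrix can be ill-conditioned and the SD falls back to 0
  with a warning.
- The surrogate backbone is deliberately small; plugging in a pretrained
  backbone changes Model-II's capacity but not the protocol code paths.
- Manual mask correction is out of scope; poorly segmented diffuse lesions
  (~5%) stay in the feature set, as flagged singleton/oversized masks.
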