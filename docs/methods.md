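# Methods

This note documents the models behind `curemetrics`, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Study design emulated by the generators

The package targets a refrigerated-storage monitoring protocol for sliced
dry-cured meat: three product types (lamb, beef, buffalo), storage days
1, 4, 8, 11, 14 and 16 after package opening, eight slices photographed
per type and day, eight ROIs per slice (so 64 ROI observations per class),
ATR-FTIR spectra at 4 cm⁻¹ resolution over 4000–500 cm⁻¹, and replicate
physicochemical/microbiological assays per day.  These counts are the
generator defaults; they are ordinary parameters and can be changed.

## Synthetic slice images

Colour is synthesised in CIELAB and converted to 8-bit sRGB (D65, 2°
observer, via scikit-image); the imaging module converts back with the
same chain, so the colour features have closed-form expectations.  The
Lab pixel field on storage day *d* is

    L(x) = L0 + marbling(x) + speckle(x) + ε_L(x)
    a(x) = a0 + fade_a · (d − 1) + ε_a(x)
    b(x) = b0 + fade_b · (d − 1) + ε_b(x)

* `base_lab` default (42, 25, 9.3): a dark red cured-meat surface with a
  hue angle near 20°.
* `fade_rates` default (−0.5, −0.35) Lab/day: the slice becomes less red
  and less yellow over storage; over 15 days this moves a\* by −7.5 and
  b\* by −5.25, comfortably inside the sRGB gamut (validated at profile
  construction; generation rejects any image where more than
  `max_clip_fraction` = 1% of pixels clip at the gamut boundary).
* marbling: white noise low-pass filtered at `marbling_scale` = 24 px and
  thresholded at zero into ±`marbling_amplitude`/2 (default 5 L\* units) —
  a two-level fat-streak field that gives day-independent coarse texture.
* speckle: per-pixel Gaussian noise with amplitude
  `fragmentation_rate` · (d−1) (default 0.4 L\*/day).  This is the
  fragmentation mechanism: co-occurrence contrast and dissimilarity grow
  with day while homogeneity and ASM fall, the direction of effect the
  analysis is designed to detect.
* `noise_sd` = 0.8 adds camera noise on all three channels.

Determinism: each image's RNG is seeded by (seed, day, slice index), so a
single slice can be regenerated without generating the whole dataset.

What the generator does **not** emulate: illumination gradients, specular
highlights, the coating paste at slice borders, camera optics, or any
photometric miscalibration.  Passing the discrimination tests on these
images shows the pipeline recovers the monotone colour/texture drift it
encodes — not that real photographs of any particular product are
classifiable at the same accuracy.

## Image features

Grayscale is BT.601 luma rounded to integers; quantisation is
`floor(raw·G/256)` with G = 32 levels.  Co-occurrence matrices
(scikit-image accumulation) use distance 1, the four standard angles,
symmetric counting, per-angle normalisation; features are averaged over
angles.  Energy is defined as the square root of the angle-averaged ASM so
that energy² = ASM holds for the reported vector.  Correlation of a
constant field is defined as 1.  Run-length matrices count maximal
equal-level runs along the four directions; the five run features are
averaged over directions.  Two of the fifteen grayscale features in the
18-feature descriptor are not uniquely fixed by the monitoring protocol;
co-occurrence entropy (base 2) and correlation were chosen as the standard
companions of the Haralick set, and the feature list is a plain tuple
(`FEATURE_NAMES`) that downstream code treats as configuration.

ROI placement defaults to a deterministic grid (rows = ⌊√n⌋) inside the
central 80% of the frame; a seeded non-overlapping random strategy is
available.  Coordinates are 0-based and half-open throughout.

## Discrimination pipeline

For a candidate feature subset the pipeline is: z-score (population SD) →
PCA to two components on the covariance of the z-scored data (equivalently
correlation PCA; loading signs fixed so each component's largest-magnitude
entry is positive; a single-feature subset gets a zero second component) →
classifier on the 2-D scores.  Leave-one-out evaluation refits all three
stages on the training observations of every fold; the training-side
parameters are computed from masked training rows only, so an arbitrarily
spiked held-out value cannot change them even at the last bit.

The exhaustive subset search enumerates every subset of size 1..cap in
(size, lexicographic) order and keeps the first maximiser of LOO accuracy,
which implements the tie-break "smaller subset, then lexicographic".

The classifier registry holds nearest centroid, k-nearest-neighbour and
linear discriminant (scikit-learn estimators) and a native depth-limited
Gini CART.  The CART is implemented in this package (numba-compiled)
because the exhaustive search performs ~1.6 million tiny tree fits
(12 615 subsets × 128 folds at the default cap of 5 over 18 features) and
a general-purpose estimator's per-call overhead dominates at that scale;
its split search is the textbook exhaustive scan with deterministic
tie-breaking (first feature, lowest threshold), and the test suite checks
it against scikit-learn's tree.  Further classifiers can be added with
`register_classifier`.

## Storage-day regression

Gradient boosting for squared error, implemented as the classical
stagewise algorithm: F₀ is the training mean and each of M trees (depth 2,
shrinkage ν) is fitted to the current residuals.  Defaults M = 300,
ν = 0.1, depth 2 — standard small-data settings; the training loss is
non-increasing in M by construction.  Evaluation is seeded, shuffled
K-fold (default K = 5) with per-fold held-out R² = 1 − SS_res/SS_tot.  The
`drift_feature_table` benchmark (three features moving linearly over six
days with noise at 0.1% of each feature's range, 64 observations per day)
is the regime in which the regressor attains mean R² ≥ 0.999; real feature
tables are noisier and should not be expected to reach that ceiling.

## Amide-I deconvolution

Processing chain: optional ATR correction A′(ν) = A(ν)·ν/ν_ref
(ν_ref = 3284.77 cm⁻¹); extract 1600–1700 cm⁻¹ (closed interval);
nine-point, third-order Savitzky–Golay smoothing; two-endpoint linear
baseline subtraction; Savitzky–Golay second derivative; band centres =
second-derivative minima above a prominence threshold.

Numerical choices, each made after measuring the alternative on the
forward model:

* **Smoothing is used for peak picking only.**  At 4 cm⁻¹ sampling the
  nine-point window spans 32 cm⁻¹ and visibly distorts σ = 6 cm⁻¹ bands;
  fitting the smoothed trace biases recovered areas by several percentage
  points, so the Gaussian fit runs on the unsmoothed, baseline-corrected
  region.
* **Reference band positions.**  The five amide-I sub-bands overlap within
  their widths, so second-derivative minima resolve at most three or four
  of them and are displaced by up to ~5 cm⁻¹; a weak α-helix shoulder
  beside a strong β-turn band is invisible at any grid step.  Following
  standard amide-I practice, `deconvolve_amide` fits one component per
  assignment window, seeded at a configurable literature position
  (defaults 1625, 1645, 1656, 1670, 1690 cm⁻¹ — the midpoints of the
  assignment windows) when the window's pick is missing or displaced;
  passing `reference_centers=None` fits the picked centres alone, which is
  appropriate for well-separated bands.
* **Constraints.**  Centres are bounded to ±2 cm⁻¹ of their initial
  values, widths to σ ∈ [2, 20] cm⁻¹, amplitudes to ≥ 0.  Amplitudes are
  initialised by non-negative linear least squares at the initial centres
  (they enter the model linearly), which removes the local minima in which
  the overlapped 1645/1656 pair otherwise trades mass.
* **Joint linear baseline.**  The two-endpoint chord clips the tail of the
  1690 cm⁻¹ band at the region edge; a linear baseline fitted jointly with
  the components absorbs that bias, and the fitted (slope, intercept) is
  reported with the fit.
* **Shared width.**  `deconvolve_amide` defaults to one σ shared by all
  components.  With per-component widths the noisy-recovery error of the
  random-coil/α-helix pair is 3–4 percentage points (residuals below the
  noise floor — estimator variance, not optimisation failure); a shared
  width reduces it to ~0.2 points.  `fit_gaussians` keeps per-component σ
  as its default for callers who need independent widths.

Structure percentages are areas (amplitude·σ·√(2π)) summed per assignment
window and normalised to 100; components sharing a window are pooled.  The
assignment windows are configurable; the defaults (β-parallel [1600,1640),
random coil [1640,1650), α-helix [1650,1662), β-turn [1662,1682),
β-antiparallel [1682,1700]) follow common literature assignments, and
published percentage rows that sum to 100 ± 0.01 due to printed rounding
are renormalised exactly by the spectrum generator.

## Statistics

Two-sided p-values throughout.  Mann–Whitney uses midranks for ties; the
exact permutation distribution is used for N ≤ 20 without ties and the
tie-corrected, continuity-corrected normal approximation otherwise (both
via scipy).  Tukey HSD uses the Tukey–Kramer statistic
q = |mean_i − mean_j| / √(MS_within·(1/n_i + 1/n_j)/2) with p-values from
scipy's studentized-range distribution (numerical integration; agreement
with `scipy.stats.tukey_hsd` is asserted to 1e-9 in the tests).  The
compact letter display uses the insert-and-absorb algorithm processed in
group-label order, so two groups share a letter exactly when they are not
significantly different.

## Assay generator

Each analyte draws replicates from Normal(mean_d, sd_d) with either a
linear drift mean or an explicit per-day mean series; packaged presets
carry published storage series for moisture, hue angle, firmness and TBARS
of the three product types, plus microbial counts parameterised at
~10⁴ cfu/g initial APC/LAB declining slowly and yeasts one log lower and
stable.  Values are clipped to physical ranges (moisture ∈ [0,100],
a_w ∈ [0,1], log counts ≥ 0); with the preset noise levels clipping is a
null operation.  The generator draws replicates independently — it does
not model within-slice correlation, batch effects or non-normal tails.

## Problem sizes

The test suite runs the exhaustive subset search once at its full size
(two classes × 64 ROI vectors, cap 5, 12 615 subsets), the deconvolution
round trip at 6 noiseless + 50 noisy fits, the texture oracles on 200
random 8×8/16×16 images, and the Tukey letter simulation at 100
replicates; these sizes were chosen so each property is measured at the
scale of the emulated study design.

## Known limitations

* The imaging model has no slice segmentation; ROIs are placed relative to
  the frame, which assumes roughly centred slices.
* The ±2 cm⁻¹ centre constraint means bands whose true positions deviate
  more than 2 cm⁻¹ from the configured references are recovered at the
  boundary; widen the references or the window for unusual samples.
* The normal approximation of the Mann–Whitney test is first-order; for
  heavily tied tiny samples prefer the exact mode without ties.
* JCAMP-DX support covers plain AFFN `(X++(Y..Y))` blocks only (no
  compression formats).
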