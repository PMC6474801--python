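# Methods

This note documents the models and procedures implemented in `tagbright`,
the parameters that matter, the design choices made where the underlying
procedure was under-specified, and what the synthetic-data generator does
and does not emulate.

## Segmentation quantifier (`segment`)

The labeling-intensity quantifier maps "the signal structure" (the
subapical aPKC band of an egg chamber, or any bright blob/band) and
reports background-corrected intensity:

1. **Difference of Gaussians.** `DoG(I) = G(σ)∗I − G(kσ)∗I` with unit-sum
   kernels and reflection boundaries, defaults σ = 4 px, k = 1.4. The DC
   component cancels exactly, so adding a constant to the image never
   changes the mask. The sign convention is fine-minus-coarse: bright
   structures come out positive, and only the positive side is
   thresholded.
2. **Rényi-entropy threshold.** The filtered image is binned into a
   256-bin histogram over its [min, max] (binning is required because the
   filtered image is real-valued; 256 matches 8-bit convention, and makes
   the threshold equivariant under intensity scaling). The default
   `renyi_combined` method computes the entropy-maximising cut for orders
   α = 0.5, the Shannon (Kapur) limit, and α = 2, and blends them with the
   Sahoo–Wilkins–Yeager three-threshold weighting used by the common
   auto-threshold suites; the 5-gray-level proximity tolerance in that
   rule is scaled proportionally for other bin counts. `renyi_single`
   exposes a single arbitrary order. Cut ties break toward the lower bin
   (argmax convention). Foreground class sums are computed as exact suffix
   sums — `1 − cumsum` cancellation at the last cut produced spurious
   infinities. A histogram with fewer than two populated bins raises a
   degenerate-input error; in `quantify_image` a constant image instead
   yields an empty-result flag.
3. **Minimum-area compositing.** Components are 8-connected, the area
   bound is inclusive (a 500-px region survives a 500-px minimum), and
   `area_um2 = area_px·(pixel/1000)²` — 500 px at the 180.2-nm default
   pixel is 16.24 µm².
4. **Measurement.** Signal is the mean of the **original** image over the
   mask, background the mean over its complement (restricted to the user
   region when one is given), corrected their difference. Measuring on the
   raw rather than the DoG-filtered image is an explicit interpretation,
   fixed here because corrected intensities must stay in detector units.

A known property of this procedure: the mapped mask carries a skirt of
PSF/DoG-blurred edge pixels around the true structure, so the corrected
signal *underestimates* the structure's plateau intensity (by roughly a
third for the default egg-chamber band geometry). The skirt fraction is
common to both conditions of a comparison, so **fold ratios of corrected
signals are unbiased** — which is what the pipeline is for. Tests
therefore assert ratio recovery, and bound (rather than pin) the absolute
corrected signal.

## Per-cell analyses (`cellquant`)

* **Detection** runs the same DoG + Rényi machinery on the reporter
  channel; each connected component ≥ 50 px (default) is one cell.
  Touching cells merge — there is no watershed splitting, a documented
  limitation; the generator places cells on a jittered grid so merging is
  rare in synthetic fields.
* **Co-labeling** replaces the by-eye "structure visible" criterion with
  `corrected marker mean > k·SD` of the cell-free marker background,
  k = 3 by default. At k = 3 the false-positive rate on label-free cells
  is far below 1% (region means average over hundreds of pixels, so the
  pixel-SD criterion is very conservative). The rule is scale-invariant:
  rescaling the channel rescales corrected means and the SD together.
* **Efficiency** is `100·n_colabeled/n_reporter_positive`.
* **Distribution fits** are maximum-likelihood Gaussians (sample mean/SD)
  scored by R² against a 20-bin density histogram; R² < 0.85 flags the
  single-Gaussian model as inadequate (e.g. for two-population mixtures).
* **Fold ratios** are ratios of group means with a seeded nonparametric
  bootstrap (2000 resamples, percentile 95% CI).
* **t-tests** default to Student's pooled two-tailed test (the common
  "unpaired t-test" default), Welch behind a flag; stars follow
  ns / * / ** / *** / **** at 0.05 / 0.01 / 0.001 / 0.0001. Two
  zero-variance groups with equal means return p = 1 by convention.

## STED time series (`stedts`)

* `sum_frames` **sums** (never averages) non-overlapping blocks of n raw
  frames, drops the trailing partial block, multiplies the frame interval
  by n, and widens the dtype so integer counts cannot clip. Photon counts
  of consumed frames are conserved exactly. The frame interval is always
  user/metadata input, never derived from acquisition descriptions.
* `display_blur` (default 0.5 px) exists for presentation only; nothing
  quantitative runs on blurred data.
* `kymograph` samples a fixed line bilinearly at 1-px steps in every
  frame, averaging across a perpendicular width; columns are time-ordered.
* `intensity_timecourse` reports `mean(ROI) − mean(background)` per frame
  with masks constant over time, then fits
  `I(t) = offset + I₀·2^(−t/t½)` by least squares. Mono-exponential decay
  plus offset is the minimal photobleaching model; the offset absorbs
  residual background. The fit is skipped and flagged when the curve has
  no net decrease (non-negative linear-regression slope), and the
  half-life is bounded positive. Initial intensity is the mean of the
  first n corrected values (default 1).

## Line profiles (`profiles`)

Profiles are bilinear line samples averaged across a width, positions in
nm. Two models, both least-squares with a constant baseline:

* **Single Gaussian** for resolution: `FWHM = 2√(2 ln 2)·σ`,
  initialisation from the max and half-max crossings.
* **Two equal-width Gaussians** for donut-shaped pit cross-sections; the
  fitted `|μ₂ − μ₁|` is reported as the pit diameter. The equal-width
  constraint stabilises fits near the resolution limit. The two-peak model
  is accepted only when *all* of the following hold, otherwise the profile
  is flagged `unresolved` and the single-peak fit returned:
  * ΔAIC ≥ 4 over the single-peak model (avoids rewarding two peaks for
    merely out-wiggling noise — the double model nests the single one);
  * separation > 2σ of the fitted components (the Sparrow limit: below
    it two equal Gaussians produce no central dip, so "two peaks" is not
    an observable claim);
  * lobe amplitudes within a factor ~3 of each other (a centre-crossing
    donut profile has comparable lobes; a strongly lopsided pair is a
    neighbouring structure);
  * double-model R² ≥ 0.5 (a diameter is only reported when the model
    actually describes the data).

## Photophysics (`photophys`)

Pure Beer–Lambert arithmetic, `A = ε·c·l`, with a 1-cm default path
(standard cuvette). Concentration and extinction are exact algebraic
inverses of each other. The saturation check accepts when the 6-equivalent
absorbance is within 5% (default) of the 3-equivalent one. Brightness is
ε·Φ; quantum yields are always external inputs — the package hard-codes
none, so a brightness fold is only computed when both Φ values are
supplied, while the ε fold is always available.

## Synthetic scenes (`synmicro`)

The generator renders a noiseless structural image of piecewise-constant
plateaus (so interior means equal configured intensities exactly),
convolves it with an isotropic Gaussian PSF (confocal default 250 nm FWHM,
STED default 60 nm), and applies detector noise:
`Poisson(photon_scale·(I + background))/photon_scale + N(0, read_sigma)`,
clipped at zero. Defaults: photon_scale 1 e⁻/count, background 10 counts,
read noise 2 counts, base marker intensity 100 counts — a
moderate-SNR confocal regime. All randomness flows from the config seed;
identical configs are bit-identical. Poisson means above 10⁶ electrons use
the Gaussian limit (indistinguishable at float precision), which is also
how the "no-noise" fixture (`NO_NOISE`, photon_scale 10⁹) works — tests
treat it as the large-photon limit, not literal zero noise.

Scene geometries (parametric, chosen for controllable summary statistics,
not anatomical realism):

* **hela_field** — cells on a jittered grid (~10 µm diameter); a
  transfected subset carries 1–3 overlapping plateau disks (Golgi) in the
  reporter channel; a configurable fraction of those also carries marker
  signal. Per-cell expression is Gaussian (CV 25%) and shared between
  channels, giving the Gaussian per-cell intensity distributions the
  per-cell analyses assume. The labeled subset is realised
  deterministically as `round(fraction·n_transfected)` per field, so the
  configured fraction is the ground truth up to rounding.
* **egg_chamber** — an elliptical follicle epithelium with a dim
  cytoplasmic annulus (12% of base) and a ~1-µm bright subapical band at
  its inner rim. The confocal pixel defaults to 180.2 nm, the size at
  which the 500-px minimum area equals 16.24 µm².
* **clathrin_field** — sparse ring-profile pits (Gaussian radial
  cross-section, 8 nm SD rim). `ring_diameter_nm` is defined as the
  **apparent** donut diameter — the peak-to-peak distance the rendered pit
  shows under the scene's PSF. A Gaussian PSF pulls the intensity peaks of
  a curved rim inward (for a thin ring the image maximum sits at the root
  of `r = R·I₁(rR/σ²)/I₀(rR/σ²)`, well inside R when σ ≈ R/2), so a
  literal 100-nm rim imaged at 60-nm FWHM would *show* only ≈ 85 nm peak
  to peak. Since reported pit diameters in STED images are the observed
  donut diameters, the generator inverts the ring⊗PSF model to find the
  underlying rim radius (recorded in the ground truth as `rim_radius_nm`)
  and renders that. Re-rendering the same rim under a 250-nm confocal PSF
  produces the expected unresolvable blurry spot. Pits keep a
  diffraction-scale margin (≥ 400 nm) from the frame edge so confocal
  re-renders stay in frame.
* **sted_timeseries** — a static structure (Golgi-like plateau blobs, or a
  ~300-nm subapical band arc for egg-chamber fields at 19.53-nm pixels)
  whose intensity decays as `2^(−t/t½)` with independent per-frame noise.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the analyses rely on — plateau structures under a
Gaussian PSF, Poisson+read noise, Gaussian per-cell brightness variation,
exponential bleaching — so recovery tests validate the *estimators*:
segmentation bias cancellation in ratios, classifier operating point,
fit identifiability. It does not model autofluorescence, depth-dependent
scattering, vectorial/aberrated PSFs, cell-shape variability, touching
cells, drift, or non-exponential (multi-component) bleaching, so passing
tests do not certify performance on real tissue in those regimes.

## Problem sizes and runtime

The default test and reproduction runs use: 12 egg-chamber images per
condition (256²), ~300 HeLa cells per condition (448² fields, ~15
reporter-positive cells each), 740 cells for the efficiency run, 4
bleaching movies per condition (256², 64 frames, 4-frame sums) for the
initial-intensity comparison, 4 + 6 egg-chamber STED series (512², 20
frames, 5-frame sums), and a 4-pit clathrin field (256² at 10-nm pixels).
These sizes put every stochastic recovery comfortably inside its
tolerance while keeping a full reproduction run under a minute on one
core; all are configurable.

## Known limitations

* No watershed splitting of touching cells; merged cells count once.
* The segmentation mask's blur skirt biases absolute corrected signals
  low (ratios are unaffected); absolute intensities should be read as
  lower bounds.
* The donut fit reports the apparent peak-to-peak diameter; it does not
  deconvolve rim curvature for arbitrary unknown PSFs.
* The bleach model is strictly mono-exponential with a constant offset.
* Interactive region drawing is out of scope; regions are accepted as
  mask files/arrays only.
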