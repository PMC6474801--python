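# tagbright

Quantification pipeline for comparing the brightness of **HaloTag** and
**SNAP-tag** fluorescence labeling in confocal and STED microscopy, with a
seeded synthetic-microscopy generator so that every analysis stage is fully
testable without microscope data.

## The problem

HaloTag and SNAP-tag are self-labeling proteins: expressed as fusions, they
covalently capture chloroalkane (CA) and benzylguanine (BG) substrates
carrying an organic fluorophore. With far-red rhodamines (SiR, JF646) the
same dye can appear several-fold brighter on a Halo fusion than on a SNAP
fusion — a difference that directly limits how long a live-cell STED movie
stays above background. Demonstrating and quantifying that difference takes
a chain of image analyses, which this package implements as a reusable
library plus a `tagbright` command-line tool:

* **segment** — the egg-chamber labeling-intensity quantifier: a
  difference-of-Gaussians band-pass (`G(σ) − G(kσ)`, default σ = 4 px,
  k = 1.4), an automatic threshold by Rényi-entropy histogram analysis
  (`H_α = (1−α)⁻¹ ln Σ (p_i/P)^α` summed over the background/foreground
  split, with the α = 0.5 / Shannon / α = 2 three-threshold combination),
  a composite of all 8-connected regions ≥ 500 px, and signal/background
  means measured on the *original* image
  (`corrected = mean_in − mean_out`).
* **cellquant** — per-cell analyses in two-channel fields: reporter-positive
  cell detection, co-labeling classification
  (`corrected marker mean > k·SD_background`, k = 3), labeling efficiency
  (% of reporter-positive cells co-labeled), Gaussian intensity-distribution
  fits, Halo:SNAP fold ratios (`mean_a/mean_b` with bootstrap 95% CI), and
  two-tailed unpaired t-tests with significance stars.
* **stedts** — STED time series: summation of n raw frames per image
  (photon-conserving), 0.5-px display blur (display only), kymographs,
  background-corrected intensity-vs-time curves fitted with
  `I(t) = offset + I₀·2^(−t/t½)`, and initial-intensity estimates.
* **profiles** — line profiles with Gaussian FWHM fits
  (`FWHM = 2√(2 ln 2)·σ`) for resolution, and two-equal-width-Gaussian
  donut fits whose peak separation is the clathrin-pit diameter, with an
  information-criterion fallback that flags unresolved (confocal-like) pits.
* **photophys** — Beer–Lambert arithmetic (`A = ε·c·l`): stock
  concentrations, conjugate extinction coefficients, labeling-saturation
  checks, and ε/brightness (ε·Φ) fold ratios.
* **synmicro** — the synthetic generator: HeLa fields with a transfected,
  partially dye-labeled subset, *Drosophila* egg-chamber epithelia with a
  bright subapical band, clathrin-pit rings near the resolution limit, and
  bleaching STED series — all rendered through a Gaussian PSF with Poisson
  shot noise, constant background and Gaussian read noise, and returned
  with exact ground truth.

## Worked example

Compare egg-chamber labeling intensity for a condition pair whose
ground-truth Halo:SNAP brightness ratio is 4.5, using 12 images per
condition:

```python
from tagbright import RunConfig, run_comparison

report = run_comparison(RunConfig(
    experiment="egg_chamber_fold", tag_ratio=4.5, n_images=12, seed=7,
))
h, s = report.per_condition["halo"], report.per_condition["snap"]
print(f"halo: n={h['n']}  corrected signal = {h['mean']:.1f} +/- {h['sd']:.1f}")
print(f"snap: n={s['n']}  corrected signal = {s['mean']:.1f} +/- {s['sd']:.1f}")
print(f"fold = {report.fold:.2f}  (95% CI {report.fold_ci[0]:.2f}-{report.fold_ci[1]:.2f})")
print(f"t = {report.t_stat:.1f}, p = {report.p_two_tailed:.2e} {report.stars}")
```

prints

```
halo: n=12  corrected signal = 267.3 +/- 4.3
snap: n=12  corrected signal = 60.3 +/- 0.9
fold = 4.44  (95% CI 4.39-4.49)
t = 161.4, p = 2.61e-35 ****
```

The fold ratio of background-corrected means recovers the configured 4.5
within a few percent; the t-test confirms the condition difference. The
same comparison is available from the shell:

```bash
tagbright compare --experiment egg_chamber_fold --seed 7 --out results/
tagbright simulate --scene egg_chamber --seed 7 --out scene/
tagbright quantify scene/scene.tif --dog-sigma 4 --dog-k 1.4 --min-area 500
```

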