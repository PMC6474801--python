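"""Seeded synthetic-microscopy scene generator.

Every analysis stage in this package was designed against real confocal and
STED data that cannot be redistributed, so this module renders surrogate
scenes with the same statistical structure and returns exact ground truth
alongside each image:

* ``hela_field`` — a field of HeLa-like cells; a transfected subset carries
  perinuclear Golgi-like blob clusters visible in the reporter (GFP)
  channel, and a configurable fraction of those also carries dye-marker
  signal whose mean brightness scales with the tag being emulated.
* ``egg_chamber`` — a follicle-epithelium annulus with a thin, bright
  subapical band, the structure the DoG + Renyi-entropy quantifier maps.
* ``clathrin_field`` — sparse clathrin-pit rings near the resolution limit
  that appear as donuts under a STED-grade PSF and as blurry spots under a
  confocal one.
* ``sted_timeseries`` — a 2D+time stack whose structure intensity decays
  mono-exponentially (photobleaching) frame to frame.

Rendering pipeline: a noiseless structural image (piecewise-constant
plateaus, so interior means equal the configured intensities exactly) is
convolved with an isotropic Gaussian PSF of the configured FWHM, then shot
noise (Poisson), constant background and Gaussian read noise are applied.
All randomness flows from ``SceneConfig.seed`` through
``numpy.random.default_rng``; identical configs give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.ndimage import gaussian_filter

from .imagestack import ImageStack, write_tiff

__all__ = [
    "NoiseModel",
    "SceneConfig",
    "GroundTruth",
    "SCENE_KINDS",
    "FWHM_TO_SIGMA",
    "apply_noise",
    "generate_scene",
    "generate_bleach_series",
    "paired_condition_configs",
    "rim_radius_for_apparent_diameter",
    "write_scene",
]

SCENE_KINDS = ("hela_field", "egg_chamber", "clathrin_field", "sted_timeseries")

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class SceneConfigError(ValueError):
    """Raised for invalid or inconsistent scene configuration."""


class SceneGenerationError(RuntimeError):
    """Raised when a valid config cannot be rendered (e.g. frame too small)."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: Poisson shot noise + constant background + read noise.

    ``photon_scale`` is the number of detected photo-electrons per intensity
    unit; the Poisson draw happens in electrons and is scaled back, so large
    values approach the noise-free limit.  ``background_offset`` is added
    before the Poisson draw (it is real detected light, not an electronic
    offset) and ``read_sigma`` is the SD of additive Gaussian read noise in
    intensity units.
    """

    photon_scale: float = 1.0
    read_sigma: float = 2.0
    background_offset: float = 10.0

    def __post_init__(self) -> None:
        for name in ("photon_scale", "read_sigma", "background_offset"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise SceneConfigError(f"NoiseModel.{name} must be finite, got {v}")
        if self.photon_scale <= 0:
            raise SceneConfigError("NoiseModel.photon_scale must be > 0")
        if self.read_sigma < 0 or self.background_offset < 0:
            raise SceneConfigError("read_sigma and background_offset must be >= 0")


NO_NOISE = NoiseModel(photon_scale=1e9, read_sigma=0.0, background_offset=0.0)


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic scene.

    Defaults correspond to the confocal HeLa experiments this package
    emulates; see the scene factory helpers at the bottom of the module for
    per-scene presets (STED pixel sizes, PSF widths, ...).

    ``tag_ratio`` is the ground-truth Halo:SNAP marker-brightness ratio used
    by :func:`paired_condition_configs`; ``base_intensity`` is the mean
    marker intensity of the dimmer (SNAP) condition.  ``bleach_halflife_s``
    of ``None`` means no bleaching.  ``ring_diameter_nm`` is the *apparent*
    donut diameter of a clathrin pit, i.e. the peak-to-peak distance a line
    profile through the rendered pit shows under this scene's PSF; the
    underlying rim radius is derived by inverting the ring (x) PSF model and
    recorded in the ground truth (see :func:`rim_radius_for_apparent_diameter`).
    """

    scene_kind: str = "hela_field"
    pixel_size_nm: float = 180.2
    image_shape: tuple[int, int] = (256, 256)
    n_frames: int = 1
    frame_interval_s: float = 1.0
    tag_ratio: float = 1.0
    transfected_fraction: float = 0.35
    labeled_fraction_above_limit: float = 1.0
    base_intensity: float = 100.0
    bleach_halflife_s: float | None = None
    psf_fwhm_nm: float = 250.0
    ring_diameter_nm: float = 100.0
    rim_radius_nm: float | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    # scene-density knobs (counts are upper bounds; placement is jittered)
    n_cells: int = 20
    n_pits: int = 6
    sted_structure: str = "golgi"  # or "band"

    def __post_init__(self) -> None:
        if self.scene_kind not in SCENE_KINDS:
            raise SceneConfigError(
                f"unknown scene_kind {self.scene_kind!r}; expected one of {SCENE_KINDS}"
            )
        ny, nx = self.image_shape
        if ny < 64 or nx < 64:
            raise SceneConfigError("image_shape must be at least (64, 64)")
        for name in ("pixel_size_nm", "base_intensity", "tag_ratio", "psf_fwhm_nm",
                     "ring_diameter_nm"):
            if getattr(self, name) <= 0:
                raise SceneConfigError(f"{name} must be positive")
        for name in ("transfected_fraction", "labeled_fraction_above_limit"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SceneConfigError(f"{name} must lie in [0, 1]")
        if self.n_frames < 1:
            raise SceneConfigError("n_frames must be >= 1")
        if self.frame_interval_s <= 0 and self.n_frames > 1:
            raise SceneConfigError("frame_interval_s must be positive for time series")
        if self.bleach_halflife_s is not None and self.bleach_halflife_s <= 0:
            raise SceneConfigError("bleach_halflife_s must be positive (or None)")
        if self.sted_structure not in ("golgi", "band"):
            raise SceneConfigError("sted_structure must be 'golgi' or 'band'")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_fwhm_nm * FWHM_TO_SIGMA / self.pixel_size_nm

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(self.image_shape)
        return d


@dataclass
class GroundTruth:
    """Exact per-object and scene-level truth for a generated scene.

    ``objects`` has one row per rendered object with columns
    ``object_id, channel, centroid_y, centroid_x, area_px, true_mean_intensity,
    colabeled``.  ``structure_mask`` is the noiseless support of the marker
    structure (before PSF), useful as an oracle ROI.
    """

    objects: pd.DataFrame
    tag_ratio: float
    bleach_halflife_s: float | None = None
    ring_diameter_nm: float | None = None
    rim_radius_nm: float | None = None
    structure_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def apply_noise(
    image: np.ndarray,
    model: NoiseModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Apply the detector noise model to a noiseless intensity image.

    ``out = Poisson(photon_scale * (image + background)) / photon_scale
    + N(0, read_sigma)``, clipped at zero.  Deterministic for a fixed seed.
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("apply_noise requires a non-negative input image")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    electrons = model.photon_scale * (image + model.background_offset)
    # Poisson sampling is exact but slow for huge means; above ~1e6 electrons
    # the Gaussian limit is indistinguishable at float precision.
    out = np.where(
        electrons < 1e6,
        rng.poisson(np.minimum(electrons, 1e6 - 1.0)).astype(float),
        electrons + rng.standard_normal(image.shape) * np.sqrt(electrons),
    )
    out /= model.photon_scale
    if model.read_sigma > 0:
        out += rng.normal(0.0, model.read_sigma, size=image.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------


def _disk(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _radius_map(shape: tuple[int, int], cy: float, cx: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return np.hypot(yy - cy, xx - cx)


def _jittered_grid(
    shape: tuple[int, int], n: int, margin: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Roughly uniform, non-clumping cell centres on a jittered grid."""
    ny, nx = shape
    cols = int(np.ceil(np.sqrt(n * nx / ny)))
    rows = int(np.ceil(n / cols))
    ys = np.linspace(margin, ny - margin, rows)
    xs = np.linspace(margin, nx - margin, cols)
    pts = [(y, x) for y in ys for x in xs]
    order = rng.permutation(len(pts))[:n]
    jitter = min((ny - 2 * margin) / max(rows, 1), (nx - 2 * margin) / max(cols, 1)) * 0.18
    out = []
    for i in order:
        y, x = pts[i]
        out.append(
            (
                float(np.clip(y + rng.uniform(-jitter, jitter), margin, ny - margin)),
                float(np.clip(x + rng.uniform(-jitter, jitter), margin, nx - margin)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# clathrin-pit apparent-diameter inversion
# ---------------------------------------------------------------------------


def _ring_peak_radius(rim_radius: float, sigma: float) -> float:
    """Radius of maximum intensity of a thin ring convolved with a Gaussian.

    The convolution of a unit ring of radius R with an isotropic Gaussian of
    SD sigma is ``I(r) = exp(-(r^2+R^2)/(2 s^2)) * I0(r R / s^2)`` (modified
    Bessel function).  The maximum sits strictly inside R; for R << sigma it
    collapses to r = 0 (unresolved donut).
    """

    def neg_log_i(r: float) -> float:
        z = r * rim_radius / sigma**2
        # ive = exp(-z) * iv, numerically stable: log I0(z) = z + log ive(0, z)
        return (r**2 + rim_radius**2) / (2 * sigma**2) - z - np.log(special.ive(0, z))

    res = optimize.minimize_scalar(neg_log_i, bounds=(0.0, rim_radius), method="bounded")
    return float(res.x)


def rim_radius_for_apparent_diameter(
    apparent_diameter_nm: float, psf_fwhm_nm: float, rim_sigma_nm: float = 8.0
) -> float:
    """Underlying rim radius whose rendered donut shows the given diameter.

    A Gaussian PSF pulls the intensity peaks of a ring inward (curvature
    effect), so the peak-to-peak distance seen in an image underestimates
    the physical rim diameter.  This inverts the thin-ring (x) Gaussian model
    (rim cross-section folded into an effective sigma) so that the rendered
    pit shows ``apparent_diameter_nm`` peak to peak under the given PSF.
    """
    sigma_eff = np.hypot(psf_fwhm_nm * FWHM_TO_SIGMA, rim_sigma_nm)
    target = apparent_diameter_nm / 2.0

    def gap(rim: float) -> float:
        return _ring_peak_radius(rim, sigma_eff) - target

    lo, hi = target, target + 8.0 * sigma_eff
    if gap(hi) < 0:  # even a huge rim cannot show this apparent radius
        raise SceneGenerationError(
            f"apparent diameter {apparent_diameter_nm} nm unreachable under "
            f"PSF FWHM {psf_fwhm_nm} nm"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-3))


# ---------------------------------------------------------------------------
# scene renderers: each returns (reporter, marker, objects, structure_mask)
# noiseless, pre-PSF; marker may be a 3D (T, Y, X) array for time series
# ---------------------------------------------------------------------------


def _render_hela_field(cfg: SceneConfig, rng: np.random.Generator):
    ny, nx = cfg.image_shape
    cell_radius = max(9.0, 10_000.0 / cfg.pixel_size_nm / 2)  # ~10 um cells
    margin = cell_radius * 1.3
    if ny <= 2 * margin or nx <= 2 * margin:
        raise SceneGenerationError("image_shape too small to contain one cell")
    centres = _jittered_grid((ny, nx), cfg.n_cells, margin, rng)
    n_cells = len(centres)
    n_transfected = int(round(cfg.transfected_fraction * n_cells))
    n_labeled = int(round(cfg.labeled_fraction_above_limit * n_transfected))
    transfected = np.zeros(n_cells, bool)
    transfected[:n_transfected] = True
    labeled = np.zeros(n_cells, bool)
    labeled[:n_labeled] = True  # labeled cells are a subset of transfected

    reporter = np.zeros((ny, nx))
    marker = np.zeros((ny, nx))
    mask = np.zeros((ny, nx), bool)
    records = []
    for i, (cy, cx) in enumerate(centres):
        if not transfected[i]:
            continue
        # Golgi = 1-3 overlapping plateau disks near the cell centre
        n_blob = rng.integers(1, 4)
        golgi = np.zeros((ny, nx), bool)
        for _ in range(n_blob):
            dy, dx = rng.uniform(-cell_radius * 0.3, cell_radius * 0.3, size=2)
            golgi |= _disk((ny, nx), cy + dy, cx + dx, cell_radius * rng.uniform(0.28, 0.42))
        # per-cell expression level, shared between channels (Gaussian, CV 25%)
        expression = max(0.1, rng.normal(1.0, 0.25))
        reporter_level = 120.0 * expression
        marker_level = cfg.base_intensity * expression if labeled[i] else 0.0
        reporter[golgi] = reporter_level
        if labeled[i]:
            marker[golgi] = marker_level
            mask |= golgi
        ys, xs = np.nonzero(golgi)
        records.append(
            dict(
                object_id=i,
                channel=1,
                centroid_y=float(ys.mean()),
                centroid_x=float(xs.mean()),
                area_px=int(golgi.sum()),
                true_mean_intensity=marker_level,
                colabeled=bool(labeled[i]),
            )
        )
    objects = pd.DataFrame(records)
    return reporter, marker, objects, mask


def _render_egg_chamber(cfg: SceneConfig, rng: np.random.Generator):
    """Follicle-epithelium annulus with a bright, thin subapical band."""
    ny, nx = cfg.image_shape
    cy = ny / 2 + rng.uniform(-ny * 0.03, ny * 0.03)
    cx = nx / 2 + rng.uniform(-nx * 0.03, nx * 0.03)
    a = 0.40 * ny * rng.uniform(0.92, 1.0)  # semi-axes of the outer ellipse
    b = 0.40 * nx * rng.uniform(0.78, 0.9)
    yy, xx = np.mgrid[:ny, :nx]
    # elliptical "radius" (1.0 on the outer epithelial boundary)
    re = np.hypot((yy - cy) / a, (xx - cx) / b)
    epithelium_width = 0.16  # fraction of the semi-axis
    band_width_px = max(3.0, 1000.0 / cfg.pixel_size_nm)  # ~1 um subapical band
    band_width = band_width_px / min(a, b)
    inner = 1.0 - epithelium_width
    epithelium = (re >= inner) & (re <= 1.0)
    band = (re >= inner) & (re <= inner + band_width)
    if band.sum() < 64:
        raise SceneGenerationError("image_shape too small for an egg-chamber band")
    marker = np.zeros((ny, nx))
    marker[epithelium] = 0.12 * cfg.base_intensity  # dim cytoplasmic signal
    marker[band] = cfg.base_intensity  # subapical aPKC band
    ys, xs = np.nonzero(band)
    objects = pd.DataFrame(
        [
            dict(
                object_id=0,
                channel=1,
                centroid_y=float(ys.mean()),
                centroid_x=float(xs.mean()),
                area_px=int(band.sum()),
                true_mean_intensity=cfg.base_intensity,
                colabeled=True,
            )
        ]
    )
    return None, marker, objects, band


def _render_clathrin_field(cfg: SceneConfig, rng: np.random.Generator):
    ny, nx = cfg.image_shape
    rim_sigma_nm = 8.0
    if cfg.rim_radius_nm is not None:
        rim_nm = cfg.rim_radius_nm
    else:
        rim_nm = rim_radius_for_apparent_diameter(
            cfg.ring_diameter_nm, cfg.psf_fwhm_nm, rim_sigma_nm
        )
    rim_px = rim_nm / cfg.pixel_size_nm
    rim_sigma_px = rim_sigma_nm / cfg.pixel_size_nm
    # keep pits a diffraction-scale distance from the frame edge so that a
    # confocal re-render of the same field stays fully in frame
    margin = rim_px + max(6 * cfg.psf_sigma_px, 400.0 / cfg.pixel_size_nm) + 2
    if ny <= 2 * margin or nx <= 2 * margin:
        raise SceneGenerationError("image_shape too small to contain one pit")
    centres = _jittered_grid((ny, nx), cfg.n_pits, margin, rng)
    marker = np.zeros((ny, nx))
    records = []
    for i, (cy, cx) in enumerate(centres):
        r = _radius_map((ny, nx), cy, cx)
        ring = np.exp(-((r - rim_px) ** 2) / (2 * rim_sigma_px**2))
        marker += cfg.base_intensity * ring
        records.append(
            dict(
                object_id=i,
                channel=1,
                centroid_y=cy,
                centroid_x=cx,
                area_px=int(np.sum(np.abs(r - rim_px) <= 2 * rim_sigma_px)),
                true_mean_intensity=cfg.base_intensity,
                colabeled=True,
            )
        )
    mask = marker > 0.2 * cfg.base_intensity
    return None, marker, pd.DataFrame(records), mask


def _render_sted_structure(cfg: SceneConfig, rng: np.random.Generator):
    """Static structure for a STED time series (Golgi blobs or aPKC band)."""
    ny, nx = cfg.image_shape
    marker = np.zeros((ny, nx))
    if cfg.sted_structure == "band":
        # subapical band crossing the small STED field: arc of a large circle
        R = 1.6 * max(ny, nx)
        cy = ny / 2 + R
        cx = nx / 2 + rng.uniform(-nx * 0.1, nx * 0.1)
        band_half = max(3.0, 150.0 / cfg.pixel_size_nm)  # ~300 nm thick band
        r = _radius_map((ny, nx), cy, cx)
        band = np.abs(r - R) <= band_half
        marker[band] = cfg.base_intensity
        support = band
    else:
        n_blob = max(3, int(rng.integers(4, 8)))
        support = np.zeros((ny, nx), bool)
        blob_r = max(4.0, 400.0 / cfg.pixel_size_nm)  # ~0.8 um Golgi elements
        for cy, cx in _jittered_grid((ny, nx), n_blob, blob_r * 3, rng):
            support |= _disk((ny, nx), cy, cx, blob_r * rng.uniform(0.7, 1.3))
        marker[support] = cfg.base_intensity
    ys, xs = np.nonzero(support)
    objects = pd.DataFrame(
        [
            dict(
                object_id=0,
                channel=1,
                centroid_y=float(ys.mean()),
                centroid_x=float(xs.mean()),
                area_px=int(support.sum()),
                true_mean_intensity=cfg.base_intensity,
                colabeled=True,
            )
        ]
    )
    return None, marker, objects, support


_RENDERERS: dict[str, Callable] = {
    "hela_field": _render_hela_field,
    "egg_chamber": _render_egg_chamber,
    "clathrin_field": _render_clathrin_field,
    "sted_timeseries": _render_sted_structure,
}


# ---------------------------------------------------------------------------
# public generation API
# ---------------------------------------------------------------------------


def _bleach_factors(cfg: SceneConfig) -> np.ndarray:
    t = np.arange(cfg.n_frames) * cfg.frame_interval_s
    if cfg.bleach_halflife_s is None:
        return np.ones(cfg.n_frames)
    return 2.0 ** (-t / cfg.bleach_halflife_s)


def generate_scene(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a scene and its exact ground truth.

    Channel layout: two-channel scenes put the reporter in channel 0 and the
    dye marker in channel 1; single-structure scenes (egg chamber, clathrin,
    STED series) have the marker alone in channel 0.  For multi-frame
    configs the structure is static and only bleaching + per-frame noise
    vary over time.
    """
    rng = np.random.default_rng(config.seed)
    reporter, marker, objects, support = _RENDERERS[config.scene_kind](config, rng)

    sigma = config.psf_sigma_px
    blur = lambda im: gaussian_filter(im, sigma, mode="reflect") if sigma > 0 else im
    marker_blurred = blur(marker)
    channels = []
    if reporter is not None:
        channels.append(blur(reporter))
    channels.append(marker_blurred)

    factors = _bleach_factors(config)
    frames = np.empty((config.n_frames, len(channels), *config.image_shape))
    noise_rng = np.random.default_rng([config.seed, 0xBEEF])
    for t, f in enumerate(factors):
        for c, ch in enumerate(channels):
            decays = c == len(channels) - 1  # only the dye marker bleaches
            frames[t, c] = apply_noise(ch * (f if decays else 1.0), config.noise, noise_rng)

    stack = ImageStack(
        frames,
        pixel_size_nm=config.pixel_size_nm,
        frame_interval_s=config.frame_interval_s if config.n_frames > 1 else 0.0,
    )
    truth = GroundTruth(
        objects=objects,
        tag_ratio=config.tag_ratio,
        bleach_halflife_s=config.bleach_halflife_s,
        ring_diameter_nm=config.ring_diameter_nm
        if config.scene_kind == "clathrin_field"
        else None,
        rim_radius_nm=(
            config.rim_radius_nm
            if config.rim_radius_nm is not None
            else rim_radius_for_apparent_diameter(config.ring_diameter_nm, config.psf_fwhm_nm)
        )
        if config.scene_kind == "clathrin_field"
        else None,
        structure_mask=support,
    )
    return stack, truth


def generate_bleach_series(config: SceneConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a 2D+time STED series with exponential photobleaching.

    Expected structure intensity at frame i is
    ``base_intensity * 2**(-t_i / halflife)`` with ``t_i = i * frame_interval``;
    noise is drawn independently per frame.
    """
    if config.n_frames < 2:
        raise SceneConfigError("generate_bleach_series needs n_frames >= 2")
    if config.scene_kind != "sted_timeseries":
        config = replace(config, scene_kind="sted_timeseries")
    return generate_scene(config)


def paired_condition_configs(config: SceneConfig) -> tuple[SceneConfig, SceneConfig]:
    """Halo/SNAP condition pair differing only in marker brightness and seed.

    The SNAP condition renders at ``base_intensity``; the Halo condition at
    ``base_intensity * tag_ratio``, so the ratio of noiseless dye-channel
    object means equals ``tag_ratio`` exactly.
    """
    halo = replace(
        config,
        base_intensity=config.base_intensity * config.tag_ratio,
        seed=config.seed,
    )
    snap = replace(config, seed=config.seed + 1_000_003)
    return halo, snap


# ---------------------------------------------------------------------------
# scene presets (the study conditions)
# ---------------------------------------------------------------------------


def hela_field_config(**overrides) -> SceneConfig:
    """Confocal HeLa field: ~180-nm pixels, 250-nm PSF, Golgi-labeled cells."""
    params = dict(
        scene_kind="hela_field",
        pixel_size_nm=180.2,
        image_shape=(448, 448),
        psf_fwhm_nm=250.0,
        n_cells=30,
        transfected_fraction=0.5,
    )
    params.update(overrides)
    return SceneConfig(**params)


def egg_chamber_config(**overrides) -> SceneConfig:
    """Confocal egg chamber: the 500-px minimum area equals 16.24 um^2."""
    params = dict(
        scene_kind="egg_chamber",
        pixel_size_nm=180.2,
        image_shape=(256, 256),
        psf_fwhm_nm=250.0,
    )
    params.update(overrides)
    return SceneConfig(**params)


def clathrin_sted_config(**overrides) -> SceneConfig:
    """Clathrin-pit STED field: 10-nm pixels, 60-nm PSF, ~100-nm donuts."""
    params = dict(
        scene_kind="clathrin_field",
        pixel_size_nm=10.0,
        image_shape=(256, 256),
        psf_fwhm_nm=60.0,
        ring_diameter_nm=100.0,
        n_pits=4,
    )
    params.update(overrides)
    return SceneConfig(**params)


def sted_series_config(**overrides) -> SceneConfig:
    """STED time series: 40-nm pixels (Golgi) with mono-exponential bleaching."""
    params = dict(
        scene_kind="sted_timeseries",
        pixel_size_nm=40.0,
        image_shape=(256, 256),
        psf_fwhm_nm=60.0,
        n_frames=64,
        frame_interval_s=1.0,
        bleach_halflife_s=50.0,
    )
    params.update(overrides)
    return SceneConfig(**params)


def egg_chamber_sted_series_config(**overrides) -> SceneConfig:
    """Egg-chamber STED series: 19.53-nm pixels, subapical band structure."""
    params = dict(
        scene_kind="sted_timeseries",
        sted_structure="band",
        pixel_size_nm=19.53,
        image_shape=(512, 512),
        psf_fwhm_nm=60.0,
        n_frames=20,
        frame_interval_s=1.9,
        bleach_halflife_s=60.0,
    )
    params.update(overrides)
    return SceneConfig(**params)


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------


def write_scene(
    config: SceneConfig, out_dir: str | Path, stem: str = "scene"
) -> dict[str, Path]:
    """Render a scene and write TIFF + ground-truth CSV + config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, truth = generate_scene(config)
    paths = {
        "tiff": write_tiff(stack, out / f"{stem}.tif"),
        "ground_truth": out / f"{stem}.ground_truth.csv",
        "config": out / f"{stem}.config.json",
    }
    truth.objects.to_csv(paths["ground_truth"], index=False)
    paths["config"].write_text(json.dumps(config.to_dict(), indent=2))
    return paths
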