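"""STED time-series processing: frame summing, kymographs, bleaching curves.

Raw STED movies are photon-starved, so consecutive raw frames are *summed*
(not averaged) into display/analysis frames — four raw frames per image for
the HeLa Golgi movies, five for the egg-chamber movies.  A small Gaussian
display blur (0.5 px) is available for presentation only; every
quantification in this module runs on unblurred data.  Bleaching is
summarised as a background-corrected mean-intensity time course fitted with
a mono-exponential decay parameterised by its half-life,
``I(t) = offset + I0 * 2**(-t / halflife)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import curve_fit

from .imagestack import ImageStack

__all__ = [
    "BleachCurve",
    "Kymograph",
    "sum_frames",
    "display_blur",
    "kymograph",
    "intensity_timecourse",
    "initial_intensity",
]


@dataclass
class BleachCurve:
    """Background-corrected mean intensity per frame, with an optional decay fit.

    ``fit`` is ``(I0, halflife_s, offset)`` when the mono-exponential fit
    converged, else ``None``; ``no_decay`` flags curves with no net decrease
    for which fitting was skipped.
    """

    times_s: np.ndarray
    intensities: np.ndarray
    fit: tuple[float, float, float] | None = None
    fit_r2: float = np.nan
    no_decay: bool = False


@dataclass
class Kymograph:
    """Space-time image: rows are positions along the line, columns frames."""

    data: np.ndarray
    p0: tuple[float, float]
    p1: tuple[float, float]
    step_px: float = 1.0

    @property
    def n_positions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def sum_frames(stack: ImageStack, n: int) -> ImageStack:
    """Sum non-overlapping blocks of ``n`` raw frames into one frame each.

    The trailing partial block is dropped; the frame interval scales by
    ``n``.  Accumulation happens in a widened dtype so integer inputs
    cannot overflow; photon counts of the consumed frames are conserved
    exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > stack.n_frames:
        raise ValueError(f"cannot sum {n} frames: stack has only {stack.n_frames}")
    n_out = stack.n_frames // n
    data = stack.data[: n_out * n]
    wide = np.int64 if np.issubdtype(data.dtype, np.integer) else np.float64
    summed = data.astype(wide).reshape(n_out, n, *data.shape[1:]).sum(axis=1)
    return stack.with_data(summed, frame_interval_s=stack.frame_interval_s * n)


def display_blur(image: np.ndarray, sigma_px: float = 0.5) -> np.ndarray:
    """Gaussian blur for presentation only; quantify unblurred data.

    Reflection boundaries; ``sigma_px = 0`` is the identity.
    """
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma_px == 0:
        return image.copy()
    return gaussian_filter(image, sigma_px, mode="reflect")


def _line_coordinates(
    p0: tuple[float, float], p1: tuple[float, float], width_px: int, step_px: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampling grid along p0->p1 (row, col): positions x width offsets."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    d = p1 - p0
    length = float(np.hypot(*d))
    if length == 0:
        raise ValueError("line endpoints are identical")
    n_steps = int(np.floor(length / step_px)) + 1
    t = np.arange(n_steps) * step_px
    unit = d / length
    normal = np.array([-unit[1], unit[0]])
    offsets = (np.arange(width_px) - (width_px - 1) / 2.0)[:, None] * normal[None, :]
    pts = p0[None, None, :] + t[None, :, None] * unit[None, None, :] + offsets[:, None, :]
    return pts[..., 0], pts[..., 1], t


def kymograph(
    stack: ImageStack,
    p0: tuple[float, float],
    p1: tuple[float, float],
    width_px: int = 1,
    channel: int = 0,
) -> Kymograph:
    """Sample a fixed line in every frame; columns are ordered by time.

    ``p0``/``p1`` are (row, col) pixel coordinates.  Each frame is sampled
    bilinearly at 1-px steps along the segment and averaged over
    ``width_px`` perpendicular samples.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    ny, nx = stack.frame_shape
    for p in (p0, p1):
        if not (0 <= p[0] <= ny - 1 and 0 <= p[1] <= nx - 1):
            raise ValueError(f"endpoint {p} outside the frame")
    rows, cols, _ = _line_coordinates(p0, p1, width_px)
    columns = []
    for t in range(stack.n_frames):
        samples = map_coordinates(
            stack.frame(t, channel).astype(float), [rows, cols], order=1, mode="nearest"
        )
        columns.append(samples.mean(axis=0))
    return Kymograph(
        data=np.stack(columns, axis=1),
        p0=(float(p0[0]), float(p0[1])),
        p1=(float(p1[0]), float(p1[1])),
    )


def _halflife_model(t: np.ndarray, i0: float, halflife: float, offset: float) -> np.ndarray:
    return offset + i0 * 2.0 ** (-t / halflife)


def intensity_timecourse(
    stack: ImageStack,
    roi_mask: np.ndarray,
    background_mask: np.ndarray,
    channel: int = 0,
) -> BleachCurve:
    """Background-corrected ROI mean per frame, with a half-life decay fit.

    Per frame, ``corrected = mean(roi) - mean(background)``; both masks are
    constant across frames and must be disjoint and non-empty.  The
    mono-exponential fit is skipped (``no_decay=True``) when the curve
    shows no net decrease.
    """
    roi = np.asarray(roi_mask, bool)
    bg = np.asarray(background_mask, bool)
    if not roi.any() or not bg.any():
        raise ValueError("roi and background masks must be non-empty")
    if (roi & bg).any():
        raise ValueError("roi and background masks overlap")
    frames = stack.channel(channel).astype(float)
    corrected = frames[:, roi].mean(axis=1) - frames[:, bg].mean(axis=1)
    times = stack.times_s
    curve = BleachCurve(times_s=times, intensities=corrected)

    slope = np.polyfit(times, corrected, 1)[0] if len(times) > 1 else 0.0
    if slope >= 0:
        curve.no_decay = True
        return curve
    try:
        span = corrected.max() - corrected.min()
        p0 = (span if span > 0 else 1.0, max(times[-1] / 2.0, 1e-6), corrected.min())
        popt, _ = curve_fit(
            _halflife_model,
            times,
            corrected,
            p0=p0,
            bounds=([0.0, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return curve
    model = _halflife_model(times, *popt)
    ss_res = float(np.sum((corrected - model) ** 2))
    ss_tot = float(np.sum((corrected - corrected.mean()) ** 2))
    curve.fit = (float(popt[0]), float(popt[1]), float(popt[2]))
    curve.fit_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return curve


def initial_intensity(curve: BleachCurve, n_initial: int = 1) -> float:
    """Mean of the first ``n_initial`` background-corrected frame intensities."""
    if len(curve.intensities) == 0:
        raise ValueError("empty bleach curve")
    if not 1 <= n_initial <= len(curve.intensities):
        raise ValueError("n_initial must be between 1 and the curve length")
    return float(np.mean(curve.intensities[:n_initial]))
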