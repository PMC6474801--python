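"""Universal image carrier for the pipeline.

An :class:`ImageStack` holds pixel data together with the two pieces of
calibration metadata every downstream analysis needs: the pixel size in
nanometres and, for time series, the frame interval in seconds.  Data are
stored in a fixed ``(frame, channel, row, col)`` axis order; stills are
simply stacks with one frame.  Channel order is fixed by convention:
channel 0 is the transfection reporter (GFP or anti-HA immunostain),
channel 1 the dye marker.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_tiff", "write_tiff"]


@dataclass
class ImageStack:
    """Pixel data plus spatial/temporal calibration.

    Parameters
    ----------
    data:
        Array of shape ``(T, C, Y, X)``.  2-D input is promoted to a
        single-frame, single-channel stack; 3-D input is interpreted as
        ``(T, Y, X)``.
    pixel_size_nm:
        Side length of one pixel in nanometres.
    frame_interval_s:
        Time between consecutive frames in seconds (0 for stills).
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        elif arr.ndim != 4:
            raise ValueError(f"expected 2-4 dimensional data, got shape {arr.shape}")
        self.data = arr
        if not np.isfinite(self.pixel_size_nm) or self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive and finite")
        if self.frame_interval_s < 0:
            raise ValueError("frame_interval_s must be non-negative")

    @classmethod
    def from_channels(
        cls,
        channels: Sequence[np.ndarray],
        pixel_size_nm: float,
        frame_interval_s: float = 0.0,
    ) -> "ImageStack":
        """Build a single-frame multi-channel stack from 2-D arrays."""
        arr = np.stack([np.asarray(c) for c in channels], axis=0)[None]
        return cls(arr, pixel_size_nm, frame_interval_s)

    # -- accessors ---------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * float(self.frame_interval_s)

    @property
    def field_of_view_um(self) -> tuple[float, float]:
        ny, nx = self.frame_shape
        return ny * self.pixel_size_nm / 1000.0, nx * self.pixel_size_nm / 1000.0

    def frame(self, t: int, channel: int = 0) -> np.ndarray:
        return self.data[t, channel]

    def channel(self, c: int) -> np.ndarray:
        """Time series of one channel, shape ``(T, Y, X)``."""
        return self.data[:, c]

    def with_data(self, data: np.ndarray, **meta) -> "ImageStack":
        return replace(self, data=data, **meta)


def write_tiff(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF plus a JSON metadata sidecar.

    Pages are ordered frame-major, reporter channel before marker channel
    within each frame.  The sidecar ``<name>.meta.json`` records pixel
    size, frame interval and axis layout so the stack round-trips.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.data, metadata={"axes": "TCYX"})
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "axes": "TCYX",
                "shape": list(stack.data.shape),
                "pixel_size_nm": stack.pixel_size_nm,
                "frame_interval_s": stack.frame_interval_s,
            },
            indent=2,
        )
    )
    return path


def read_tiff(
    path: str | Path,
    pixel_size_nm: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a TIFF written by :func:`write_tiff` (or any plain TIFF).

    Calibration is taken from the sidecar when present; explicit arguments
    override it.  A bare TIFF with no sidecar requires ``pixel_size_nm``.
    """
    path = Path(path)
    data = tifffile.imread(path)
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        data = np.asarray(data).reshape(meta["shape"])
    if pixel_size_nm is None:
        pixel_size_nm = meta.get("pixel_size_nm")
    if pixel_size_nm is None:
        raise ValueError(f"no pixel size for {path}: pass pixel_size_nm explicitly")
    if frame_interval_s is None:
        frame_interval_s = meta.get("frame_interval_s", 0.0)
    return ImageStack(data, pixel_size_nm, frame_interval_s)
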