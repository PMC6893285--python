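"""Calibrated image stacks and TIFF I/O.

The carrier for all raw imagery in this package is :class:`CalibratedStack`,
a ``T x Z x Y x X`` array of non-negative intensities plus the physical
calibration needed to convert pixels and frames into micrometres and
minutes.  Stacks are written and read as ImageJ-compatible multi-page TIFF
via :mod:`tifffile`, so they round-trip through Fiji.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile


@dataclass
class CalibratedStack:
    """An intensity hyper-stack with physical calibration.

    Parameters
    ----------
    data
        Array of shape ``(T, Z, Y, X)`` with non-negative intensities.
        2-D input is promoted to ``(1, 1, Y, X)``, 3-D input to
        ``(T, 1, Y, X)`` (a time series of single planes).
    pixel_size_um
        Lateral pixel size in micrometres (> 0).
    z_step_um
        Axial slice spacing in micrometres (> 0).
    frame_interval_min
        Time between consecutive frames in minutes (> 0).
    channel_name
        Free-text channel label (e.g. ``"MCP-GFP"``).
    start_time_min
        Acquisition time of frame 0, in minutes.  Used to build the time
        axis; defaults to 0.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float = 1.0
    frame_interval_min: float = 1.0
    channel_name: str = ""
    start_time_min: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        elif arr.ndim != 4:
            raise ValueError(
                f"stack data must be 2-D, 3-D or 4-D (T,Z,Y,X); got ndim={arr.ndim}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("stack intensities must be finite")
        if arr.size and arr.min() < 0:
            raise ValueError("stack intensities must be non-negative")
        for name in ("pixel_size_um", "z_step_um", "frame_interval_min"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v}")
        self.data = arr.astype(np.float64, copy=False)

    # -- convenience accessors -------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def frame_times_min(self) -> np.ndarray:
        """Acquisition time of each frame, in minutes."""
        return self.start_time_min + np.arange(self.n_frames) * self.frame_interval_min

    def frame(self, t: int, z: int = 0) -> np.ndarray:
        return self.data[t, z]

    def with_data(self, data: np.ndarray) -> "CalibratedStack":
        return replace(self, data=data)


def write_stack(path, stack: CalibratedStack) -> None:
    """Write a stack as ImageJ-style TIFF with calibration metadata.

    Pixel size goes into the TIFF resolution tags, z spacing into the
    ImageJ ``spacing`` field and the frame interval (converted to seconds,
    the ImageJ convention) into ``finterval``.
    """
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata={
            "axes": "TZYX",
            "spacing": stack.z_step_um,
            "unit": "um",
            "finterval": stack.frame_interval_min * 60.0,
        },
    )


def read_stack(
    path,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    frame_interval_min: float | None = None,
    channel_name: str = "",
) -> CalibratedStack:
    """Read a TIFF stack, taking calibration from metadata or overrides.

    Calibration present in the file is used unless explicitly overridden.
    A stack without a recoverable pixel size and no override raises: the
    package never substitutes a silent default calibration.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arr = series.asarray()
        axes = series.axes
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        res = page.tags.get("XResolution")
        px = None
        if res is not None:
            num, den = res.value
            # a bare (1, 1) resolution with no physical unit is tifffile's
            # placeholder, not a real calibration
            if num and (den != num or meta.get("unit") in ("um", "micron")):
                px = den / num

    arr = _normalize_axes(arr, axes)
    if pixel_size_um is None:
        pixel_size_um = px
    if pixel_size_um is None:
        raise ValueError(
            f"{path}: no pixel size in TIFF metadata and no override given"
        )
    if z_step_um is None:
        z_step_um = float(meta.get("spacing", 0)) or 1.0
    if frame_interval_min is None:
        finterval_s = float(meta.get("finterval", 0))
        frame_interval_min = finterval_s / 60.0 if finterval_s else 1.0
    return CalibratedStack(
        data=np.clip(arr.astype(np.float64), 0, None),
        pixel_size_um=float(pixel_size_um),
        z_step_um=float(z_step_um),
        frame_interval_min=float(frame_interval_min),
        channel_name=channel_name,
    )


def _normalize_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    """Normalize a tifffile array to (T, Z, Y, X).

    Shape inference: trailing two axes are always Y, X.  A third axis is Z
    if the file declares it so, otherwise T; missing axes get length 1.
    """
    axes = (axes or "").upper()
    if arr.ndim == 2:
        return arr[None, None]
    if arr.ndim == 3:
        if "Z" in axes and "T" not in axes:
            return arr[None, :, :, :]
        return arr[:, None, :, :]
    if arr.ndim == 4:
        if axes.startswith("ZT"):
            return np.swapaxes(arr, 0, 1)
        return arr
    raise ValueError(f"cannot normalize array of ndim {arr.ndim} (axes={axes!r})")
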