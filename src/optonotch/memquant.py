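"""Membrane/interface intensity quantification and vesicle colocalization.

Three measurement families share this module:

* **Interface profiles** -- the intensity profile across a cell-cell
  interface is sampled along a user line with a 7-pixel perpendicular
  averaging width, the dominant peak is located, and the profile is
  integrated over a 0.78-um window centred at the peak (trapezoidal rule
  in physical units).  Values are typically normalized per embryo to the
  median of a reference region (the ectoderm).
* **Membrane bands** -- per segmented cell, mean intensity in a 0.3-um
  band lining the membrane vs. the mean over the remaining interior,
  and their cytoplasm-to-membrane ratio.  The band is built by eroding
  each cell label by ``round(band_um / pixel_size)`` pixels.
* **Colocalization** -- particles are detected independently in two
  channels with the spot detector; a channel-A particle counts as
  colocalized when its mask shares at least one pixel with any
  channel-B particle mask.

Coordinates are 0-based pixel centres; distances are converted to
micrometres via the stack's pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import profile_line
from skimage.morphology import disk

from .spotcall import SpotCallConfig, detect_spots

__all__ = [
    "InterfaceMeasurement",
    "CompartmentQuant",
    "ColocResult",
    "project_sum",
    "measure_interface",
    "normalize_to_reference",
    "membrane_band_quant",
    "coloc_percent",
]


def project_sum(stack, n_slices: int, t: int = 0, z_start: int = 0) -> np.ndarray:
    """Sum-of-slice projection of ``n_slices`` focal planes of one frame."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if z_start + n_slices > stack.n_slices:
        raise ValueError(
            f"requested slices [{z_start}, {z_start + n_slices}) exceed the "
            f"{stack.n_slices} available z-slices"
        )
    return stack.data[t, z_start:z_start + n_slices].sum(axis=0)


# ---------------------------------------------------------------------------
# Interface line profiles
# ---------------------------------------------------------------------------

@dataclass
class InterfaceMeasurement:
    """One interface intensity profile and its peak-window integral.

    ``integrated_intensity`` is in intensity x um (the trapezoidal
    integral of the profile over the window).  ``flagged`` marks profiles
    with no usable peak; ``clipped`` marks windows truncated by the
    profile's ends.
    """

    line_id: str
    distance_um: np.ndarray
    intensity: np.ndarray
    peak_position_um: float
    integrated_intensity: float
    window_um: float
    region: str = ""
    embryo_id: str = ""
    flagged: bool = False
    clipped: bool = False
    normalized_intensity: float = float("nan")


def measure_interface(
    image: np.ndarray,
    start_xy: tuple[float, float],
    end_xy: tuple[float, float],
    pixel_size_um: float,
    width_px: int = 7,
    w_int_um: float = 0.78,
    smooth_sigma_px: float = 1.0,
    min_prominence: float = 0.0,
    line_id: str = "",
    region: str = "",
    embryo_id: str = "",
) -> InterfaceMeasurement:
    """Extract a width-averaged line profile and integrate around its peak.

    The profile is sampled at ~1-pixel steps along the segment from
    ``start_xy`` to ``end_xy`` (x, y pixel coordinates), averaging over
    ``width_px`` perpendicular pixels.  The dominant peak of the lightly
    smoothed profile (Gaussian sigma ``smooth_sigma_px``) is located with
    a prominence-based peak finder and the raw profile is integrated over
    ``w_int_um`` centred at the peak with the trapezoidal rule; the
    window is clipped to the profile's support if necessary.
    """
    from scipy.signal import find_peaks

    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be a positive odd integer")
    if w_int_um <= 0:
        raise ValueError("w_int_um must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")

    image = np.asarray(image, dtype=float)
    src = (start_xy[1], start_xy[0])  # profile_line takes (row, col)
    dst = (end_xy[1], end_xy[0])
    profile = profile_line(
        image, src, dst, linewidth=width_px, order=1, mode="reflect",
        reduce_func=np.mean,
    )
    n = len(profile)
    length_px = float(np.hypot(end_xy[0] - start_xy[0], end_xy[1] - start_xy[1]))
    step_um = (length_px / (n - 1)) * pixel_size_um if n > 1 else pixel_size_um
    dist = np.arange(n) * step_um

    smoothed = ndimage.gaussian_filter1d(profile, smooth_sigma_px) if smooth_sigma_px > 0 else profile
    peaks, props = find_peaks(smoothed, prominence=min_prominence if min_prominence > 0 else None)
    if len(peaks) == 0 or not np.any(smoothed > smoothed.min()):
        return InterfaceMeasurement(
            line_id=line_id, distance_um=dist, intensity=profile,
            peak_position_um=float("nan"), integrated_intensity=0.0,
            window_um=w_int_um, region=region, embryo_id=embryo_id, flagged=True,
        )
    if "prominences" in props and len(props["prominences"]):
        peak = peaks[int(np.argmax(props["prominences"]))]
    else:
        peak = peaks[int(np.argmax(smoothed[peaks]))]

    centre = dist[peak]
    half = w_int_um / 2.0
    lo, hi = centre - half, centre + half
    clipped = bool(lo < dist[0] or hi > dist[-1])
    lo_c, hi_c = max(lo, dist[0]), min(hi, dist[-1])
    integral = _trapz_window(dist, profile, lo_c, hi_c)

    return InterfaceMeasurement(
        line_id=line_id, distance_um=dist, intensity=profile,
        peak_position_um=float(centre), integrated_intensity=float(integral),
        window_um=w_int_um, region=region, embryo_id=embryo_id,
        flagged=False, clipped=clipped,
    )


def _trapz_window(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the piecewise-linear (x, y) over [lo, hi]."""
    if hi <= lo:
        return 0.0
    inner = (x > lo) & (x < hi)
    xs = np.concatenate([[lo], x[inner], [hi]])
    ys = np.concatenate([[np.interp(lo, x, y)], y[inner], [np.interp(hi, x, y)]])
    return float(np.trapezoid(ys, xs))


def normalize_to_reference(
    measurements: list[InterfaceMeasurement],
    reference_region: str = "ectoderm",
) -> list[InterfaceMeasurement]:
    """Divide each measurement by the per-embryo median of the reference region.

    Flagged measurements are excluded from the reference median but still
    receive a normalized value.  Raises if any embryo lacks reference
    measurements.
    """
    by_embryo: dict[str, list[InterfaceMeasurement]] = {}
    for m in measurements:
        by_embryo.setdefault(m.embryo_id, []).append(m)
    for embryo, ms in by_embryo.items():
        ref = [m.integrated_intensity for m in ms if m.region == reference_region and not m.flagged]
        if not ref:
            raise ValueError(
                f"embryo {embryo!r} has no {reference_region!r} reference measurements"
            )
        med = float(np.median(ref))
        if med <= 0:
            raise ValueError(f"embryo {embryo!r}: reference median is not positive")
        for m in ms:
            m.normalized_intensity = m.integrated_intensity / med
    return measurements


# ---------------------------------------------------------------------------
# Membrane band quantification
# ---------------------------------------------------------------------------

@dataclass
class CompartmentQuant:
    """Membrane-band vs cytoplasm intensity for one cell."""

    cell_id: int
    membrane_band_mean: float
    cytoplasm_mean: float
    cyt_to_mem_ratio: float
    region: str = ""
    flagged: bool = False


def membrane_band_quant(
    image: np.ndarray,
    cell_labels: np.ndarray,
    pixel_size_um: float,
    band_um: float = 0.3,
    region_labels: np.ndarray | None = None,
    region_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-cell membrane-band and cytoplasm means plus their ratio.

    The band is the rim of each cell label left after eroding it by
    ``round(band_um / pixel_size_um)`` pixels with a disk structuring
    element, so its physical thickness matches ``band_um`` to within one
    pixel.  Cells too small to retain an interior after erosion are
    flagged (ratio NaN).
    """
    image = np.asarray(image, dtype=float)
    cell_labels = np.asarray(cell_labels)
    if image.shape != cell_labels.shape:
        raise ValueError("image and cell label mask must share a shape")
    if band_um <= 0 or pixel_size_um <= 0:
        raise ValueError("band_um and pixel_size_um must be positive")

    r = max(1, int(round(band_um / pixel_size_um)))
    selem = disk(r)
    region_names = region_names or {1: "ectoderm", 2: "mesoderm"}

    rows = []
    objects = ndimage.find_objects(cell_labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        pad = tuple(
            slice(max(s.start - r, 0), min(s.stop + r, dim))
            for s, dim in zip(sl, cell_labels.shape)
        )
        mask = cell_labels[pad] == lab
        interior = ndimage.binary_erosion(mask, structure=selem)
        band = mask & ~interior
        sub = image[pad]
        mem = float(sub[band].mean()) if band.any() else float("nan")
        flagged = not interior.any()
        cyt = float(sub[interior].mean()) if interior.any() else float("nan")
        ratio = cyt / mem if (not flagged and mem > 0) else float("nan")
        region = ""
        if region_labels is not None:
            vals = region_labels[pad][mask]
            region = region_names.get(int(np.bincount(vals.astype(int)).argmax()), "")
        rows.append(
            {
                "cell_id": lab,
                "membrane_band_mean": mem,
                "cytoplasm_mean": cyt,
                "cyt_to_mem_ratio": ratio,
                "region": region,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-channel particle colocalization
# ---------------------------------------------------------------------------

@dataclass
class ColocResult:
    """Pixel-overlap colocalization of channel-A particles with channel B."""

    n_a: int
    n_b: int
    n_a_overlapping_b: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_a_overlapping_b <= self.n_a):
            raise ValueError("overlap count must be between 0 and n_a")

    @property
    def percent_coloc(self) -> float:
        return 100.0 * self.n_a_overlapping_b / self.n_a if self.n_a else float("nan")

    def summary(self) -> str:
        return (
            f"{self.n_a_overlapping_b}/{self.n_a} channel-A particles overlap "
            f"channel B in >= 1 pixel ({self.percent_coloc:.1f}%); "
            f"n_B = {self.n_b}"
        )


def coloc_percent(stack_a, stack_b, cfg: SpotCallConfig | None = None, frame: int = 0) -> ColocResult:
    """Detect particles in both channels and classify A by >= 1-pixel overlap.

    Both stacks must be aligned (same frame shape and calibration).  The
    spot detector runs in single-frame mode on ``frame`` of each stack.
    """
    if stack_a.data.shape[-2:] != stack_b.data.shape[-2:]:
        raise ValueError("channel stacks are not aligned")
    spots_a = detect_spots(_single_frame(stack_a, frame), cfg)
    spots_b = detect_spots(_single_frame(stack_b, frame), cfg)
    mask_a = spots_a.masks[0]
    mask_b = spots_b.masks[0] > 0
    n_a = int(mask_a.max())
    n_b = int(spots_b.masks[0].max())
    overlapping = np.unique(mask_a[mask_b & (mask_a > 0)])
    return ColocResult(n_a=n_a, n_b=n_b, n_a_overlapping_b=int(len(overlapping)))


def _single_frame(stack, t: int):
    return stack.with_data(stack.data[t:t + 1])
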