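"""Synthetic fluorescence-microscopy data with ground truth.

Every input the analysis pipeline consumes can be generated here, with the
generating parameters and per-object ground truth recorded alongside, so
the whole pipeline is exercisable and testable without any external data.

The generators emulate, at desk scale, the study conditions of an
optogenetic Delta/Notch experiment in the early fly embryo and pupal
notum:

``gen_spot_movie``
    Two parallel rows of static interphase nuclei in which
    diffraction-limited nascent-transcription spots switch ON
    irreversibly at exponentially distributed onset times after a delay,
    with spot intensity fluctuating around a stable per-spot mean
    ("digital" transcription: a spot is absent or present, never
    graded).
``gen_cluster_movie``
    A membrane lattice whose signal redistributes into bright clusters
    with exponential half-time kinetics while total signal mass is
    conserved (light-induced oligomerization of a membrane ligand).
``gen_interface_image``
    A cell lattice with Gaussian-cross-section membrane ridges whose
    amplitude and cytoplasmic level differ between two tissue regions
    (ectoderm vs. mesoderm membrane depletion).
``gen_vesicle_field``
    A two-channel field of vesicles with a prescribed overlap fraction
    (endosomal colocalization).
``gen_clone_tissue``
    A mosaic tissue with a clone mask and sensory-organ-precursor (SOP)
    positions placed at the clone boundary with a logistic bias.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .stack import CalibratedStack

__all__ = [
    "SpotMovieParams",
    "SpotMovieTruth",
    "ClusterMovieParams",
    "ClusterMovieTruth",
    "InterfaceImageParams",
    "InterfaceImageTruth",
    "VesicleFieldParams",
    "VesicleFieldTruth",
    "CloneTissueParams",
    "CloneTissueTruth",
    "gen_spot_movie",
    "gen_cluster_movie",
    "gen_interface_image",
    "gen_vesicle_field",
    "gen_clone_tissue",
    "per_nucleus_rate",
]

_NOISE_MODELS = ("none", "gaussian", "poisson")


def _check_positive(name: str, value: float, strict: bool = True) -> None:
    if not np.isfinite(value) or (value <= 0 if strict else value < 0):
        kind = "positive" if strict else "non-negative"
        raise ValueError(f"{name} must be a finite {kind} number, got {value}")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and coefficient of variation."""
    if cv == 0:
        return np.full(size, float(mean))
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - 0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def _apply_noise(rng: np.random.Generator, img: np.ndarray, model: str, scale: float) -> np.ndarray:
    if model == "none":
        return img
    if model == "gaussian":
        return np.clip(img + rng.normal(0.0, scale, img.shape), 0, None)
    if model == "poisson":
        return rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    raise ValueError(f"unknown noise model {model!r}")


def per_nucleus_rate(tissue_rate_per_um_min: float, nuclei_per_um: float) -> float:
    """Convert a tissue-level activation rate to a per-nucleus rate.

    A tissue-level rate is expressed as newly activated spots per minute
    per micrometre of tissue length.  Early in the activation process the
    expected tissue rate is ``k * lambda`` where ``k`` is the per-nucleus
    exponential rate (1/min) and ``lambda`` the linear nucleus density
    (nuclei/um, both rows pooled).  The density is tissue-specific and must
    be supplied by the user; it is not a constant of the method.
    """
    _check_positive("tissue_rate_per_um_min", tissue_rate_per_um_min, strict=False)
    _check_positive("nuclei_per_um", nuclei_per_um)
    return tissue_rate_per_um_min / nuclei_per_um


# ---------------------------------------------------------------------------
# Nascent-transcription spot movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotMovieParams:
    """Parameters of the two-row transcription-spot movie generator.

    Onset model: nucleus ``i`` switches ON at ``t0 + Exp(k)`` (minutes)
    and stays ON for the rest of the movie.  While ON it shows a single
    2-D Gaussian spot of standard deviation ``psf_sigma_px``; the spot's
    mean amplitude is drawn per nucleus with coefficient of variation
    ``cv_between_spots`` and its per-frame amplitude fluctuates around
    that mean with ``cv_over_time`` (both lognormal).

    Defaults encode the study conditions: onset delay 30 min after the
    start of the cycle, per-nucleus rate 0.3/min (so nearly all nuclei
    are ON within ~10 min of the first onsets), ~75% amplitude variation
    between spots but only ~20% over time for a given spot, pixel size
    0.13 um and a diffraction-limited sigma of 3 px.
    """

    n_nuclei_per_row: int = 30
    n_rows: int = 2
    row_spacing_um: float = 4.0
    nucleus_spacing_um: float = 3.0
    onset_rate_k: float = 0.3          # per minute, per nucleus
    onset_delay_t0: float = 30.0       # minutes
    movie_start: float = 25.0          # minutes
    movie_end: float = 55.0            # minutes
    frame_interval: float = 0.5        # minutes
    psf_sigma_px: float = 3.0
    mean_spot_amplitude: float = 500.0
    cv_between_spots: float = 0.75
    cv_over_time: float = 0.20
    background_level: float = 100.0
    noise_model: str = "none"
    noise_scale: float = 0.0
    pixel_size_um: float = 0.13
    position_jitter_px: float = 1.0
    min_frame_px: int = 112
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei_per_row < 1 or self.n_rows < 1:
            raise ValueError("need at least one nucleus and one row")
        _check_positive("onset_rate_k", self.onset_rate_k, strict=False)
        _check_positive("frame_interval", self.frame_interval)
        _check_positive("pixel_size_um", self.pixel_size_um)
        _check_positive("psf_sigma_px", self.psf_sigma_px)
        _check_positive("mean_spot_amplitude", self.mean_spot_amplitude)
        _check_positive("row_spacing_um", self.row_spacing_um)
        _check_positive("nucleus_spacing_um", self.nucleus_spacing_um)
        _check_positive("cv_between_spots", self.cv_between_spots, strict=False)
        _check_positive("cv_over_time", self.cv_over_time, strict=False)
        _check_positive("background_level", self.background_level, strict=False)
        _check_positive("noise_scale", self.noise_scale, strict=False)
        if self.movie_start > self.movie_end:
            raise ValueError("movie_start must be <= movie_end")
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {_NOISE_MODELS}")

    @property
    def n_nuclei(self) -> int:
        return self.n_nuclei_per_row * self.n_rows

    @property
    def frame_times(self) -> np.ndarray:
        n = int(math.floor((self.movie_end - self.movie_start) / self.frame_interval)) + 1
        return self.movie_start + np.arange(n) * self.frame_interval

    @property
    def region_length_um(self) -> float:
        """Length of tissue covered by one nucleus row."""
        return self.n_nuclei_per_row * self.nucleus_spacing_um


@dataclass
class SpotMovieTruth:
    """Ground truth for a spot movie.

    ``positions`` has one row per nucleus (nucleus_id, row, x_px, y_px);
    ``onset_times`` is minutes (inf = never ON); ``amplitudes`` has shape
    (n_frames, n_nuclei) with NaN while a nucleus is OFF.
    """

    positions: pd.DataFrame
    onset_times: np.ndarray
    amplitudes: np.ndarray
    frame_times: np.ndarray
    params: SpotMovieParams

    def n_on(self, t: float) -> int:
        return int(np.sum(self.onset_times <= t))

    def onset_table(self) -> pd.DataFrame:
        out = self.positions.copy()
        out["onset_min"] = self.onset_times
        return out


def gen_spot_movie(params: SpotMovieParams) -> tuple[CalibratedStack, SpotMovieTruth]:
    """Simulate a nascent-transcription reporter movie with ground truth."""
    rng = np.random.default_rng(params.seed)
    spacing_px = params.nucleus_spacing_um / params.pixel_size_um
    row_px = params.row_spacing_um / params.pixel_size_um
    margin = max(4.0 * params.psf_sigma_px + 4.0, 8.0)

    width = int(math.ceil(2 * margin + spacing_px * (params.n_nuclei_per_row - 1)))
    height = int(math.ceil(2 * margin + row_px * (params.n_rows - 1)))
    width = max(width, params.min_frame_px)
    height = max(height, params.min_frame_px)

    x0 = (width - spacing_px * (params.n_nuclei_per_row - 1)) / 2.0
    y0 = (height - row_px * (params.n_rows - 1)) / 2.0

    rows, xs, ys = [], [], []
    for r in range(params.n_rows):
        for i in range(params.n_nuclei_per_row):
            rows.append(r)
            xs.append(x0 + i * spacing_px)
            ys.append(y0 + r * row_px)
    xs = np.asarray(xs) + rng.uniform(-params.position_jitter_px, params.position_jitter_px, params.n_nuclei)
    ys = np.asarray(ys) + rng.uniform(-params.position_jitter_px, params.position_jitter_px, params.n_nuclei)
    positions = pd.DataFrame(
        {"nucleus_id": np.arange(params.n_nuclei), "row": rows, "x_px": xs, "y_px": ys}
    )

    if params.onset_rate_k > 0:
        onsets = params.onset_delay_t0 + rng.exponential(1.0 / params.onset_rate_k, params.n_nuclei)
    else:
        onsets = np.full(params.n_nuclei, np.inf)

    mean_amps = _lognormal(rng, params.mean_spot_amplitude, params.cv_between_spots, params.n_nuclei)

    times = params.frame_times
    n_frames = len(times)
    amplitudes = np.full((n_frames, params.n_nuclei), np.nan)
    frames = np.empty((n_frames, 1, height, width))

    sigma = params.psf_sigma_px
    half = int(math.ceil(4 * sigma))
    for ti, t in enumerate(times):
        img = np.full((height, width), float(params.background_level))
        on = np.nonzero(onsets <= t)[0]
        if on.size:
            amps = mean_amps[on] * _lognormal(rng, 1.0, params.cv_over_time, on.size)
            amplitudes[ti, on] = amps
            for j, a in zip(on, amps):
                _add_gaussian_spot(img, xs[j], ys[j], a, sigma, half)
        frames[ti, 0] = _apply_noise(rng, img, params.noise_model, params.noise_scale)

    stack = CalibratedStack(
        data=frames,
        pixel_size_um=params.pixel_size_um,
        frame_interval_min=params.frame_interval,
        channel_name="MCP-GFP",
        start_time_min=params.movie_start,
    )
    truth = SpotMovieTruth(
        positions=positions,
        onset_times=onsets,
        amplitudes=amplitudes,
        frame_times=times,
        params=params,
    )
    return stack, truth


def _add_gaussian_spot(img: np.ndarray, x: float, y: float, amp: float, sigma: float, half: int) -> None:
    h, w = img.shape
    cx, cy = int(round(x)), int(round(y))
    x_lo, x_hi = max(cx - half, 0), min(cx + half + 1, w)
    y_lo, y_hi = max(cy - half, 0), min(cy + half + 1, h)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    img[y_lo:y_hi, x_lo:x_hi] += amp * np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma * sigma)
    )


# ---------------------------------------------------------------------------
# Membrane cluster movies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterMovieParams:
    """Parameters of the light-induced membrane clustering movie.

    The membrane lattice carries a fixed total signal mass
    ``total_intensity``.  At time ``t`` (seconds since illumination
    onset) a fraction ``f(t) = f_max * (1 - 2**(-t / half_time_s))`` of
    that mass has relocated into clusters at fixed sites on the
    membrane; the remainder stays uniformly spread over the membrane.
    Mass is conserved exactly in every noise-free frame.

    Defaults mirror the clustering experiment: 2-s frame interval over
    6 min and a half-time of 40 s.
    """

    frame_size_px: int = 256
    cell_size_px: int = 32
    membrane_width_px: int = 2
    n_cluster_sites: int = 20
    cluster_radius_px: int = 1
    f_max: float = 0.8
    half_time_s: float = 40.0
    duration_s: float = 360.0
    frame_interval_s: float = 2.0
    total_intensity: float = 1.0e6
    noise_model: str = "none"
    noise_scale: float = 0.0
    pixel_size_um: float = 0.13
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive("half_time_s", self.half_time_s)
        _check_positive("frame_interval_s", self.frame_interval_s)
        _check_positive("total_intensity", self.total_intensity)
        _check_positive("pixel_size_um", self.pixel_size_um)
        if not (0.0 < self.f_max <= 1.0):
            raise ValueError(f"f_max must be in (0, 1], got {self.f_max}")
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {_NOISE_MODELS}")
        if self.cell_size_px < 4 or self.frame_size_px < 2 * self.cell_size_px:
            raise ValueError("lattice geometry too small")

    @property
    def frame_times_s(self) -> np.ndarray:
        n = int(math.floor(self.duration_s / self.frame_interval_s)) + 1
        return np.arange(n) * self.frame_interval_s

    def clustered_fraction(self, t) -> np.ndarray:
        """Ground-truth clustered fraction f(t)."""
        return self.f_max * (1.0 - 2.0 ** (-np.asarray(t, dtype=float) / self.half_time_s))


@dataclass
class ClusterMovieTruth:
    f_t: np.ndarray
    frame_times_s: np.ndarray
    membrane_mask: np.ndarray
    cluster_mask: np.ndarray
    cluster_sites: np.ndarray  # (n, 2) array of (y, x)
    params: ClusterMovieParams


def _membrane_lattice(size: int, cell: int, width: int) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    for p in range(0, size, cell):
        lo, hi = p, min(p + width, size)
        mask[lo:hi, :] = True
        mask[:, lo:hi] = True
    return mask


def gen_cluster_movie(params: ClusterMovieParams) -> tuple[CalibratedStack, ClusterMovieTruth]:
    """Simulate light-induced redistribution of membrane signal into clusters."""
    rng = np.random.default_rng(params.seed)
    n = params.frame_size_px
    membrane = _membrane_lattice(n, params.cell_size_px, params.membrane_width_px)
    mem_idx = np.argwhere(membrane)

    n_sites = params.n_cluster_sites
    if n_sites > len(mem_idx):
        raise ValueError("more cluster sites than membrane pixels")
    sites = mem_idx[rng.choice(len(mem_idx), size=n_sites, replace=False)]

    r = params.cluster_radius_px
    yy, xx = np.mgrid[0:n, 0:n]
    cluster_mask = np.zeros((n, n), dtype=bool)
    for cy, cx in sites:
        cluster_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r

    base_unit = membrane.astype(float) / membrane.sum()          # sums to 1
    cluster_unit = cluster_mask.astype(float) / cluster_mask.sum()  # sums to 1

    times = params.frame_times_s
    f_t = params.clustered_fraction(times)
    frames = np.empty((len(times), 1, n, n))
    M = params.total_intensity
    for i, f in enumerate(f_t):
        img = M * ((1.0 - f) * base_unit + f * cluster_unit)
        frames[i, 0] = _apply_noise(rng, img, params.noise_model, params.noise_scale)

    stack = CalibratedStack(
        data=frames,
        pixel_size_um=params.pixel_size_um,
        frame_interval_min=params.frame_interval_s / 60.0,
        channel_name="Delta-GFP-CRY2",
    )
    truth = ClusterMovieTruth(
        f_t=f_t,
        frame_times_s=times,
        membrane_mask=membrane,
        cluster_mask=cluster_mask,
        cluster_sites=sites,
        params=params,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Interface images (membrane ridges in a two-region cell lattice)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterfaceImageParams:
    """Parameters of the two-region cell-lattice interface image.

    Each cell edge is a ridge with Gaussian cross-section of standard
    deviation ``ridge_sigma_um``.  Cells in the left half of the image
    belong to region 1 ("ectoderm"), cells in the right half to region 2
    ("mesoderm"); mesoderm ridge amplitude is
    ``membrane_amplitude * depletion_factor`` (the default 0.3 encodes a
    ~70% membrane depletion) and each region has its own flat cytoplasm
    level.
    """

    n_cells_x: int = 10
    n_cells_y: int = 6
    cell_size_px: int = 24
    ridge_sigma_um: float = 0.15
    membrane_amplitude: float = 1000.0
    depletion_factor: float = 0.3
    cytoplasm_level_ectoderm: float = 10.0
    cytoplasm_level_mesoderm: float = 10.0
    noise_model: str = "none"
    noise_scale: float = 0.0
    pixel_size_um: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        _check_positive("membrane_amplitude", self.membrane_amplitude, strict=False)
        _check_positive("depletion_factor", self.depletion_factor, strict=False)
        _check_positive("ridge_sigma_um", self.ridge_sigma_um)
        _check_positive("pixel_size_um", self.pixel_size_um)
        _check_positive("cytoplasm_level_ectoderm", self.cytoplasm_level_ectoderm, strict=False)
        _check_positive("cytoplasm_level_mesoderm", self.cytoplasm_level_mesoderm, strict=False)
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {_NOISE_MODELS}")
        if self.n_cells_x < 2:
            raise ValueError("need at least 2 cell columns to have two regions")


@dataclass
class InterfaceImageTruth:
    skeleton: np.ndarray           # membrane centreline mask
    cell_labels: np.ndarray        # per-cell integer labels, 1-based
    region_labels: np.ndarray      # 1 = ectoderm, 2 = mesoderm
    ridge_amplitude: dict
    cytoplasm_level: dict
    params: InterfaceImageParams


def gen_interface_image(
    params: InterfaceImageParams,
) -> tuple[CalibratedStack, dict, InterfaceImageTruth]:
    """Simulate a two-region cell lattice with membrane ridges.

    Returns the image stack, a dict of label masks (``cells``,
    ``regions``) and the ground truth.
    """
    from scipy import ndimage

    rng = np.random.default_rng(params.seed)
    cell = params.cell_size_px
    h = params.n_cells_y * cell + 1
    w = params.n_cells_x * cell + 1

    skeleton = np.zeros((h, w), dtype=bool)
    skeleton[::cell, :] = True
    skeleton[:, ::cell] = True

    cell_labels = np.zeros((h, w), dtype=np.int32)
    region_labels = np.zeros((h, w), dtype=np.int32)
    mid_col = params.n_cells_x // 2
    lab = 0
    for j in range(params.n_cells_y):
        for i in range(params.n_cells_x):
            lab += 1
            sl = (slice(j * cell, (j + 1) * cell + 1), slice(i * cell, (i + 1) * cell + 1))
            cell_labels[sl] = lab
            region_labels[sl] = 1 if i < mid_col else 2

    sigma_px = params.ridge_sigma_um / params.pixel_size_um
    dist = ndimage.distance_transform_edt(~skeleton)
    amp_ecto = params.membrane_amplitude
    amp_meso = params.membrane_amplitude * params.depletion_factor
    amp_map = np.where(region_labels == 1, amp_ecto, amp_meso)
    cyt_map = np.where(
        region_labels == 1, params.cytoplasm_level_ectoderm, params.cytoplasm_level_mesoderm
    )
    img = amp_map * np.exp(-(dist ** 2) / (2.0 * sigma_px ** 2)) + cyt_map
    img = _apply_noise(rng, img, params.noise_model, params.noise_scale)

    stack = CalibratedStack(data=img, pixel_size_um=params.pixel_size_um, channel_name="Delta")
    truth = InterfaceImageTruth(
        skeleton=skeleton,
        cell_labels=cell_labels,
        region_labels=region_labels,
        ridge_amplitude={"ectoderm": amp_ecto, "mesoderm": amp_meso},
        cytoplasm_level={
            "ectoderm": params.cytoplasm_level_ectoderm,
            "mesoderm": params.cytoplasm_level_mesoderm,
        },
        params=params,
    )
    return stack, {"cells": cell_labels, "regions": region_labels}, truth


# ---------------------------------------------------------------------------
# Two-channel vesicle fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesicleFieldParams:
    """Parameters of the two-channel vesicle colocalization field.

    Channel A holds ``n_vesicles`` spots.  A Bernoulli(``overlap_fraction``)
    subset gets a channel-B partner whose disk mask shares at least one
    pixel with the A disk; the remaining B spots are placed at least
    ``exclusion_px`` away from every A centre so that no pixel is shared
    even after segmentation broadens the masks.  Default overlap 0.75.
    """

    n_vesicles: int = 200
    overlap_fraction: float = 0.75
    vesicle_radius_px: float = 2.0
    frame_size_px: int = 360
    amplitude: float = 800.0
    background_level: float = 20.0
    min_separation_px: float = 16.0
    exclusion_px: float = 16.0
    noise_model: str = "none"
    noise_scale: float = 0.0
    pixel_size_um: float = 0.13
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError(f"overlap_fraction must be in [0, 1], got {self.overlap_fraction}")
        _check_positive("vesicle_radius_px", self.vesicle_radius_px)
        _check_positive("amplitude", self.amplitude)
        _check_positive("pixel_size_um", self.pixel_size_um)
        if self.n_vesicles < 1:
            raise ValueError("need at least one vesicle")
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {_NOISE_MODELS}")


@dataclass
class VesicleFieldTruth:
    centers_a: np.ndarray          # (n, 2) of (y, x)
    centers_b: np.ndarray
    overlaps: np.ndarray           # bool per A vesicle
    mask_a: np.ndarray
    mask_b: np.ndarray
    params: VesicleFieldParams

    @property
    def n_overlapping(self) -> int:
        return int(self.overlaps.sum())

    @property
    def realized_overlap_percent(self) -> float:
        return 100.0 * self.overlaps.mean()


def gen_vesicle_field(
    params: VesicleFieldParams,
) -> tuple[CalibratedStack, CalibratedStack, VesicleFieldTruth]:
    """Simulate a two-channel vesicle field with a set overlap fraction."""
    rng = np.random.default_rng(params.seed)
    n = params.frame_size_px
    sep = params.min_separation_px
    margin = sep / 2.0 + params.vesicle_radius_px + 2.0

    # grid-based placement guarantees the minimum separation and gives a
    # clean capacity check
    step = sep
    coords = np.arange(margin, n - margin, step)
    grid = np.array([(y, x) for y in coords for x in coords])
    if len(grid) < params.n_vesicles:
        raise ValueError(
            f"cannot place {params.n_vesicles} vesicles of separation {sep} px "
            f"in a {n}x{n} frame"
        )
    # jitter small enough that the guaranteed centre separation stays above
    # the blob-merging distance of the downstream detector (~2*sqrt(2)*sigma)
    jitter = rng.uniform(-1.5, 1.5, size=(len(grid), 2))
    grid = grid + jitter
    centers_a = grid[rng.choice(len(grid), size=params.n_vesicles, replace=False)]

    overlaps = rng.random(params.n_vesicles) < params.overlap_fraction
    r = params.vesicle_radius_px
    centers_b = np.empty_like(centers_a)
    for i, (cy, cx) in enumerate(centers_a):
        if overlaps[i]:
            # partner within one radius: disks of equal radius always share pixels
            ang = rng.uniform(0, 2 * math.pi)
            d = rng.uniform(0, r / 2.0)
            centers_b[i] = (cy + d * math.sin(ang), cx + d * math.cos(ang))
        else:
            centers_b[i] = _place_away(rng, n, margin, centers_a, params.exclusion_px)

    yy, xx = np.mgrid[0:n, 0:n]

    def render(centers):
        img = np.full((n, n), float(params.background_level))
        mask = np.zeros((n, n), dtype=bool)
        for cy, cx in centers:
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            img += params.amplitude * np.exp(-d2 / (2.0 * r * r))
            mask |= d2 <= r * r
        return img, mask

    img_a, mask_a = render(centers_a)
    img_b, mask_b = render(centers_b)
    img_a = _apply_noise(rng, img_a, params.noise_model, params.noise_scale)
    img_b = _apply_noise(rng, img_b, params.noise_model, params.noise_scale)

    stack_a = CalibratedStack(data=img_a, pixel_size_um=params.pixel_size_um, channel_name="Delta")
    stack_b = CalibratedStack(data=img_b, pixel_size_um=params.pixel_size_um, channel_name="Rab5")
    truth = VesicleFieldTruth(
        centers_a=centers_a,
        centers_b=centers_b,
        overlaps=overlaps,
        mask_a=mask_a,
        mask_b=mask_b,
        params=params,
    )
    return stack_a, stack_b, truth


def _place_away(rng, n, margin, centers, exclusion, max_tries=10_000):
    for _ in range(max_tries):
        cand = rng.uniform(margin, n - margin, size=2)
        d = np.sqrt(((centers - cand) ** 2).sum(axis=1))
        if d.min() >= exclusion:
            return cand
    raise ValueError("could not place a non-overlapping vesicle; frame too crowded")


# ---------------------------------------------------------------------------
# Mosaic clone tissues
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloneTissueParams:
    """Parameters of the mosaic clone tissue generator.

    The clone occupies the left half of the tissue (``x < boundary_x``).
    ``n_proneural_clusters`` boundary-straddling proneural clusters each
    produce one SOP, which falls inside the clone with probability
    ``exp(beta) / (1 + exp(beta))``; ``bias_beta = 0`` reproduces the
    50:50 null of an unbiased fate decision at a clone border.
    """

    tissue_size_px: int = 256
    n_proneural_clusters: int = 30
    cluster_radius_px: int = 6
    bias_beta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.bias_beta) or np.isposinf(self.bias_beta) or np.isneginf(self.bias_beta)):
            raise ValueError("bias_beta must be a real number (or +/-inf for saturation)")
        if self.n_proneural_clusters < 1:
            raise ValueError("need at least one proneural cluster")
        if self.cluster_radius_px < 1 or self.tissue_size_px < 4 * self.cluster_radius_px:
            raise ValueError("tissue too small for the cluster radius")

    @property
    def p_inside(self) -> float:
        """Probability that a boundary SOP falls inside the clone."""
        if np.isposinf(self.bias_beta):
            return 1.0
        if np.isneginf(self.bias_beta):
            return 0.0
        return 1.0 / (1.0 + math.exp(-self.bias_beta))


@dataclass
class CloneTissueTruth:
    inside: np.ndarray             # bool per cluster
    cluster_y: np.ndarray
    p_inside: float
    params: CloneTissueParams


def gen_clone_tissue(
    params: CloneTissueParams,
) -> tuple[np.ndarray, pd.DataFrame, CloneTissueTruth]:
    """Simulate a mosaic tissue: clone mask, SOP point list and ground truth."""
    rng = np.random.default_rng(params.seed)
    n = params.tissue_size_px
    bx = n // 2
    clone_mask = np.zeros((n, n), dtype=bool)
    clone_mask[:, :bx] = True

    r = params.cluster_radius_px
    ys = rng.uniform(r, n - r, params.n_proneural_clusters)
    inside = rng.random(params.n_proneural_clusters) < params.p_inside

    sop_x = np.where(
        inside,
        bx - rng.uniform(1.0, r, params.n_proneural_clusters),
        bx + rng.uniform(0.0, r - 1.0, params.n_proneural_clusters),
    )
    sop_y = ys + rng.uniform(-1.0, 1.0, params.n_proneural_clusters)
    sop_y = np.clip(sop_y, 0, n - 1)

    sops = pd.DataFrame(
        {"sop_id": np.arange(params.n_proneural_clusters), "x_px": sop_x, "y_px": sop_y}
    )
    truth = CloneTissueTruth(inside=inside, cluster_y=ys, p_inside=params.p_inside, params=params)
    return clone_mask, sops, truth
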