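"""Membrane cluster segmentation, clustering index and half-time kinetics.

Light-induced oligomerization of a membrane ligand redistributes a fixed
amount of signal into bright clusters.  The per-frame summary statistic
is the clustering index

    index = (number of clusters x mean cluster intensity) / total image intensity
          = (sum of intensity inside clusters) / total image intensity,

a number in [0, 1]: the fraction of the frame's signal locked into
clusters.  Mean cluster intensity here is the mean of the per-cluster
*integrated* intensities, so the numerator is exactly the summed
intensity inside all clusters.

The rise of the index over time is fitted with an exponential approach
to plateau parameterized by its half-time,

    index(t) = P * (1 - 2**(-t / t_half)).

Cluster segmentation is a robust threshold (median + m * MAD over the
signal-bearing pixels) plus a minimum-size filter; both statistics scale
with the image, so segmentation and the index are invariant under
intensity rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

__all__ = [
    "ClusterConfig",
    "ClusterSeries",
    "ClusterKinetics",
    "HalfTimeResult",
    "segment_clusters",
    "clustering_index",
    "build_cluster_series",
    "estimate_half_time",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Robust-threshold segmentation settings.

    ``mad_factor`` is the multiple of the median absolute deviation added
    to the median to form the threshold; statistics are computed over the
    strictly positive pixels so a large zero background does not drag the
    threshold down.  ``min_size_px`` rejects specks.
    """

    mad_factor: float = 3.0
    min_size_px: int = 2
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.mad_factor < 0:
            raise ValueError("mad_factor must be >= 0")
        if self.min_size_px < 1:
            raise ValueError("min_size_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def segment_clusters(frame: np.ndarray, cfg: ClusterConfig | None = None) -> np.ndarray:
    """Label connected pixel groups above a robust intensity threshold.

    Returns an int32 label image; a degenerate flat frame yields zero
    clusters.
    """
    cfg = cfg or ClusterConfig()
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    support = frame > 0
    if not support.any():
        return np.zeros(frame.shape, dtype=np.int32)
    vals = frame[support]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    thr = med + cfg.mad_factor * mad
    mask = frame > thr
    structure = ndimage.generate_binary_structure(2, 2 if cfg.connectivity == 8 else 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels, float), labels, np.arange(1, n + 1))
        keep = np.arange(1, n + 1)[sizes >= cfg.min_size_px]
        lut = np.zeros(n + 1, dtype=np.int32)
        lut[keep] = np.arange(1, len(keep) + 1)
        labels = lut[labels]
    return labels.astype(np.int32)


def clustering_index(frame: np.ndarray, clusters: np.ndarray) -> float:
    """Fraction of total image intensity residing in the segmented clusters.

    Returns NaN (with a warning) if the total intensity is not positive,
    where the index is undefined.
    """
    frame = np.asarray(frame, dtype=float)
    total = frame.sum()
    if total <= 0:
        warnings.warn("clustering index undefined: total image intensity <= 0")
        return float("nan")
    inside = frame[clusters > 0].sum()
    return float(inside / total)


@dataclass
class ClusterSeries:
    """Per-frame cluster statistics over a movie."""

    times_s: np.ndarray
    n_clusters: np.ndarray
    mean_cluster_intensity: np.ndarray
    total_image_intensity: np.ndarray
    index: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)

    def __len__(self) -> int:
        return len(self.times_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "n_clusters": self.n_clusters,
                "mean_cluster_intensity": self.mean_cluster_intensity,
                "total_image_intensity": self.total_image_intensity,
                "clustering_index": self.index,
            }
        )

    def relative_to_plateau(self) -> np.ndarray:
        """Index normalized to its final value, for plotting a relative rise."""
        final = self.index[-1]
        if not np.isfinite(final) or final <= 0:
            raise ValueError("cannot normalize: final index is not positive")
        return self.index / final


def build_cluster_series(stack, cfg: ClusterConfig | None = None, z: int = 0) -> ClusterSeries:
    """Segment every frame of a movie and assemble the cluster series."""
    cfg = cfg or ClusterConfig()
    n_cl, mean_int, totals, idxs = [], [], [], []
    for t in range(stack.n_frames):
        frame = stack.frame(t, z)
        labels = segment_clusters(frame, cfg)
        n = int(labels.max())
        n_cl.append(n)
        if n:
            sums = ndimage.sum_labels(frame, labels, np.arange(1, n + 1))
            mean_int.append(float(np.mean(sums)))
        else:
            mean_int.append(0.0)
        totals.append(float(frame.sum()))
        idxs.append(clustering_index(frame, labels) if frame.sum() > 0 else np.nan)
    times_s = stack.frame_times_min * 60.0
    return ClusterSeries(
        times_s=times_s - times_s[0],
        n_clusters=np.asarray(n_cl),
        mean_cluster_intensity=np.asarray(mean_int),
        total_image_intensity=np.asarray(totals),
        index=np.asarray(idxs),
    )


# ---------------------------------------------------------------------------
# Half-time kinetics
# ---------------------------------------------------------------------------

def _half_time_model(t, plateau, t_half):
    return plateau * (1.0 - 2.0 ** (-np.asarray(t, dtype=float) / t_half))


@dataclass
class HalfTimeResult:
    """Fitted exponential-approach parameters for the clustering rise."""

    t_half_s: float
    plateau: float
    rss: float
    n_points: int
    converged: bool

    def predict(self, t) -> np.ndarray:
        return _half_time_model(t, self.plateau, self.t_half_s)

    def summary(self) -> str:
        return (
            "Clustering half-time fit\n"
            "========================\n"
            f"t_half:    {self.t_half_s:.6g} s\n"
            f"plateau:   {self.plateau:.6g}\n"
            f"rss:       {self.rss:.6g}\n"
            f"n_points:  {self.n_points}\n"
            f"converged: {self.converged}"
        )


class ClusterKinetics:
    """Least-squares half-time model of a clustering-index series."""

    def __init__(self, series: ClusterSeries):
        valid = np.isfinite(series.index)
        if valid.sum() < 5:
            raise ValueError("need at least 5 valid frames spanning the rise")
        self.t = series.times_s[valid]
        self.y = series.index[valid]

    def fit(self) -> HalfTimeResult:
        t, y = self.t, self.y
        y_max = y.max()
        if y_max <= 0 or y[-1] < 0.05 * y_max or np.ptp(y) < 1e-12:
            return HalfTimeResult(
                t_half_s=float("nan"), plateau=float("nan"),
                rss=float(np.sum((y - y.mean()) ** 2)), n_points=len(t),
                converged=False,
            )

        def resid(p):
            return _half_time_model(t, p[0], p[1]) - y

        span = max(t[-1] - t[0], 1.0)
        best = None
        for th0 in np.geomspace(span / 100.0, span, 7):
            sol = optimize.least_squares(
                resid, x0=[y_max, th0],
                bounds=([0.0, 1e-9], [np.inf, np.inf]),
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
            )
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol)
        rss, sol = best
        return HalfTimeResult(
            t_half_s=float(sol.x[1]), plateau=float(sol.x[0]),
            rss=rss, n_points=len(t), converged=bool(sol.success),
        )


def estimate_half_time(series: ClusterSeries) -> HalfTimeResult:
    """Convenience wrapper: ``ClusterKinetics(series).fit()``."""
    return ClusterKinetics(series).fit()
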