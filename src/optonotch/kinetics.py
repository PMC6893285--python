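"""Activation-kinetics curves, saturating-exponential fits and condition comparisons.

The tissue-level activation of a Notch target is summarized as a
spot-density curve (spots per micrometre of tissue length over time, with
times aligned so the onset of ventral-furrow formation is t = 0) and
fitted with a saturating exponential

    N(t) = N_max * (1 - exp(-k * (t - t0))),   N(t) = 0 for t < t0,

where ``N_max`` is the maximum number of spots that can be activated
(the nucleus census, held constant during fitting), ``k`` the
per-nucleus activation rate (1/min) and ``t0`` the onset delay (min).
Only ``k`` and ``t0`` are adjusted.  The model is clamped to zero before
``t0``.

The fitting API follows the model/results convention: build an
:class:`ActivationKinetics` model from a curve, call :meth:`fit`, and
read estimates and diagnostics off the returned
:class:`ActivationKineticsResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ActivationCurve",
    "ActivationKinetics",
    "ActivationKineticsResults",
    "StabilityReport",
    "saturating_exponential",
    "build_activation_curve",
    "curve_from_onsets",
    "fit_activation",
    "compare_conditions",
    "spot_intensity_stability",
    "percent_of_control",
]


def saturating_exponential(t, n_max, k, t0):
    """``n_max * (1 - exp(-k (t - t0)))``, clamped to 0 for ``t < t0``."""
    t = np.asarray(t, dtype=float)
    out = n_max * (1.0 - np.exp(-k * (t - t0)))
    return np.where(t < t0, 0.0, out)


@dataclass
class ActivationCurve:
    """Spot-density time series for one embryo/condition.

    ``times`` are minutes (strictly increasing; align so ventral-furrow
    onset is t = 0 by passing ``alignment_time`` to the builders);
    ``density`` is spots per micrometre of tissue length; ``counts`` are
    the raw per-frame spot counts.
    """

    times: np.ndarray
    density: np.ndarray
    counts: np.ndarray | None = None
    region_length_um: float | None = None
    embryo_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.density.shape:
            raise ValueError("times and density must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)

    def __len__(self) -> int:
        return len(self.times)


def build_activation_curve(
    spots,
    region_length_um: float,
    alignment_time: float = 0.0,
    frame_times_min=None,
    embryo_id: str = "",
    condition: str = "",
) -> ActivationCurve:
    """Per-frame spot counts divided by tissue length, on a shifted time axis.

    ``spots`` is a :class:`~optonotch.spotcall.SpotSet`; its recorded
    frame times are used unless ``frame_times_min`` overrides them.
    ``alignment_time`` is subtracted from all times (e.g. the
    ventral-furrow onset time).  An empty spot set yields a curve of
    zeros, which is valid data, not an error.
    """
    if region_length_um <= 0:
        raise ValueError("region_length_um must be positive")
    times = np.asarray(
        frame_times_min if frame_times_min is not None else spots.frame_times_min,
        dtype=float,
    )
    counts = spots.counts_per_frame()
    if len(times) != len(counts):
        raise ValueError("frame times do not match the number of frames")
    return ActivationCurve(
        times=times - alignment_time,
        density=counts / region_length_um,
        counts=counts,
        region_length_um=region_length_um,
        embryo_id=embryo_id,
        condition=condition,
    )


def curve_from_onsets(
    onset_times,
    times,
    region_length_um: float,
    embryo_id: str = "",
    condition: str = "",
) -> ActivationCurve:
    """Ground-truth activation curve: cumulative onsets <= t per unit length.

    The irreversible-switch oracle for generator-based tests and for
    curves built directly from recorded onset times.
    """
    if region_length_um <= 0:
        raise ValueError("region_length_um must be positive")
    onset_times = np.asarray(onset_times, dtype=float)
    times = np.asarray(times, dtype=float)
    counts = np.array([(onset_times <= t).sum() for t in times])
    return ActivationCurve(
        times=times,
        density=counts / region_length_um,
        counts=counts,
        region_length_um=region_length_um,
        embryo_id=embryo_id,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------

@dataclass
class ActivationKineticsResults:
    """Fitted saturating-exponential parameters and diagnostics."""

    k: float
    t0: float
    n_max: float
    rss: float
    n_points: int
    converged: bool
    curve: ActivationCurve | None = None

    def predict(self, t) -> np.ndarray:
        scale = self.n_max
        if self.curve is not None and self.curve.region_length_um:
            scale = self.n_max / self.curve.region_length_um
        return saturating_exponential(t, scale, self.k, self.t0)

    def summary(self) -> str:
        lines = [
            "Saturating-exponential activation fit",
            "=====================================",
            f"embryo:     {self.curve.embryo_id if self.curve else ''}",
            f"condition:  {self.curve.condition if self.curve else ''}",
            f"N_max:      {self.n_max:g} spots (held constant)",
            f"k:          {self.k:.6g} 1/min",
            f"t0:         {self.t0:.6g} min",
            f"rss:        {self.rss:.6g}",
            f"n_points:   {self.n_points}",
            f"converged:  {self.converged}",
        ]
        return "\n".join(lines)


class ActivationKinetics:
    """Least-squares saturating-exponential model of an activation curve.

    Parameters
    ----------
    curve
        The observed spot-density curve.
    n_max
        Maximum number of activatable spots (nucleus census).  Held
        constant; only ``k`` and ``t0`` are free.  When the curve has a
        known ``region_length_um``, the model is fitted in density units
        (``n_max / length``).

    The optimizer is deterministic: a fixed grid of ``(k, t0)`` starting
    values is refined with :func:`scipy.optimize.least_squares` and the
    best final residual wins.
    """

    def __init__(self, curve: ActivationCurve, n_max: float):
        if n_max <= 0:
            raise ValueError("n_max must be positive")
        if len(curve) < 3:
            raise ValueError("need at least 3 time points to fit")
        self.curve = curve
        self.n_max = float(n_max)

    def _plateau(self) -> float:
        if self.curve.region_length_um:
            return self.n_max / self.curve.region_length_um
        return self.n_max

    def fit(self, k_grid=None, t0_grid=None) -> ActivationKineticsResults:
        t = self.curve.times
        y = self.curve.density
        n = len(t)
        if not np.any(y > 0):
            return ActivationKineticsResults(
                k=float("nan"), t0=float("nan"), n_max=self.n_max,
                rss=float(np.sum(y ** 2)), n_points=n, converged=False,
                curve=self.curve,
            )
        plateau = self._plateau()
        first_pos = t[np.argmax(y > 0)]
        if k_grid is None:
            k_grid = np.geomspace(0.01, 3.0, 8)
        if t0_grid is None:
            lo = t[0]
            t0_grid = np.unique(np.concatenate([
                np.linspace(lo, first_pos, 6),
                [first_pos - (t[1] - t[0])],
            ]))

        def resid(p):
            k, t0 = p
            return saturating_exponential(t, plateau, k, t0) - y

        best = None
        span = t[-1] - t[0]
        atol = 1e-24 * max(1.0, float(np.sum(y ** 2)))
        for k0 in k_grid:
            if best is not None and best[0] <= atol:
                break  # an (effectively) exact fit cannot be improved
            for t00 in t0_grid:
                sol = optimize.least_squares(
                    resid, x0=[k0, t00],
                    bounds=([0.0, t[0] - span], [np.inf, t[-1]]),
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
                rss = float(np.sum(sol.fun ** 2))
                if best is None or rss < best[0]:
                    best = (rss, sol)
        rss, sol = best
        return ActivationKineticsResults(
            k=float(sol.x[0]), t0=float(sol.x[1]), n_max=self.n_max,
            rss=rss, n_points=n, converged=bool(sol.success),
            curve=self.curve,
        )


def fit_activation(curve: ActivationCurve, n_max: float) -> ActivationKineticsResults:
    """Convenience wrapper: ``ActivationKinetics(curve, n_max).fit()``."""
    return ActivationKinetics(curve, n_max).fit()


# ---------------------------------------------------------------------------
# Condition comparisons
# ---------------------------------------------------------------------------

def compare_conditions(
    fits: list[ActivationKineticsResults],
    control: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-condition summary of fitted (k, t0) with Welch tests vs control.

    ``fits`` must carry their curves (for the condition labels).  Returns
    one row per condition with mean +/- s.e.m. of ``k`` and ``t0``, the
    differences to the control means, Welch two-sample t-test p-values
    against the control, and significance flags at ``alpha``.  A
    condition with a single embryo is reported without p-values.
    """
    rows = {}
    for f in fits:
        cond = f.curve.condition if f.curve else ""
        rows.setdefault(cond, []).append(f)
    if control not in rows:
        raise ValueError(f"control condition {control!r} not present")

    def arr(fs, attr):
        return np.array([getattr(f, attr) for f in fs if np.isfinite(getattr(f, attr))])

    ctrl_k = arr(rows[control], "k")
    ctrl_t0 = arr(rows[control], "t0")
    out = []
    for cond, fs in rows.items():
        ks, t0s = arr(fs, "k"), arr(fs, "t0")
        rec = {
            "condition": cond,
            "n_embryos": len(fs),
            "k_mean": ks.mean() if len(ks) else np.nan,
            "k_sem": stats.sem(ks) if len(ks) > 1 else np.nan,
            "t0_mean": t0s.mean() if len(t0s) else np.nan,
            "t0_sem": stats.sem(t0s) if len(t0s) > 1 else np.nan,
        }
        rec["delta_rate"] = rec["k_mean"] - ctrl_k.mean()
        rec["delta_onset_delay"] = rec["t0_mean"] - ctrl_t0.mean()
        if cond == control or len(ks) < 2 or len(ctrl_k) < 2:
            rec["p_rate"] = np.nan
            rec["p_onset_delay"] = np.nan
        else:
            rec["p_rate"] = stats.ttest_ind(ks, ctrl_k, equal_var=False).pvalue
            rec["p_onset_delay"] = stats.ttest_ind(t0s, ctrl_t0, equal_var=False).pvalue
        rec["significant_rate"] = bool(rec["p_rate"] < alpha) if np.isfinite(rec["p_rate"]) else False
        rec["significant_onset_delay"] = (
            bool(rec["p_onset_delay"] < alpha) if np.isfinite(rec["p_onset_delay"]) else False
        )
        out.append(rec)
    return pd.DataFrame(out).set_index("condition")


def percent_of_control(curve: ActivationCurve, control_plateau_density: float) -> np.ndarray:
    """Density expressed as a percentage of the control plateau density."""
    if control_plateau_density <= 0:
        raise ValueError("control plateau density must be positive")
    return 100.0 * curve.density / control_plateau_density


# ---------------------------------------------------------------------------
# Spot-intensity stability
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Temporal vs population variability of spot intensities.

    ``cv_over_time`` is the mean over tracked spots of each spot's
    coefficient of variation across frames (how much an individual
    transcription site fluctuates over time); ``cv_within_timepoint`` is
    the mean over frames of the CV across spots within that frame (how
    different spots are from each other at a given moment).  A digital
    (ON/OFF) reporter shows a small temporal CV next to a large
    population CV.
    """

    cv_over_time: float
    cv_within_timepoint: float
    n_spots: int
    n_frames: int

    def summary(self) -> str:
        return (
            "Spot-intensity stability\n"
            "========================\n"
            f"CV over time (per spot):      {100 * self.cv_over_time:.1f}%\n"
            f"CV within time point:         {100 * self.cv_within_timepoint:.1f}%\n"
            f"n_spots={self.n_spots}  n_frames={self.n_frames}"
        )


def spot_intensity_stability(tracked: pd.DataFrame) -> StabilityReport:
    """Compute the stability report from tracked spot intensities.

    ``tracked`` is long-format with columns ``nucleus_id`` (track id),
    ``frame`` and ``intensity``.  Requires at least 2 frames overall and
    at least one frame with >= 2 spots.
    """
    required = {"nucleus_id", "frame", "intensity"}
    if not required.issubset(tracked.columns):
        raise ValueError(f"tracked table needs columns {sorted(required)}")
    df = tracked.dropna(subset=["intensity"])
    if df["frame"].nunique() < 2:
        raise ValueError("need spots in at least 2 frames")

    def cv(x):
        x = np.asarray(x, dtype=float)
        m = x.mean()
        return x.std(ddof=1) / m if len(x) > 1 and m > 0 else np.nan

    per_track = df.groupby("nucleus_id")["intensity"].apply(cv).dropna()
    per_frame = df.groupby("frame")["intensity"].apply(cv).dropna()
    if not len(per_frame):
        raise ValueError("no frame has >= 2 spots; cannot compute within-frame CV")
    if not len(per_track):
        raise ValueError("no track spans >= 2 frames; cannot compute temporal CV")
    return StabilityReport(
        cv_over_time=float(per_track.mean()),
        cv_within_timepoint=float(per_frame.mean()),
        n_spots=int(df["nucleus_id"].nunique()),
        n_frames=int(df["frame"].nunique()),
    )
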