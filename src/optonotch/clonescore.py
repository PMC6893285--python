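"""Clone-border SOP scoring and proportion statistics.

In a mosaic tissue, sensory organ precursors (SOPs) arising from
proneural clusters that straddle a clone boundary are scored by which
side of the boundary they fall on.  Under the null of unbiased lateral
inhibition there is a 50% chance for an SOP to sit on either side; a
shift away from 50% indicates impaired signal sending or receiving in
the clone.

Per-pupa tallies are summarized as mean +/- s.d. of the inside
percentage across pupae; the pooled counts are tested against 0.5 with
an exact two-sided binomial test, and two conditions are compared with a
Welch t-test on the per-pupa percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "CloneBorderTally",
    "ProportionSummary",
    "GenotypeRatioResult",
    "score_border_sops",
    "summarize_tallies",
    "genotype_ratio_test",
]


@dataclass
class CloneBorderTally:
    """Boundary-SOP counts for one pupa."""

    pupa_id: str
    condition: str
    n_sop_border: int
    n_inside: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_inside <= self.n_sop_border):
            raise ValueError("n_inside must be between 0 and n_sop_border")

    @property
    def percent_inside(self) -> float:
        if self.n_sop_border == 0:
            return float("nan")
        return 100.0 * self.n_inside / self.n_sop_border


def score_border_sops(
    clone_mask: np.ndarray,
    sops,
    border_band_px: float,
    pupa_id: str = "",
    condition: str = "",
) -> CloneBorderTally:
    """Tally boundary SOPs by clone side.

    ``sops`` is an (n, 2) array of (x, y) pixel positions or a DataFrame
    with ``x_px``/``y_px`` columns.  An SOP is "at the border" when its
    Euclidean distance to the clone boundary is at most
    ``border_band_px``; it is "inside" when the clone mask is True at its
    position.  A tissue whose SOPs all lie deep in the bulk yields a
    tally with ``n_sop_border = 0`` (valid, excluded from summaries).
    """
    clone_mask = np.asarray(clone_mask, dtype=bool)
    if not clone_mask.any() or clone_mask.all():
        raise ValueError("clone mask must contain both inside and outside pixels")
    if isinstance(sops, pd.DataFrame):
        xy = sops[["x_px", "y_px"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(sops, dtype=float).reshape(-1, 2)

    # distance to the boundary: for inside pixels the distance to the
    # nearest outside pixel, and vice versa (minus half a pixel so that a
    # pixel adjacent to the boundary line is at distance ~0.5)
    d_in = ndimage.distance_transform_edt(clone_mask)
    d_out = ndimage.distance_transform_edt(~clone_mask)
    dist_to_boundary = np.where(clone_mask, d_in, d_out) - 0.5

    n_border = 0
    n_inside = 0
    for x, y in xy:
        iy = int(np.clip(round(y), 0, clone_mask.shape[0] - 1))
        ix = int(np.clip(round(x), 0, clone_mask.shape[1] - 1))
        if dist_to_boundary[iy, ix] <= border_band_px:
            n_border += 1
            if clone_mask[iy, ix]:
                n_inside += 1
    return CloneBorderTally(
        pupa_id=pupa_id, condition=condition,
        n_sop_border=n_border, n_inside=n_inside,
    )


@dataclass
class ProportionSummary:
    """Per-condition summary of clone-border tallies.

    ``table`` has one row per condition: number of pupae, mean and s.d.
    of the per-pupa inside percentage, pooled counts, and the exact
    two-sided binomial p-value of the pooled counts against 0.5.
    ``pairwise_p`` maps condition pairs to Welch t-test p-values on the
    per-pupa percentages.
    """

    table: pd.DataFrame
    pairwise_p: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Clone-border SOP summary", "========================"]
        for cond, row in self.table.iterrows():
            lines.append(
                f"{cond}: {row['mean_percent_inside']:.1f} +/- "
                f"{row['sd_percent_inside']:.1f}% inside "
                f"(N = {int(row['n_pupae'])} pupae, pooled "
                f"{int(row['pooled_inside'])}/{int(row['pooled_border'])}, "
                f"binomial p vs 50% = {row['p_binomial_vs_half']:.3g})"
            )
        for (a, b), p in self.pairwise_p.items():
            lines.append(f"{a} vs {b}: Welch t-test p = {p:.3g}")
        return "\n".join(lines)


def summarize_tallies(tallies: list[CloneBorderTally]) -> ProportionSummary:
    """Summarize tallies per condition and compare conditions pairwise.

    Pupae with zero border SOPs are excluded.  Raises if a condition ends
    up with no valid tally.
    """
    valid = [t for t in tallies if t.n_sop_border > 0]
    conditions: dict[str, list[CloneBorderTally]] = {}
    for t in valid:
        conditions.setdefault(t.condition, []).append(t)
    if not conditions:
        raise ValueError("no tallies with border SOPs")

    rows = []
    percents: dict[str, np.ndarray] = {}
    for cond, ts in conditions.items():
        p = np.array([t.percent_inside for t in ts])
        percents[cond] = p
        pooled_in = sum(t.n_inside for t in ts)
        pooled_n = sum(t.n_sop_border for t in ts)
        rows.append(
            {
                "condition": cond,
                "n_pupae": len(ts),
                "mean_percent_inside": p.mean(),
                "sd_percent_inside": p.std(ddof=1) if len(p) > 1 else 0.0,
                "pooled_inside": pooled_in,
                "pooled_border": pooled_n,
                "p_binomial_vs_half": stats.binomtest(pooled_in, pooled_n, 0.5).pvalue,
            }
        )
    table = pd.DataFrame(rows).set_index("condition")

    pairwise = {}
    conds = list(conditions)
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            if len(percents[a]) > 1 and len(percents[b]) > 1:
                pairwise[(a, b)] = float(
                    stats.ttest_ind(percents[a], percents[b], equal_var=False).pvalue
                )
            else:
                pairwise[(a, b)] = float("nan")
    return ProportionSummary(table=table, pairwise_p=pairwise)


@dataclass
class GenotypeRatioResult:
    """Observed genotype proportion and exact binomial test vs 50:50."""

    count_a: int
    count_b: int
    percent_a: float
    p_value: float

    def summary(self) -> str:
        return (
            f"{self.count_a}:{self.count_b} "
            f"({self.percent_a:.1f}% : {100 - self.percent_a:.1f}%), "
            f"exact binomial p vs 50:50 = {self.p_value:.3g}"
        )


def genotype_ratio_test(count_a: int, count_b: int) -> GenotypeRatioResult:
    """Proportion of genotype A among hatched adults, tested against 50:50.

    Returns ``100 * a / (a + b)`` and the exact two-sided binomial
    p-value against p = 0.5.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    n = count_a + count_b
    if n == 0:
        raise ValueError("need at least one counted individual")
    p = stats.binomtest(count_a, n, 0.5).pvalue
    return GenotypeRatioResult(
        count_a=count_a, count_b=count_b,
        percent_a=100.0 * count_a / n, p_value=float(p),
    )
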