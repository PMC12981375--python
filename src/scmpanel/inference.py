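"""Placebo-based permutation inference.

Every brand in the panel is refit as if it were the intervention unit; the
resulting "false" effects form the null distribution.  The overall test
statistic is the post/pre MSE ratio, week-specific statistics are absolute
gaps, and p-values are the share of all units (placebos plus the actual
treated brand) whose statistic is at least as extreme as the treated one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ScmPanelError
from .panel_io import StudyWindows
from .scm_core import ScmFit, fit_scm
from .standardize import StandardizedPanel


def window_mse(gap: np.ndarray, window_pos: Iterable[int]) -> float:
    """Mean squared gap over the given week positions."""
    pos = np.asarray(list(window_pos), dtype=int)
    if pos.size == 0:
        raise ValueError("window must be non-empty")
    g = np.asarray(gap, dtype=float)[pos]
    return float(np.mean(g**2))


def fisher_p(
    treated_stat: float,
    placebo_stats: Sequence[float],
    include_treated: bool = True,
) -> float:
    """Share of statistics greater than or equal to the treated statistic.

    Ties count as "at least as extreme".  With ``include_treated`` the
    treated unit itself enters both numerator and denominator, so the
    smallest attainable p is ``1/(len(placebo_stats) + 1)``.
    """
    stats = np.asarray(placebo_stats, dtype=float)
    if stats.size == 0:
        raise ValueError("placebo_stats must be non-empty")
    count = int(np.sum(stats >= treated_stat))
    total = stats.size
    if include_treated:
        count += 1
        total += 1
    return count / total


@dataclass
class PlaceboDistribution:
    """Gap series, MSE ratios and permutation p-values for all brands."""

    brand_ids: list[str]
    treated_id: str
    gaps: np.ndarray  # (n_brands, n_weeks), standardized scale
    pre_mse: np.ndarray
    post_mse: np.ndarray
    mse_ratio: np.ndarray
    rank_of_treated: int
    p_overall: float
    p_weekly: dict[int, float]  # week label -> p, over intervention+post weeks
    windows: StudyWindows
    treated_fit: ScmFit
    excluded: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.brand_ids)

    def treated_index(self) -> int:
        return self.brand_ids.index(self.treated_id)


def _safe_ratio(post: float, pre: float) -> float:
    if pre > 0:
        return post / pre
    return float("inf") if post > 0 else 1.0


def placebo_analysis(
    std: StandardizedPanel,
    windows: StudyWindows,
    treated_id: str | None = None,
    exclude_treated_from_placebo_pools: bool = True,
    two_sided_weekly: bool = True,
) -> PlaceboDistribution:
    """Fit a synthetic control for every brand and rank the MSE ratios.

    The treated brand's donor pool is every other brand.  Each placebo
    brand's pool excludes both itself and (by default) the treated brand, so
    the null fits are not contaminated by the true effect.  Placebo fits
    that fail are excluded from the null distribution with a warning.
    """
    treated_id = str(treated_id if treated_id is not None else std.treated_id)
    all_ids = list(std.brand_ids)
    if treated_id not in all_ids:
        raise ValueError(f"treated brand {treated_id!r} not in standardized panel")
    if len(all_ids) < 3:
        raise ValueError("placebo analysis needs at least 3 brands")

    pre_pos = std.week_positions(windows.pre)
    post_pos = std.week_positions(windows.post)
    analysis_weeks = list(windows.intervention) + list(windows.post)

    kept: list[str] = []
    gaps: list[np.ndarray] = []
    fits: dict[str, ScmFit] = {}
    excluded: list[str] = []
    for brand in all_ids:
        donors = [b for b in all_ids if b != brand]
        if brand != treated_id and exclude_treated_from_placebo_pools:
            donors = [b for b in donors if b != treated_id]
        try:
            fit = fit_scm(std, brand, donors, windows)
        except ScmPanelError as exc:
            if brand == treated_id:
                raise
            warnings.warn(f"placebo fit failed for {brand!r}: {exc}", stacklevel=2)
            excluded.append(brand)
            continue
        kept.append(brand)
        fits[brand] = fit
        gaps.append(fit.gap)

    gap_mat = np.vstack(gaps)
    pre_mse = np.array([window_mse(g, pre_pos) for g in gap_mat])
    post_mse = np.array([window_mse(g, post_pos) for g in gap_mat])
    ratio = np.array([_safe_ratio(po, pr) for po, pr in zip(post_mse, pre_mse)])

    t_idx = kept.index(treated_id)
    rank = int(np.sum(ratio >= ratio[t_idx]))
    p_overall = rank / len(kept)

    p_weekly: dict[int, float] = {}
    week_pos = std.week_positions(analysis_weeks)
    for week, pos in zip(analysis_weeks, week_pos):
        col = gap_mat[:, pos]
        stat = np.abs(col) if two_sided_weekly else -col  # one-sided: declines extreme
        placebo = np.delete(stat, t_idx)
        p_weekly[int(week)] = fisher_p(stat[t_idx], placebo, include_treated=True)

    return PlaceboDistribution(
        brand_ids=kept,
        treated_id=treated_id,
        gaps=gap_mat,
        pre_mse=pre_mse,
        post_mse=post_mse,
        mse_ratio=ratio,
        rank_of_treated=rank,
        p_overall=p_overall,
        p_weekly=p_weekly,
        windows=windows,
        treated_fit=fits[treated_id],
        excluded=excluded,
    )


def weekly_p(placebos: PlaceboDistribution, week: int) -> float:
    """Week-specific p-value (absolute-gap statistic, treated included)."""
    week = int(week)
    if week not in placebos.p_weekly:
        raise ValueError(
            f"week {week} outside the analysis range "
            f"{sorted(placebos.p_weekly)[0]}..{sorted(placebos.p_weekly)[-1]}"
        )
    return placebos.p_weekly[week]


def mse_scatter(placebos: PlaceboDistribution) -> pd.DataFrame:
    """Per-brand MSE diagnostics sorted by descending ratio.

    Surfaces brands whose high rank is driven by a tiny pre-period MSE
    denominator rather than a large post-period divergence.
    """
    order = np.argsort(-placebos.mse_ratio, kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    frame = pd.DataFrame(
        {
            "brand": placebos.brand_ids,
            "pre_mse": placebos.pre_mse,
            "post_mse": placebos.post_mse,
            "ratio": placebos.mse_ratio,
            "rank": ranks,
            "is_treated": [b == placebos.treated_id for b in placebos.brand_ids],
        }
    )
    return frame.sort_values("rank", kind="stable").reset_index(drop=True)
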