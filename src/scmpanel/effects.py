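"""Back-transformation of standardized gaps into unit-scale effects.

Because standardization is affine per brand, the unit-scale gap is just
``standardized gap * treated scale`` (the location terms cancel in the
difference), so cumulative and percent effects are identical across
standardization methods up to the fit itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .panel_io import SalesPanel, StudyWindows
from .scm_core import ScmFit
from .standardize import StandardizedPanel, destandardize


@dataclass
class EffectSummary:
    """Policy-relevant effect sizes for one focal brand."""

    window_used: tuple[int, ...]
    cumulative_units: float  # negative = reduction
    final_week_pct: float  # 100 * (synthetic - actual) / synthetic at final week
    weekly_units_gap: np.ndarray  # full-length unit-scale gap series
    sd_gap_final: float  # standardized gap at the final analyzed week


def effect_window(windows: StudyWindows, include_intervention: bool = False) -> tuple[int, ...]:
    """Weeks over which effects are accumulated: post, or intervention+post."""
    if include_intervention:
        return tuple(windows.intervention) + tuple(windows.post)
    return tuple(windows.post)


def effect_summary(
    fit: ScmFit,
    std: StandardizedPanel,
    panel: SalesPanel,
    window: Sequence[int],
) -> EffectSummary:
    """Convert a fit's standardized gaps into unit-scale effect summaries.

    ``cumulative_units`` sums the unit-scale weekly gaps over ``window``;
    ``final_week_pct`` compares actual against destandardized synthetic
    sales at the last week of ``window``.
    """
    window = tuple(int(w) for w in window)
    if not window:
        raise ValueError("effect window must be non-empty")
    loc, scale = std.params_of(fit.focal_id)

    weekly_units_gap = fit.gap * scale
    win_pos = std.week_positions(window)
    cumulative_units = float(weekly_units_gap[win_pos].sum())

    final_week = window[-1]
    final_pos = int(std.week_positions([final_week])[0])
    syn_units = float(destandardize(fit.synthetic[final_pos], loc, scale))
    actual_units = float(panel.brand_row(fit.focal_id)[panel.week_positions([final_week])[0]])
    if syn_units <= 0:
        warnings.warn(
            "destandardized synthetic sales non-positive at the final week; "
            "percent reduction undefined",
            stacklevel=2,
        )
        final_week_pct = float("nan")
    else:
        final_week_pct = 100.0 * (syn_units - actual_units) / syn_units

    return EffectSummary(
        window_used=window,
        cumulative_units=cumulative_units,
        final_week_pct=final_week_pct,
        weekly_units_gap=weekly_units_gap,
        sd_gap_final=float(fit.gap[final_pos]),
    )
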