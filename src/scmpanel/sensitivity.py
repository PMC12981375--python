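"""Pipeline orchestration across standardization methods.

Runs standardize -> placebo analysis -> effect back-transformation for each
requested method and assembles a comparison table (rank, overall and
final-week p-values, cumulative unit reduction, final-week percent
reduction) with one row per method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .effects import effect_summary, effect_window
from .errors import ScmPanelError
from .inference import PlaceboDistribution, placebo_analysis, weekly_p
from .panel_io import SalesPanel, StudyWindows
from .standardize import METHODS, standardize_panel

logger = logging.getLogger(__name__)


@dataclass
class MethodResult:
    """Full pipeline output for one standardization method."""

    method: str
    placebos: PlaceboDistribution | None = None
    effect: "object | None" = None
    excluded_donors: list[str] = field(default_factory=list)
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class SensitivityTable:
    """One comparison row per standardization method."""

    rows: pd.DataFrame
    results: dict[str, MethodResult]

    def __len__(self) -> int:
        return len(self.rows)


def run_method(
    panel: SalesPanel,
    windows: StudyWindows,
    method: str,
    include_intervention: bool = False,
) -> MethodResult:
    """Run the full pipeline for a single standardization method."""
    result = MethodResult(method=method)
    try:
        std = standardize_panel(panel, windows, method=method)
        before = set(panel.brand_ids)
        result.excluded_donors = sorted(before - set(std.brand_ids))
        if result.excluded_donors:
            logger.info(
                "method %s: dropped donors with degenerate scale: %s",
                method,
                result.excluded_donors,
            )
        placebos = placebo_analysis(std, windows)
        window = effect_window(windows, include_intervention=include_intervention)
        effect = effect_summary(placebos.treated_fit, std, panel, window)
        result.placebos = placebos
        result.effect = effect
    except ScmPanelError as exc:
        logger.warning("method %s failed: %s", method, exc)
        result.error = str(exc)
    return result


def run_sensitivity(
    panel: SalesPanel,
    windows: StudyWindows,
    methods: Sequence[str] = METHODS,
    include_intervention: bool = False,
) -> SensitivityTable:
    """Assemble the cross-method comparison table.

    A method that fails (e.g. the treated brand has zero IQR under robust
    rescaling) yields a row flagged ``failed``; the other rows are still
    produced.
    """
    results: dict[str, MethodResult] = {}
    rows = []
    for method in methods:
        res = run_method(panel, windows, method, include_intervention=include_intervention)
        results[method] = res
        if res.failed:
            rows.append(
                {
                    "method": method,
                    "rank_of_treated": np.nan,
                    "p_overall": np.nan,
                    "p_final_week": np.nan,
                    "cumulative_units": np.nan,
                    "final_week_pct": np.nan,
                    "n_brands": np.nan,
                    "failed": True,
                }
            )
            continue
        placebos, effect = res.placebos, res.effect
        final_week = effect.window_used[-1]
        rows.append(
            {
                "method": method,
                "rank_of_treated": placebos.rank_of_treated,
                "p_overall": placebos.p_overall,
                "p_final_week": weekly_p(placebos, final_week),
                "cumulative_units": effect.cumulative_units,
                "final_week_pct": effect.final_week_pct,
                "n_brands": placebos.n,
                "failed": False,
            }
        )
    return SensitivityTable(rows=pd.DataFrame(rows), results=results)
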