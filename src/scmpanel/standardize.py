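"""Per-brand rescaling using pre-intervention statistics.

Each brand's full series is mapped through ``(x - location) / scale`` where
location and scale are computed from the pre window only:

========  =================  ==================
method    location           scale
========  =================  ==================
zscore    pre mean           pre SD (sample)
minmax    pre minimum        pre range
robust    pre median         pre IQR
========  =================  ==================

The affine map is stored so gaps can be converted back to unit scale
exactly (``values * scale + location``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ScaleError
from .panel_io import SalesPanel, StudyWindows

METHODS = ("zscore", "minmax", "robust")

_SCALE_EPS = 1e-12


@dataclass
class StandardizedPanel:
    """Standardized sales with the per-brand affine parameters retained."""

    brand_ids: list[str]
    week_index: np.ndarray
    values: np.ndarray  # (n_brands, n_weeks), dimensionless
    method: str
    location: np.ndarray  # (n_brands,)
    scale: np.ndarray  # (n_brands,), strictly positive
    treated_id: str

    @property
    def n_brands(self) -> int:
        return len(self.brand_ids)

    @property
    def n_weeks(self) -> int:
        return len(self.week_index)

    def brand_row(self, brand_id: str) -> np.ndarray:
        return self.values[self.index_of(brand_id)]

    def index_of(self, brand_id: str) -> int:
        return self.brand_ids.index(str(brand_id))

    def week_positions(self, weeks) -> np.ndarray:
        pos = np.searchsorted(self.week_index, np.asarray(list(weeks), dtype=int))
        return pos

    def params_of(self, brand_id: str) -> tuple[float, float]:
        i = self.index_of(brand_id)
        return float(self.location[i]), float(self.scale[i])


def _location_scale(pre: np.ndarray, method: str, ddof: int, iqr_method: str):
    if method == "zscore":
        return pre.mean(), pre.std(ddof=ddof)
    if method == "minmax":
        return pre.min(), pre.max() - pre.min()
    if method == "robust":
        q1, q3 = np.quantile(pre, [0.25, 0.75], method=iqr_method)
        return float(np.median(pre)), float(q3 - q1)
    raise ValueError(f"unknown standardization method {method!r}; choose from {METHODS}")


def standardize_panel(
    panel: SalesPanel,
    windows: StudyWindows,
    method: str = "zscore",
    ddof: int = 1,
    iqr_method: str = "linear",
) -> StandardizedPanel:
    """Rescale every brand using its own pre-window location and scale.

    Donor brands whose scale is degenerate (constant pre-period sales under
    zscore/minmax, zero IQR under robust) are dropped with a warning; a
    degenerate treated brand raises :class:`ScaleError`.

    Parameters
    ----------
    ddof
        Degrees-of-freedom correction for the zscore SD (1 = sample SD).
    iqr_method
        Quantile interpolation rule passed to :func:`numpy.quantile` for the
        robust method.
    """
    if method not in METHODS:
        raise ValueError(f"unknown standardization method {method!r}; choose from {METHODS}")
    incomplete = panel.incomplete_brands()
    if incomplete:
        raise ScaleError(
            f"panel has incomplete brands {incomplete}; run filter_brands first"
        )
    pre_pos = panel.week_positions(windows.pre)

    keep: list[int] = []
    locs: list[float] = []
    scales: list[float] = []
    dropped: list[str] = []
    for i, brand in enumerate(panel.brand_ids):
        loc, scale = _location_scale(panel.sales[i, pre_pos], method, ddof, iqr_method)
        if scale <= _SCALE_EPS:
            if brand == str(panel.treated_id):
                raise ScaleError(
                    f"treated brand {brand!r} has zero pre-period scale under {method!r}"
                )
            dropped.append(brand)
            continue
        keep.append(i)
        locs.append(float(loc))
        scales.append(float(scale))

    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} donor brand(s) with zero pre-period scale "
            f"under {method!r}: {dropped}",
            stacklevel=2,
        )

    location = np.asarray(locs)
    scale = np.asarray(scales)
    values = (panel.sales[keep] - location[:, None]) / scale[:, None]
    return StandardizedPanel(
        brand_ids=[panel.brand_ids[i] for i in keep],
        week_index=panel.week_index.copy(),
        values=values,
        method=method,
        location=location,
        scale=scale,
        treated_id=str(panel.treated_id),
    )


def destandardize(values: np.ndarray, location: float, scale: float) -> np.ndarray:
    """Invert the standardization: ``values * scale + location``."""
    if scale <= 0:
        raise ScaleError("scale must be positive")
    return np.asarray(values, dtype=float) * scale + location
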