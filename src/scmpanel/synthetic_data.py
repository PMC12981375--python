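"""Synthetic multi-brand weekly sales panels with known ground truth.

Donor brand ``j`` at week ``t`` has sales

    mu_j * (1 + trend)^t * exp(sum_k lambda_jk f_kt) * eps_jt

with log-normal brand scales ``mu_j`` (heavy-tailed across brands), common
weekly factors ``f_kt`` shared by all brands, and multiplicative log-normal
noise ``eps``.  The treated brand's no-effect path is a convex combination
of a random donor subset times its own noise; the realized series applies a
multiplicative decline ramping from 1 at the effect onset down to
``1 - effect_final_fraction``.  The exact counterfactual path is returned
so estimator recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .panel_io import SalesPanel, StudyWindows, _default_meta

TREATED_ID = "TREATED"


@dataclass
class GeneratorConfig:
    """Knobs for the panel generator; defaults emulate the target market.

    The default size parameters give a median weekly brand size near 1,400
    units with a heavy upper tail reaching into the millions, and the
    default effect ramps linearly to a 68.5% final-week reduction.
    """

    n_brands: int = 52
    n_weeks: int = 52
    size_log_mean: float = 7.25
    size_log_sd: float = 3.4
    trend_per_week: float = -0.002
    n_factors: int = 2
    factor_loading_mean: float = 0.08
    factor_loading_sd: float = 0.04
    noise_cv: float = 0.05
    treated_n_donors: int = 10
    treated_noise_cv: float = 0.02
    effect_final_fraction: float = 0.685
    effect_onset_week: int = 20
    effect_ramp_weeks: int | None = None  # None -> ramp to the final week
    effect_log_space: bool = False  # linear decline by default
    seed: int = 0
    windows: StudyWindows | None = None

    def __post_init__(self) -> None:
        if self.treated_n_donors >= self.n_brands:
            raise ConfigurationError("treated_n_donors must be < n_brands")
        if not (0.0 <= self.effect_final_fraction < 1.0):
            raise ConfigurationError("effect_final_fraction must be in [0, 1)")
        if min(self.noise_cv, self.treated_noise_cv) < 0:
            raise ConfigurationError("noise CVs must be non-negative")
        if self.windows is None:
            self.windows = StudyWindows.default(self.n_weeks)
        if not (self.windows.intervention[0] <= self.effect_onset_week <= self.windows.intervention[-1]):
            raise ConfigurationError("effect_onset_week must lie in the intervention window")


@dataclass
class GroundTruth:
    """Exact generator internals needed to score estimator recovery."""

    counterfactual: np.ndarray  # treated no-effect path, unit scale
    actual: np.ndarray  # treated realized path
    effect_multiplier: np.ndarray  # per-week multiplicative factor
    donor_subset: list[str]
    donor_weights: np.ndarray
    week_index: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counterfactual": self.counterfactual.tolist(),
            "actual": self.actual.tolist(),
            "effect_multiplier": self.effect_multiplier.tolist(),
            "donor_subset": self.donor_subset,
            "donor_weights": self.donor_weights.tolist(),
            "week_index": self.week_index.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def _effect_multiplier(cfg: GeneratorConfig) -> np.ndarray:
    """Per-week multiplier: 1 before onset, ramping to 1 - final_fraction."""
    weeks = np.arange(1, cfg.n_weeks + 1)
    ramp_weeks = cfg.effect_ramp_weeks
    if ramp_weeks is None:
        ramp_weeks = cfg.n_weeks - cfg.effect_onset_week
    ramp_weeks = max(int(ramp_weeks), 1)
    progress = np.clip((weeks - cfg.effect_onset_week) / ramp_weeks, 0.0, 1.0)
    floor = 1.0 - cfg.effect_final_fraction
    if cfg.effect_log_space:
        return np.exp(np.log(floor) * progress) if floor > 0 else np.where(progress > 0, 0.0, 1.0)
    return 1.0 - cfg.effect_final_fraction * progress


def generate_panel(config: GeneratorConfig) -> tuple[SalesPanel, GroundTruth]:
    """Draw a complete synthetic panel plus its ground-truth record."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_donors = cfg.n_brands - 1
    t = np.arange(1, cfg.n_weeks + 1)

    mu = rng.lognormal(mean=cfg.size_log_mean, sigma=cfg.size_log_sd, size=n_donors)
    factors = rng.standard_normal((cfg.n_factors, cfg.n_weeks))
    loadings = np.empty((n_donors, cfg.n_factors))
    # first factor has a common positive loading so brand paths co-move;
    # remaining factors add idiosyncratic shape
    loadings[:, 0] = rng.normal(cfg.factor_loading_mean, cfg.factor_loading_sd, n_donors)
    if cfg.n_factors > 1:
        loadings[:, 1:] = rng.normal(0.0, cfg.factor_loading_sd, (n_donors, cfg.n_factors - 1))

    trend = (1.0 + cfg.trend_per_week) ** t
    common = np.exp(loadings @ factors)  # (n_donors, n_weeks)
    noise = _lognormal_noise(rng, cfg.noise_cv, (n_donors, cfg.n_weeks))
    donor_sales = mu[:, None] * trend[None, :] * common * noise

    donor_ids = [f"D{j:03d}" for j in range(1, n_donors + 1)]
    subset_pos = rng.choice(n_donors, size=cfg.treated_n_donors, replace=False)
    subset_pos.sort()
    v = rng.dirichlet(np.ones(cfg.treated_n_donors))
    treated_noise = _lognormal_noise(rng, cfg.treated_noise_cv, cfg.n_weeks)
    counterfactual = (v @ donor_sales[subset_pos]) * treated_noise
    multiplier = _effect_multiplier(cfg)
    actual = counterfactual * multiplier

    sales = np.vstack([actual[None, :], donor_sales])
    brand_ids = [TREATED_ID] + donor_ids
    panel = SalesPanel(
        brand_ids=brand_ids,
        week_index=t,
        sales=sales,
        treated_id=TREATED_ID,
        brand_meta=_default_meta(brand_ids, TREATED_ID),
    )
    truth = GroundTruth(
        counterfactual=counterfactual,
        actual=actual,
        effect_multiplier=multiplier,
        donor_subset=[donor_ids[j] for j in subset_pos],
        donor_weights=v,
        week_index=t,
    )
    return panel, truth


def ground_truth_effect(truth: GroundTruth, window) -> tuple[float, float]:
    """Exact (cumulative unit gap, final-week reduction fraction) in ``window``.

    The cumulative gap is ``sum(actual - counterfactual)`` (negative under a
    decline); the final-week fraction is the relative reduction at the last
    week of the window.
    """
    window = np.asarray(list(window), dtype=int)
    pos = np.searchsorted(truth.week_index, window)
    cumulative = float(np.sum(truth.actual[pos] - truth.counterfactual[pos]))
    final = pos[-1]
    if truth.counterfactual[final] == 0:
        return cumulative, 0.0
    fraction = float(
        (truth.counterfactual[final] - truth.actual[final]) / truth.counterfactual[final]
    )
    return cumulative, fraction


def truth_summary(cfg: GeneratorConfig, truth: GroundTruth) -> dict:
    """Ground-truth effects over the default post window, for manifests."""
    windows = cfg.windows or StudyWindows.default(cfg.n_weeks)
    cum, frac = ground_truth_effect(truth, windows.post)
    return {
        "config": {k: v for k, v in asdict(cfg).items() if k != "windows"},
        "cumulative_units_post": cum,
        "final_week_fraction": frac,
        "donor_subset": truth.donor_subset,
    }
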