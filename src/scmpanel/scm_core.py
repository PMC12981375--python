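"""Synthetic-control weight estimation.

Weights solve the simplex-constrained least-squares problem

    min_w  sum_{t in pre} ( y_t - sum_j w_j x_jt )^2
    s.t.   w_j >= 0,  sum_j w_j = 1

over the standardized pre-window outcomes.  The solver combines a
penalized non-negative least squares pass (the sum constraint is enforced
through a heavily weighted extra row) with an exact active-set polish on
the recovered support, and is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import SolverError
from .panel_io import StudyWindows
from .standardize import StandardizedPanel, destandardize

#: weights below this are zeroed and the remainder renormalized
SPARSITY_THRESHOLD = 1e-6


@dataclass
class ScmFit:
    """Donor weights and the implied synthetic series for one focal brand."""

    focal_id: str
    donor_ids: list[str]
    weights: np.ndarray  # (n_donors,), on the simplex
    synthetic: np.ndarray  # (n_weeks,), standardized scale
    gap: np.ndarray  # focal - synthetic, per week
    pre_mse: float

    def nonzero_donors(self) -> list[tuple[str, float]]:
        """(donor, weight) pairs with positive weight, largest first."""
        pairs = [(d, float(w)) for d, w in zip(self.donor_ids, self.weights) if w > 0]
        return sorted(pairs, key=lambda p: (-p[1], p[0]))


def _objective(A: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    r = A @ w - b
    return float(r @ r)


def _restricted_solution(A: np.ndarray, b: np.ndarray, support: np.ndarray) -> np.ndarray | None:
    """Solve the equality-constrained LS restricted to ``support`` via KKT.

    Returns the full-length weight vector, or None when the restricted
    solution leaves the non-negative orthant.
    """
    k = int(support.sum())
    As = A[:, support]
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = 2.0 * As.T @ As
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.concatenate([2.0 * As.T @ b, [1.0]])
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    u = sol[:k]
    if u.min() < -1e-10:
        return None
    w = np.zeros(A.shape[1])
    w[support] = np.clip(u, 0.0, None)
    s = w.sum()
    if s <= 0:
        return None
    return w / s


def simplex_lstsq(A: np.ndarray, b: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Least squares on the probability simplex.

    Deterministic: a penalized NNLS pass finds a near-feasible solution and
    identifies the active set; an exact KKT solve on that support (shrinking
    it while the restricted optimum is infeasible) polishes the result.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    m, n = A.shape
    if n == 1:
        return np.ones(1)

    rho = 1e6 * max(1.0, float(np.abs(A).max()), float(np.abs(b).max()))
    A_aug = np.vstack([A, rho * np.ones((1, n))])
    b_aug = np.concatenate([b, [rho]])
    try:
        w, _ = optimize.nnls(A_aug, b_aug)
    except Exception as exc:  # pragma: no cover - scipy failure path
        raise SolverError(f"NNLS pass failed: {exc}") from exc
    total = w.sum()
    if total <= 0:
        # all-zero can only happen for pathological inputs; fall back to uniform
        w = np.full(n, 1.0 / n)
    else:
        w = w / total
    best = w
    best_obj = _objective(A, b, w)

    # active-set polish: exact KKT solve on the support, dropping the most
    # negative coordinate until feasible
    support = w > 1e-12
    if not support.any():
        support = np.ones(n, dtype=bool)
    for _ in range(n):
        polished = _restricted_solution(A, b, support)
        if polished is not None:
            obj = _objective(A, b, polished)
            if obj <= best_obj + tol:
                best, best_obj = polished, obj
            break
        # identify the most negative coordinate of the unconstrained
        # restricted solution and remove it from the support
        k = int(support.sum())
        if k <= 1:
            break
        As = A[:, support]
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = 2.0 * As.T @ As
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.concatenate([2.0 * As.T @ b, [1.0]])
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        u = sol[:k]
        drop_local = int(np.argmin(u))
        support_idx = np.flatnonzero(support)
        support[support_idx[drop_local]] = False

    if abs(best.sum() - 1.0) > 1e-8 or best.min() < -1e-12:
        raise SolverError("solver returned an infeasible weight vector")
    return np.clip(best, 0.0, None) / best.sum()


def fit_scm(
    panel: StandardizedPanel,
    focal_id: str,
    donor_ids: Sequence[str],
    windows: StudyWindows,
    sparsity_threshold: float = SPARSITY_THRESHOLD,
) -> ScmFit:
    """Fit synthetic-control weights for ``focal_id`` from ``donor_ids``.

    Weights minimize the pre-window sum of squared discrepancies on the
    standardized scale.  Weights below ``sparsity_threshold`` are zeroed and
    the remainder renormalized so the count of contributing donors is
    stable across platforms.
    """
    focal_id = str(focal_id)
    donor_ids = [str(d) for d in donor_ids]
    if focal_id in donor_ids:
        raise ValueError("focal brand must not be in its own donor pool")
    if len(donor_ids) < 2:
        raise ValueError("need at least 2 donors")

    pre_pos = panel.week_positions(windows.pre)
    donor_rows = np.asarray([panel.index_of(d) for d in donor_ids])
    A = panel.values[donor_rows][:, pre_pos].T  # (n_pre, n_donors)
    b = panel.values[panel.index_of(focal_id), pre_pos]

    w = simplex_lstsq(A, b)

    small = (w > 0) & (w < sparsity_threshold)
    if small.any():
        w = np.where(small, 0.0, w)
        w = w / w.sum()

    synthetic = w @ panel.values[donor_rows]
    gap = panel.values[panel.index_of(focal_id)] - synthetic
    pre_mse = float(np.mean(gap[pre_pos] ** 2))
    return ScmFit(
        focal_id=focal_id,
        donor_ids=donor_ids,
        weights=w,
        synthetic=synthetic,
        gap=gap,
        pre_mse=pre_mse,
    )


def synthetic_series(fit: ScmFit, panel: StandardizedPanel) -> np.ndarray:
    """Weight-combination of the donor series over all weeks."""
    rows = np.asarray([panel.index_of(d) for d in fit.donor_ids])
    return fit.weights @ panel.values[rows]


def pre_fit_diagnostic(fit: ScmFit, panel, std: StandardizedPanel, windows: StudyWindows) -> float:
    """Mean percent gap between actual and synthetic unit sales pre-window.

    Returns ``mean over pre weeks of 100 * (actual - synthetic) / synthetic``
    on the unit scale, or NaN (with a warning) when the destandardized
    synthetic is non-positive at any pre week.
    """
    loc, scale = std.params_of(fit.focal_id)
    pre_pos = std.week_positions(windows.pre)
    syn_units = destandardize(fit.synthetic[pre_pos], loc, scale)
    actual_units = panel.brand_row(fit.focal_id)[panel.week_positions(windows.pre)]
    if np.any(syn_units <= 0):
        warnings.warn(
            "synthetic unit sales non-positive in the pre window; percent diagnostic undefined",
            stacklevel=2,
        )
        return float("nan")
    return float(np.mean(100.0 * (actual_units - syn_units) / syn_units))
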