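import numpy as np
import pytest

from scmpanel import (
    StandardizedPanel,
    StudyWindows,
    fit_scm,
    pre_fit_diagnostic,
    placebo_analysis,
    simplex_lstsq,
    standardize_panel,
    synthetic_series,
)
from scmpanel.synthetic_data import GeneratorConfig, generate_panel

from conftest import make_panel


def std_panel(values, treated="B0"):
    values = np.asarray(values, dtype=float)
    n, t = values.shape
    ids = [f"B{i}" for i in range(n)]
    return StandardizedPanel(
        brand_ids=ids,
        week_index=np.arange(1, t + 1),
        values=values,
        method="zscore",
        location=np.zeros(n),
        scale=np.ones(n),
        treated_id=treated,
    )


def grid_objective(A, b, step=1e-3):
    """Dense grid search over the simplex (oracle for <=3 donors)."""
    n = A.shape[1]
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    if n == 2:
        W = np.column_stack([ticks, 1.0 - ticks])
    elif n == 3:
        w1, w2 = np.meshgrid(ticks, ticks)
        mask = w1 + w2 <= 1.0 + 1e-12
        W = np.column_stack([w1[mask], w2[mask], 1.0 - w1[mask] - w2[mask]])
    else:
        raise ValueError("oracle supports 2 or 3 donors")
    resid = W @ A.T - b  # (n_points, n_pre)
    return float(np.min(np.einsum("ij,ij->i", resid, resid)))


@pytest.fixture
def ten_week_windows():
    return StudyWindows(pre=(1, 2, 3, 4, 5), intervention=(6, 7), post=(8, 9, 10))


class TestSimplexLstsq:
    def test_exact_match_donor_gets_full_weight(self, ten_week_windows, rng):
        vals = rng.normal(size=(5, 10))
        vals[0] = vals[3]  # focal identical to donor 3 (B3)
        panel = std_panel(vals)
        fit = fit_scm(panel, "B0", ["B1", "B2", "B3", "B4"], ten_week_windows)
        assert fit.pre_mse == pytest.approx(0.0, abs=1e-12)
        idx = fit.donor_ids.index("B3")
        assert fit.weights[idx] == pytest.approx(1.0, abs=1e-6)

    def test_half_half_mixture_recovered(self, ten_week_windows, rng):
        # oracle value frozen from a 2-simplex grid search at step 1e-4:
        # focal = 0.5 A + 0.5 B with affinely independent donors
        vals = rng.normal(size=(3, 10))
        vals[0] = 0.5 * vals[1] + 0.5 * vals[2]
        panel = std_panel(vals)
        fit = fit_scm(panel, "B0", ["B1", "B2"], ten_week_windows)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=1e-6)
        A = vals[1:3, :5].T
        b = vals[0, :5]
        assert grid_objective(A, b, step=1e-4) == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_oracle_three_donors(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(7, 3))
        b = rng.normal(size=7)
        w = simplex_lstsq(A, b)
        obj = float(np.sum((A @ w - b) ** 2))
        assert obj <= grid_objective(A, b, step=1e-3) + 1e-6

    def test_degenerate_identical_donors_still_valid(self, ten_week_windows):
        base = np.sin(np.arange(10.0))
        vals = np.vstack([base, base, base, base])
        panel = std_panel(vals)
        fit = fit_scm(panel, "B0", ["B1", "B2", "B3"], ten_week_windows)
        assert fit.weights.min() >= 0
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(fit.synthetic, base, atol=1e-8)

    def test_simplex_feasibility_random_problems(self, rng):
        for _ in range(25):
            A = rng.normal(size=(6, rng.integers(2, 12)))
            b = rng.normal(size=6)
            w = simplex_lstsq(A, b)
            assert w.min() >= 0
            assert abs(w.sum() - 1.0) < 1e-8

    def test_beats_best_single_donor(self, ten_week_windows, rng):
        # interpolation bias bound: fitted pre_mse <= best single donor's
        for _ in range(10):
            vals = rng.normal(size=(6, 10))
            panel = std_panel(vals)
            donors = ["B1", "B2", "B3", "B4", "B5"]
            fit = fit_scm(panel, "B0", donors, ten_week_windows)
            singles = [np.mean((vals[0, :5] - vals[j, :5]) ** 2) for j in range(1, 6)]
            assert fit.pre_mse <= min(singles) + 1e-10


class TestFitScm:
    def test_focal_in_pool_rejected(self, ten_week_windows):
        panel = std_panel(np.zeros((3, 10)))
        with pytest.raises(ValueError, match="donor pool"):
            fit_scm(panel, "B0", ["B0", "B1"], ten_week_windows)

    def test_needs_two_donors(self, ten_week_windows):
        panel = std_panel(np.zeros((3, 10)))
        with pytest.raises(ValueError, match="at least 2"):
            fit_scm(panel, "B0", ["B1"], ten_week_windows)

    def test_gap_and_premse_consistency(self, ten_week_windows, rng):
        vals = rng.normal(size=(5, 10))
        panel = std_panel(vals)
        fit = fit_scm(panel, "B0", ["B1", "B2", "B3", "B4"], ten_week_windows)
        np.testing.assert_allclose(fit.gap, vals[0] - fit.synthetic, atol=1e-12)
        assert fit.pre_mse == pytest.approx(float(np.mean(fit.gap[:5] ** 2)))

    def test_donor_order_permutation_invariant(self, ten_week_windows, rng):
        vals = rng.normal(size=(6, 10))
        panel = std_panel(vals)
        donors = ["B1", "B2", "B3", "B4", "B5"]
        a = fit_scm(panel, "B0", donors, ten_week_windows)
        b = fit_scm(panel, "B0", donors[::-1], ten_week_windows)
        np.testing.assert_allclose(a.synthetic, b.synthetic, atol=1e-7)

    def test_sparsity_thresholding(self, ten_week_windows, rng):
        vals = rng.normal(size=(5, 10))
        panel = std_panel(vals)
        fit = fit_scm(panel, "B0", ["B1", "B2", "B3", "B4"], ten_week_windows)
        nz = fit.weights[fit.weights > 0]
        assert (nz >= 1e-6).all()
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-8)

    def test_default_scenario_selects_near_ten_donors(self, default_scenario, default_windows):
        cfg, panel, truth = default_scenario
        std = standardize_panel(panel, default_windows)
        donors = [b for b in std.brand_ids if b != panel.treated_id]
        fit = fit_scm(std, panel.treated_id, donors, default_windows)
        n_active = len(fit.nonzero_donors())
        assert 2 <= n_active <= 25  # qualitative: sparse, order ~10


class TestSyntheticSeries:
    def test_all_weight_on_one_donor(self, ten_week_windows, rng):
        vals = rng.normal(size=(4, 10))
        vals[0] = vals[2]
        panel = std_panel(vals)
        fit = fit_scm(panel, "B0", ["B1", "B2", "B3"], ten_week_windows)
        np.testing.assert_allclose(synthetic_series(fit, panel), vals[2], atol=1e-6)

    def test_uniform_weights_over_identical_donors(self):
        base = np.cos(np.arange(10.0))
        panel = std_panel(np.vstack([base, base, base]))
        from scmpanel import ScmFit

        fit = ScmFit(
            focal_id="B0",
            donor_ids=["B1", "B2"],
            weights=np.array([0.5, 0.5]),
            synthetic=base,
            gap=np.zeros(10),
            pre_mse=0.0,
        )
        np.testing.assert_allclose(synthetic_series(fit, panel), base)

    def test_hand_computed_three_week_toy(self):
        vals = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        panel = std_panel(vals)
        from scmpanel import ScmFit

        fit = ScmFit(
            focal_id="B0",
            donor_ids=["B1", "B2"],
            weights=np.array([0.3, 0.7]),
            synthetic=np.zeros(3),
            gap=np.zeros(3),
            pre_mse=0.0,
        )
        np.testing.assert_allclose(synthetic_series(fit, panel), [2.4, 2.0, 1.6])


class TestPreFitDiagnostic:
    def test_perfect_fit_is_zero(self, ten_week_windows, rng):
        sales = rng.uniform(100, 200, size=(4, 10))
        sales[0] = sales[2]
        panel = make_panel(sales)
        std = standardize_panel(panel, ten_week_windows)
        fit = fit_scm(std, "B0", ["B1", "B2", "B3"], ten_week_windows)
        assert pre_fit_diagnostic(fit, panel, std, ten_week_windows) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_one_percent_gap(self, ten_week_windows, rng):
        # construct a fit whose destandardized synthetic is exactly actual/1.01
        sales = rng.uniform(100, 200, size=(3, 10))
        panel = make_panel(sales)
        std = standardize_panel(panel, ten_week_windows)
        fit = fit_scm(std, "B0", ["B1", "B2"], ten_week_windows)
        loc, scale = std.params_of("B0")
        fit.synthetic = (sales[0] / 1.01 - loc) / scale
        assert pre_fit_diagnostic(fit, panel, std, ten_week_windows) == pytest.approx(1.0, rel=1e-9)

    def test_nonpositive_synthetic_units_warns_nan(self, ten_week_windows, rng):
        sales = rng.uniform(100, 200, size=(3, 10))
        panel = make_panel(sales)
        std = standardize_panel(panel, ten_week_windows)
        fit = fit_scm(std, "B0", ["B1", "B2"], ten_week_windows)
        loc, scale = std.params_of("B0")
        fit.synthetic = np.full(10, (-5.0 - loc) / scale)  # units = -5 everywhere
        with pytest.warns(UserWarning, match="non-positive"):
            out = pre_fit_diagnostic(fit, panel, std, ten_week_windows)
        assert np.isnan(out)

    def test_default_scenario_below_one_percent(self, default_scenario, default_windows):
        cfg, panel, truth = default_scenario
        std = standardize_panel(panel, default_windows)
        pl = placebo_analysis(std, default_windows)
        diag = pre_fit_diagnostic(pl.treated_fit, panel, std, default_windows)
        assert abs(diag) < 1.0
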