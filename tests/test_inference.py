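"""Conditional-logistic likelihood, fitting, effect summaries, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime

from lagcrossover.design import StackedDesign, build_design_matrix, build_strata_table
from lagcrossover.inference import (
    ModelSpec,
    bspline_basis,
    compare_strata,
    conditional_loglik,
    cumulative_effect,
    fit_conditional_logistic,
    linearity_lrt,
    single_lag_effect,
)

from conftest import constant_series


def stack(strata_rows, case_flags, colnames=None):
    """Build a StackedDesign from a list of per-stratum row arrays."""
    blocks = []
    for s in strata_rows:
        a = np.asarray(s, dtype=float)
        blocks.append(a[:, None] if a.ndim == 1 else a)  # 1-D = one covariate
    X = np.vstack(blocks)
    sizes = [b.shape[0] for b in blocks]
    starts = np.cumsum([0] + sizes[:-1])
    return StackedDesign(
        X=X,
        is_case=np.concatenate([np.asarray(c) for c in case_flags]),
        starts=np.asarray(starts),
        colnames=colnames or [f"x{j}" for j in range(X.shape[1])],
    )


class TestBSplineBasis:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-3, 11, size=400)
        B = bspline_basis(x, df=4, degree=2, xrange=(-3, 11))
        assert B.shape == (400, 5)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_two_equally_spaced_interior_knots(self):
        # with df=4, degree=2 the interior knots sit at range thirds; the
        # basis must be exactly symmetric under reflection about the midpoint
        x = np.linspace(0, 9, 301)
        B = bspline_basis(x, df=4, degree=2, xrange=(0, 9))
        np.testing.assert_allclose(B, B[::-1, ::-1], atol=1e-12)
        # piecewise structure changes exactly at 3 and 6: second derivative
        # of a quadratic spline is piecewise constant with breaks at knots
        col = B[:, 2]
        d2 = np.diff(col, 2)
        breaks = np.flatnonzero(np.abs(np.diff(d2)) > 1e-10) * 9 / 300
        assert len(breaks) > 0
        # every curvature break sits at one of the two thirds-points
        assert all(min(abs(b - 3.0), abs(b - 6.0)) < 0.1 for b in breaks)
        assert any(abs(b - 3.0) < 0.1 for b in breaks)
        assert any(abs(b - 6.0) < 0.1 for b in breaks)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bspline_basis(np.array([1.0]), xrange=(2.0, 2.0))


class TestConditionalLoglik:
    def test_uniform_probability_at_zero_beta(self):
        D = stack([np.arange(5.0)], [[1, 0, 0, 0, 0]])
        ll = conditional_loglik(np.zeros(1), D.X, D.is_case, D.starts, order=0)
        assert ll == pytest.approx(np.log(1 / 5))

    def test_identical_rows_contribute_log_uniform_any_beta(self):
        D = stack([np.full(4, 3.3)], [[1, 0, 0, 0]])
        for b in (-2.0, 0.0, 5.0):
            ll, grad = conditional_loglik(np.array([b]), D.X, D.is_case, D.starts, order=1)
            assert ll == pytest.approx(np.log(1 / 4))
            assert grad[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(2)
        rows = [rng.normal(size=(n, 2)) for n in (4, 5, 4)]
        flags = [[1, 0, 0, 0], [1, 0, 0, 0, 0], [1, 0, 0, 0]]
        D = stack(rows, flags)
        beta = np.array([0.4, -0.7])
        expected = sum(
            np.log(np.exp(r[0] @ beta) / np.exp(r @ beta).sum()) for r in rows
        )
        ll = conditional_loglik(beta, D.X, D.is_case, D.starts, order=0)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_gradient_and_hessian_match_finite_differences(self):
        rng = np.random.default_rng(3)
        rows = [rng.normal(size=(4, 3)) for _ in range(6)]
        flags = [[1, 0, 0, 0]] * 6
        D = stack(rows, flags)
        beta = rng.normal(scale=0.3, size=3)
        ll, grad, hess = conditional_loglik(beta, D.X, D.is_case, D.starts)
        f = lambda b: conditional_loglik(b, D.X, D.is_case, D.starts, order=0)
        num_grad = approx_fprime(beta, f, 1e-7)
        np.testing.assert_allclose(grad, num_grad, atol=1e-5)
        num_hess = np.array(
            [approx_fprime(beta, lambda b: conditional_loglik(
                b, D.X, D.is_case, D.starts, order=1)[1][j], 1e-6)
             for j in range(3)]
        )
        np.testing.assert_allclose(hess, num_hess, atol=1e-4)

    def test_invariance_to_stratum_constant_shifts_and_row_relabeling(self):
        rng = np.random.default_rng(4)
        rows = [rng.normal(size=(5, 2)) for _ in range(5)]
        flags = [[1, 0, 0, 0, 0]] * 5
        D = stack(rows, flags)
        beta = np.array([0.3, -0.2])
        ll0 = conditional_loglik(beta, D.X, D.is_case, D.starts, order=0)
        # add an arbitrary per-stratum constant to column 0
        shifts = np.repeat(rng.normal(size=5), 5)
        X2 = D.X.copy()
        X2[:, 0] += shifts
        assert conditional_loglik(beta, X2, D.is_case, D.starts, order=0) == (
            pytest.approx(ll0, abs=1e-10)
        )
        # permute rows within each stratum (case flag travels with its row)
        X3, c3 = D.X.copy(), D.is_case.copy()
        for s in range(5):
            sl = slice(5 * s, 5 * s + 5)
            perm = rng.permutation(5)
            X3[sl], c3[sl] = X3[sl][perm], c3[sl][perm]
        assert conditional_loglik(beta, X3, c3, D.starts, order=0) == (
            pytest.approx(ll0, abs=1e-10)
        )


class TestFitConditionalLogistic:
    def test_matched_pair_closed_form(self):
        # 6 case-exposed-only + 4 control-exposed-only pairs -> beta = ln(6/4)
        rows = [[[1.0], [0.0]]] * 6 + [[[0.0], [1.0]]] * 4
        flags = [[1, 0]] * 10
        fit = fit_conditional_logistic(stack(rows, flags))
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(1.5), abs=1e-6)

    def test_all_identical_strata_raise_no_information_error(self):
        rows = [np.full((4, 1), 2.0)] * 3
        flags = [[1, 0, 0, 0]] * 3
        with pytest.raises(ValueError, match="informative"):
            fit_conditional_logistic(stack(rows, flags))

    def test_constant_column_reported_noninformative(self):
        rng = np.random.default_rng(6)
        rows = [np.column_stack([rng.normal(size=4), np.full(4, 7.0)]) for _ in range(8)]
        flags = [[1, 0, 0, 0]] * 8
        fit = fit_conditional_logistic(stack(rows, flags, ["x", "const"]))
        assert fit.noninformative == ["const"]
        assert fit.beta[1] == 0.0 and np.isnan(fit.cov[1, 1])

    def test_agrees_with_statsmodels(self, small_rows):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rows, _ = small_rows
        D = build_design_matrix(rows, ModelSpec(temp_structure=None))
        fit = fit_conditional_logistic(D)
        groups = np.repeat(np.arange(D.n_strata), D.counts)
        sm = ConditionalLogit(D.is_case, D.X, groups=groups).fit(disp=0)
        np.testing.assert_allclose(fit.beta, sm.params, atol=5e-3)
        assert fit.loglik >= sm.llf - 1e-6  # our Newton converges at least as far
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.cov)), sm.bse, rtol=0.02
        )


class TestEffectSummaries:
    def test_percent_transform_round_trips_exactly(self):
        rng = np.random.default_rng(7)
        rows = [rng.normal(size=(4, 7)) for _ in range(30)]
        flags = [[1, 0, 0, 0]] * 30
        D = stack(rows, flags, [f"pm25_lag{l}" for l in range(7)])
        fit = fit_conditional_logistic(D)
        eff = cumulative_effect(fit)
        assert eff.percent == pytest.approx((np.exp(10 * eff.beta_sum) - 1) * 100, abs=1e-12)
        assert eff.ci_low < eff.percent < eff.ci_high
        back = np.log1p(eff.percent / 100) / 10
        assert back == pytest.approx(eff.beta_sum, abs=1e-15)

    def test_null_fit_gives_zero_percent_with_symmetric_ci(self):
        # antisymmetric two-stratum design: MLE is exactly 0
        rows = [[[1.0], [0.0]], [[0.0], [1.0]]]
        flags = [[1, 0], [1, 0]]
        fit = fit_conditional_logistic(
            stack(rows, flags, ["pm25_lag0"])
        )
        eff = single_lag_effect(fit, 0)
        assert eff.percent == pytest.approx(0.0, abs=1e-8)
        assert eff.ci_low == pytest.approx(-eff.ci_high / (1 + eff.ci_high / 100), rel=1e-3)

    def test_delta_method_matches_explicit_reparameterization(self):
        # reparameterize so the first coefficient IS the lag sum: gamma = A beta
        # with A = [1...1; e2; ...; e7] and design Z = X A^-1.  The fitted
        # se(gamma_1) must equal the delta-method se of 1'beta from the X fit.
        rng = np.random.default_rng(8)
        rows = [rng.normal(size=(5, 7)) for _ in range(60)]
        flags = [[1, 0, 0, 0, 0]] * 60
        D = stack(rows, flags, [f"pm25_lag{l}" for l in range(7)])
        fit_x = fit_conditional_logistic(D)
        eff = cumulative_effect(fit_x, scale=1.0)
        A = np.eye(7)
        A[0, :] = 1.0
        Z = D.X @ np.linalg.inv(A)
        fit_z = fit_conditional_logistic(
            StackedDesign(Z, D.is_case, D.starts, [f"g{j}" for j in range(7)])
        )
        assert fit_z.beta[0] == pytest.approx(eff.beta_sum, abs=1e-6)
        assert np.sqrt(fit_z.cov[0, 0]) == pytest.approx(eff.se_sum, rel=1e-6)


class TestLinearityLRT:
    def test_statistic_nonnegative_by_nesting(self, small_rows):
        rows, _ = small_rows
        out = linearity_lrt(rows.iloc[: 5 * 400])
        assert out["stat"] >= 0.0
        assert out["df"] == 14
        assert 0.0 <= out["p"] <= 1.0

    def test_rejects_plain_spec_violations(self, small_rows):
        rows, _ = small_rows
        with pytest.raises(ValueError, match="linear-lag null"):
            linearity_lrt(rows, ModelSpec(pm_spline_df=3))


class TestCompareStrata:
    def test_equal_coefficients_centered_at_zero(self):
        cmp_ = compare_strata(0.01, 0.004, 0.01, 0.004)
        assert cmp_.diff == 0.0
        assert cmp_.ci_low == pytest.approx(-cmp_.ci_high)
        assert not cmp_.modification_flag

    def test_hand_computed_difference_ci(self):
        cmp_ = compare_strata(0.020, 0.006, 0.005, 0.008)
        assert cmp_.diff == pytest.approx(0.015)
        assert cmp_.ci_low == pytest.approx(-0.0046, abs=1e-4)
        assert cmp_.ci_high == pytest.approx(0.0346, abs=1e-4)
        assert not cmp_.modification_flag
        # CI half-width is exactly 1.96 * sqrt(se1^2 + se2^2)
        half = 1.96 * np.sqrt(0.006**2 + 0.008**2)
        assert cmp_.ci_high - cmp_.diff == pytest.approx(half, abs=1e-15)

    def test_three_sigma_difference_flags(self):
        se1, se2 = 0.004, 0.003
        diff = 3 * np.sqrt(se1**2 + se2**2)
        cmp_ = compare_strata(diff, se1, 0.0, se2)
        assert cmp_.modification_flag

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compare_strata(0.1, 0.0, 0.0, 0.01)
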