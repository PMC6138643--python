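import numpy as np
import pytest

from protodyn.halflife import LN2
from protodyn.io_preprocess import MinuteGrid
from protodyn.solver import (
    closed_form_R0,
    compute_k_trans,
    predict_protein,
    solve_periodic_R,
    solve_periodic_R_closed_form,
    step_R,
)
from protodyn.synthetic import analytic_periodic_protein, sinusoid_mrna


def constant_grid(value: float, T: float = 60.0, dt: float = 1.0) -> MinuteGrid:
    n = round(T / dt)
    return MinuteGrid("const", T, dt, np.full(n + 1, value))


class TestStepR:
    def test_zero_dynamics(self):
        assert step_R(0.0, 0.0, 0.0, 0.1, 1.0) == 0.0

    def test_constant_fixed_point(self):
        # R* = m/k_d reproduces itself under constant forcing
        assert step_R(100.0, 10.0, 10.0, 0.1, 1.0) == pytest.approx(100.0, rel=1e-14)

    def test_forced_arithmetic(self):
        assert step_R(0.0, 10.0, 10.0, 0.1, 1.0) == pytest.approx(20.0 / 2.1)

    def test_non_contractive_step_raises(self):
        with pytest.raises(ValueError, match="k_d\\*dt"):
            step_R(0.0, 1.0, 1.0, 2.5, 1.0)


class TestSolvePeriodicR:
    def test_constant_forcing_converges_to_m_over_kd(self):
        r = solve_periodic_R(constant_grid(10.0), 0.1)
        np.testing.assert_allclose(r.values, 100.0, rtol=1e-10)
        # contraction factor exp(-k_d T) = e^-6 per sweep: a handful of sweeps
        assert r.iterations <= 10
        assert r.residual <= 5e-10

    def test_matches_analytic_sinusoid_with_dt_squared_error(self, sinus_gene):
        oracle = analytic_periodic_protein(
            sinus_gene.m0,
            sinus_gene.amplitude,
            2 * np.pi / sinus_gene.period_T,
            sinus_gene.phase,
            1.0,
            sinus_gene.true_k_d,
        )
        errs = {}
        for dt in (1.0, 0.5):
            grid = sinusoid_mrna(sinus_gene, dt)
            r = solve_periodic_R(grid, sinus_gene.true_k_d)
            errs[dt] = np.max(np.abs(r.values - oracle(grid.times)))
        assert errs[1.0] < 5e-3 * (sinus_gene.m0 / sinus_gene.true_k_d)
        # halving dt quarters the error (second-order scheme)
        assert errs[1.0] / errs[0.5] == pytest.approx(4.0, rel=0.15)

    def test_residual_contracts_like_exp_minus_kd_T(self, random_grid_factory):
        grid = random_grid_factory(5)
        k_d = LN2 / 22.0
        # run two successive sweeps manually via decreasing tolerances
        from protodyn.solver import sweep_R

        R = sweep_R(0.0, grid.values, k_d, grid.dt)
        res1 = abs(R[-1] - R[0])
        R2 = sweep_R(R[-1], grid.values, k_d, grid.dt)
        res2 = abs(R2[-1] - R2[0])
        factor = res2 / res1
        assert factor == pytest.approx(np.exp(-k_d * grid.period_T), rel=0.05)

    def test_nonconvergence_suggests_closed_form(self):
        with pytest.raises(Exception, match="closed_form"):
            solve_periodic_R(constant_grid(10.0), 1e-7, max_sweeps=3)


class TestClosedForm:
    def test_constant_forcing_gives_m_over_kd(self):
        assert closed_form_R0(constant_grid(10.0), 0.1) == pytest.approx(100.0)

    def test_closed_form_is_exact_fixed_point(self, random_grid_factory):
        from protodyn.solver import sweep_R

        grid = random_grid_factory(1)
        k_d = LN2 / 50.0
        R0 = closed_form_R0(grid, k_d)
        R = sweep_R(R0, grid.values, k_d, grid.dt)
        assert abs(R[-1] - R0) < 1e-9 * max(R0, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_fixed_point_iteration(self, random_grid_factory, seed):
        grid = random_grid_factory(seed)
        k_d = LN2 / 22.0
        rc = solve_periodic_R_closed_form(grid, k_d)
        rf = solve_periodic_R(grid, k_d, tol=5e-10)
        np.testing.assert_allclose(rc.values, rf.values, atol=1e-8)

    def test_vanishing_degradation_raises(self):
        with pytest.raises(ValueError, match="too small"):
            closed_form_R0(constant_grid(10.0), 1e-18)


class TestConservation:
    """Discrete analogue of averaging the kinetic equation over one period."""

    @pytest.mark.parametrize("seed", range(10))
    def test_mean_R_equals_mean_m_over_kd(self, random_grid_factory, seed):
        grid = random_grid_factory(seed)
        k_d = LN2 / np.random.default_rng(seed).uniform(5, 200)
        r = solve_periodic_R_closed_form(grid, k_d)
        expected = grid.period_mean() / k_d
        assert r.period_mean() == pytest.approx(expected, rel=1e-12)

    def test_positivity(self, random_grid_factory):
        r = solve_periodic_R_closed_form(random_grid_factory(3), LN2 / 22.0)
        assert np.all(r.values >= 0)


class TestKTransAndPrediction:
    def test_division(self, sinus_grid, sinus_gene):
        r = solve_periodic_R_closed_form(sinus_grid, sinus_gene.true_k_d)
        k = compute_k_trans(2.0 * r.period_mean(), r)
        assert k == pytest.approx(2.0)

    def test_constant_mrna_gives_P_equals_mean(self):
        grid = constant_grid(10.0)
        k_d = 0.1
        r = solve_periodic_R_closed_form(grid, k_d)
        k_trans = compute_k_trans(1000.0, r)
        p = predict_protein(r, k_trans)
        np.testing.assert_allclose(p.values, 1000.0, rtol=1e-10)
        assert k_trans == pytest.approx(1000.0 * k_d / 10.0)

    def test_prediction_mean_matches_supplied_average(self, sinus_grid, sinus_gene):
        r = solve_periodic_R_closed_form(sinus_grid, sinus_gene.true_k_d)
        p = predict_protein(r, compute_k_trans(1234.5, r))
        assert p.period_mean() == pytest.approx(1234.5, rel=1e-14)

    def test_linearity_in_k_trans(self, sinus_grid, sinus_gene):
        r = solve_periodic_R_closed_form(sinus_grid, sinus_gene.true_k_d)
        p1 = predict_protein(r, 1.0)
        p2 = predict_protein(r, 2.0)
        np.testing.assert_allclose(p2.values, 2.0 * p1.values, rtol=1e-15)

    def test_zero_mRNA_raises(self):
        grid = constant_grid(0.0)
        r = solve_periodic_R_closed_form(grid, 0.1)
        with pytest.raises(ValueError, match="not positive"):
            compute_k_trans(100.0, r)
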