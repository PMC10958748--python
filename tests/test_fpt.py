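import numpy as np
import pytest
from scipy import stats
from scipy.integrate import trapezoid

from gapddm.core import ModelParams
from gapddm.fpt import (
    FPTSolution,
    GridResolutionError,
    convolve_nondecision,
    predicted_summary,
    simulate_trials,
    solve,
)
from gapddm.kinematics import Condition

# constant-coefficient drift-diffusion closed forms (mu=1, B=1, unit noise):
# P(upper) = 1 / (1 + exp(-2 mu B)),  E[T] = (B/mu) tanh(mu B)
P_UPPER_CLOSED = 1 / (1 + np.exp(-2))
MEAN_FPT_CLOSED = np.tanh(1.0)

# frozen initial drift = alpha*((tta0 + beta*d0) - theta_crit) = 1
CONST = ModelParams(alpha=1.0, beta=0.0, theta_crit=19.0, b0=1.0)
FAR = Condition(20.0, 100.0)  # censoring horizon far beyond the decision


class TestSolveClosedForm:
    def test_symmetric_zero_drift_splits_evenly(self):
        p = ModelParams(alpha=0.0, b0=1.0)
        s = solve(p, FAR, "const_drift_const_bound", t_max=15.0)
        assert s.p_go == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("dt,dx", [(0.005, 0.025), (0.002, 0.01)])
    def test_upper_probability(self, dt, dx):
        s = solve(CONST, FAR, "const_drift_const_bound", dt=dt, dx=dx, t_max=15.0)
        assert s.p_go == pytest.approx(P_UPPER_CLOSED, abs=1e-3)

    def test_mean_decision_time_converges(self):
        errs = []
        for dt, dx in [(0.005, 0.025), (0.002, 0.01)]:
            s = solve(CONST, FAR, "const_drift_const_bound", dt=dt, dx=dx, t_max=15.0)
            errs.append(abs(s.mean_decision_time() - MEAN_FPT_CLOSED))
        assert errs[0] / MEAN_FPT_CLOSED < 0.01
        assert errs[1] < errs[0]  # refinement moves toward the closed form


class TestSolutionInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_mass_conservation_random_params(self, seed):
        rng = np.random.default_rng(seed)
        p = ModelParams(
            alpha=rng.uniform(0.2, 1.0),
            beta=rng.uniform(0.02, 0.08),
            theta_crit=rng.uniform(8, 11),
            b0=rng.uniform(1.0, 2.5),
            k=rng.uniform(0.5, 2.5),
            tau=rng.uniform(2, 5),
            mu_nd=rng.uniform(0.2, 0.5),
            sigma_nd=rng.uniform(0.03, 0.1),
        )
        c = Condition(rng.choice([4.0, 5.0, 6.0]), rng.choice([90.0, 120.0, 150.0]))
        s = solve(p, c)
        assert s.p_go + s.p_stay == pytest.approx(1.0, abs=1e-3)
        assert np.all(s.go_density >= 0)
        assert trapezoid(s.go_density, s.time_grid) == pytest.approx(s.p_go, abs=1e-3)
        assert trapezoid(s.rt_density_observed, s.time_grid) == pytest.approx(
            s.p_go, abs=1e-3
        )

    def test_go_probability_monotone_in_design(self, truth_params):
        """More time or more distance never lowers the go probability."""
        for d0 in (90.0, 120.0, 150.0):
            ps = [solve(truth_params, Condition(t, d0)).p_go for t in (4, 5, 6)]
            assert np.all(np.diff(ps) >= 0)
        for tta0 in (4.0, 5.0, 6.0):
            ps = [solve(truth_params, Condition(tta0, d)).p_go for d in (90, 120, 150)]
            assert np.all(np.diff(ps) >= 0)

    def test_grid_refusal_on_extreme_drift(self):
        p = ModelParams(alpha=5.0, beta=1.0, theta_crit=2.0)
        with pytest.raises(GridResolutionError):
            solve(p, Condition(6, 150), dt=0.005, dx=0.025)


class TestSimulator:
    def test_deterministic_given_seed(self):
        a = simulate_trials(CONST, FAR, "const_drift_const_bound", n=200, seed=9, t_max=5.0)
        b = simulate_trials(CONST, FAR, "const_drift_const_bound", n=200, seed=9, t_max=5.0)
        assert a.equals(b)

    def test_symmetric_split(self):
        p = ModelParams(alpha=0.0, b0=1.0)
        df = simulate_trials(p, FAR, "const_drift_const_bound", n=20_000, seed=3, t_max=15.0)
        se = np.sqrt(0.25 / len(df))
        assert (df.decision == "go").mean() == pytest.approx(0.5, abs=3 * se)

    def test_matches_closed_form_upper_probability(self):
        df = simulate_trials(CONST, FAR, "const_drift_const_bound", n=50_000, seed=4, t_max=15.0)
        frac = (df.decision == "go").mean()
        se = np.sqrt(P_UPPER_CLOSED * (1 - P_UPPER_CLOSED) / len(df))
        assert frac == pytest.approx(P_UPPER_CLOSED, abs=3 * se + 0.003)

    def test_stay_trials_carry_no_rt(self, truth_params):
        df = simulate_trials(truth_params, Condition(4, 90), n=500, seed=5)
        assert df.loc[df.decision == "stay", "rt"].isna().all()
        assert df.loc[df.decision == "go", "rt"].notna().all()


class TestNondecisionConvolution:
    def test_delta_kernel_shifts_exactly(self):
        dt = 0.01
        dens = np.zeros(300)
        dens[50] = 1.0 / dt  # point mass at 0.5 s
        p = ModelParams(mu_nd=0.3, sigma_nd=0.0)
        out = convolve_nondecision(dens, p, dt)
        assert out[80] == pytest.approx(1.0 / dt)
        assert out.sum() * dt == pytest.approx(1.0, abs=1e-9)

    def test_delta_blurs_to_normal(self):
        dt = 0.002
        dens = np.zeros(1000)
        dens[250] = 1.0 / dt  # decision time 0.5 s
        p = ModelParams(mu_nd=0.3, sigma_nd=0.05)
        out = convolve_nondecision(dens, p, dt)
        t = dt * np.arange(1000)
        expected = stats.norm.pdf(t, 0.8, 0.05)
        assert np.max(np.abs(out - expected)) < 0.05 * expected.max()

    def test_mass_preserved(self, truth_params):
        s = solve(truth_params, Condition(5, 120))
        before = s.go_density.sum()
        after = s.rt_density_observed.sum()
        assert after == pytest.approx(before, rel=1e-3)


class TestPredictedSummary:
    def test_uniform_median(self):
        dt = 0.001
        grid = dt * np.arange(1001)
        dens = np.where(grid <= 1.0, 1.0, 0.0)
        sol = FPTSolution(
            time_grid=grid, go_density=dens, stay_density=np.zeros_like(dens),
            rt_density_observed=dens, p_go=1.0, p_stay=0.0, t_max=1.0,
        )
        p_go, q = predicted_summary(sol, [0.5])
        assert q[0] == pytest.approx(0.5, abs=2 * dt)

    def test_point_mass_with_shift_only(self):
        p = ModelParams(alpha=2.0, beta=0.0, theta_crit=19.0, b0=0.5, mu_nd=0.3, sigma_nd=0.0)
        s = solve(p, FAR, "const_drift_const_bound", t_max=10.0)
        # all quantiles of a sharply peaked density sit near mode + mu_nd
        _, q = predicted_summary(s, [0.1, 0.5, 0.9])
        assert np.all(np.diff(q) >= 0)

    def test_normal_tail_quantile(self):
        dt = 0.002
        grid = dt * np.arange(1500)
        dens = stats.norm.pdf(grid, 0.8, 0.05)
        sol = FPTSolution(
            time_grid=grid, go_density=dens, stay_density=np.zeros_like(dens),
            rt_density_observed=dens, p_go=1.0, p_stay=0.0, t_max=3.0,
        )
        _, q = predicted_summary(sol, [0.9])
        assert q[0] == pytest.approx(0.8 + 1.2815515655 * 0.05, abs=0.002)

    def test_no_go_mass_flags_quantiles_undefined(self):
        grid = np.linspace(0, 1, 100)
        zero = np.zeros_like(grid)
        sol = FPTSolution(
            time_grid=grid, go_density=zero, stay_density=zero,
            rt_density_observed=zero, p_go=0.0, p_stay=1.0, t_max=1.0,
        )
        p_go, q = predicted_summary(sol, [0.5])
        assert p_go == 0.0
        assert np.isnan(q).all()


class TestOracleEquivalence:
    """The PDE solve and the Monte-Carlo simulator must agree."""

    @pytest.mark.parametrize("variant", ["full", "var_drift_const_bound"])
    def test_solver_vs_simulation(self, variant, truth_params):
        c = Condition(5.0, 120.0)
        s = solve(truth_params, c, variant)
        mc = simulate_trials(truth_params, c, variant, n=20_000, dt=0.001, seed=17)
        frac_go = (mc.decision == "go").mean()
        assert abs(s.p_go - frac_go) < 0.015
        rts = mc.loc[mc.decision == "go", "rt"].to_numpy()
        cdf = s.rt_cdf() / s.p_go
        model_at = np.interp(np.sort(rts), s.time_grid, cdf)
        emp = np.arange(1, len(rts) + 1) / len(rts)
        assert np.max(np.abs(model_at - emp)) < 0.025
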