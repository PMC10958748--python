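import numpy as np
import pandas as pd
import pytest

from gapddm.core import ModelParams
from gapddm.fitting import (
    ConditionSummary,
    DESettings,
    fit,
    fit_per_participant,
    summarize_conditions,
    wls_loss,
)
from gapddm.fpt import solve
from gapddm.kinematics import Condition


def _trials(rows):
    return pd.DataFrame(rows, columns=["participant_id", "tta_condition", "d_condition", "decision", "rt"])


def noise_free_summaries(params, conditions, n_trials=200, levels=(0.1, 0.3, 0.5, 0.7, 0.9)):
    """Summaries whose targets are exactly the model's own predictions."""
    out = []
    for c in conditions:
        s = solve(params, c)
        n_go = int(round(s.p_go * n_trials))
        out.append(
            ConditionSummary(
                condition=c,
                n_trials=n_trials,
                n_go=n_go,
                p_go=s.p_go,
                go_rt_quantiles=s.rt_quantiles(levels),
                quantile_levels=levels,
                quantiles_valid=n_go >= 4,
            )
        )
    return out


class TestSummarize:
    def test_counts_and_median(self):
        rows = [(1, 4.0, 90.0, "go", 0.5 + 0.1 * i) for i in range(6)]
        rows += [(1, 4.0, 90.0, "stay", np.nan)] * 4
        (s,) = summarize_conditions(_trials(rows))
        assert s.n_trials == 10 and s.n_go == 6
        assert s.p_go == pytest.approx(0.6)
        assert s.quantiles_valid
        assert s.go_rt_quantiles[2] == pytest.approx(0.75)  # median of 0.5..1.0

    def test_sparse_go_marks_quantiles_invalid(self):
        rows = [(1, 5.0, 120.0, "go", 0.7)] * 3 + [(1, 5.0, 120.0, "stay", np.nan)] * 7
        (s,) = summarize_conditions(_trials(rows))
        assert not s.quantiles_valid

    def test_all_stay_condition(self):
        rows = [(1, 6.0, 150.0, "stay", np.nan)] * 5
        (s,) = summarize_conditions(_trials(rows))
        assert s.p_go == 0.0 and s.go_rt_quantiles is None

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            summarize_conditions(_trials([]))

    def test_invariant_to_trial_ordering(self, small_dataset):
        shuffled = small_dataset.sample(frac=1.0, random_state=0)
        a = summarize_conditions(small_dataset)
        b = summarize_conditions(shuffled)
        for x, y in zip(a, b):
            assert x.condition == y.condition
            assert x.p_go == pytest.approx(y.p_go)
            np.testing.assert_allclose(x.go_rt_quantiles, y.go_rt_quantiles)


class TestLoss:
    @pytest.fixture(scope="class")
    def summaries(self, truth_params):
        return noise_free_summaries(truth_params, [Condition(4, 120), Condition(6, 150)])

    def test_zero_at_perfect_fit(self, truth_params, summaries):
        # targets are the model's own predictions at the same grid settings
        assert wls_loss(truth_params, summaries) == pytest.approx(0.0, abs=1e-9)

    def test_linear_in_weights(self, truth_params, summaries):
        p = truth_params.replace(theta_crit=10.5)
        l1 = wls_loss(p, summaries, weight_p=2.0, weight_q=1.0)
        l2 = wls_loss(p, summaries, weight_p=4.0, weight_q=2.0)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_quantile_perturbation_quadratic(self, truth_params, summaries):
        s = summaries[0]
        delta = 0.08
        q = np.array(s.go_rt_quantiles, dtype=float)
        q[2] += delta
        bumped = ConditionSummary(
            condition=s.condition, n_trials=s.n_trials, n_go=s.n_go, p_go=s.p_go,
            go_rt_quantiles=q, quantile_levels=s.quantile_levels, quantiles_valid=True,
        )
        base = wls_loss(truth_params, summaries)
        l = wls_loss(truth_params, [bumped, summaries[1]])
        assert l - base == pytest.approx(1.0 * s.n_go * delta**2, rel=1e-6)


class TestFit:
    def test_one_parameter_recovery(self, truth_params, condition_grid):
        """With everything else fixed at truth, theta_crit is recovered."""
        summaries = noise_free_summaries(truth_params, condition_grid)
        fixed = truth_params.to_dict()
        del fixed["theta_crit"]
        res = fit(
            summaries, "full", fixed=fixed, seed=2,
            de_settings=DESettings(popsize=8, maxiter=40),
        )
        assert res.params.theta_crit == pytest.approx(truth_params.theta_crit, rel=0.02)
        assert res.loss == pytest.approx(
            wls_loss(res.params, summaries), rel=1e-6, abs=1e-9
        )

    def test_deterministic_given_seed(self, truth_params):
        summaries = noise_free_summaries(truth_params, [Condition(5, 120)])
        fixed = truth_params.to_dict()
        del fixed["mu_nd"]
        kw = dict(fixed=fixed, seed=5, de_settings=DESettings(popsize=4, maxiter=10))
        a = fit(summaries, "full", **kw)
        b = fit(summaries, "full", **kw)
        assert a.params == b.params and a.loss == b.loss

    def test_params_within_bounds(self, truth_params):
        summaries = noise_free_summaries(truth_params, [Condition(5, 120), Condition(4, 90)])
        fixed = truth_params.to_dict()
        del fixed["b0"], fixed["mu_nd"]
        res = fit(summaries, "full", fixed=fixed, seed=3,
                  de_settings=DESettings(popsize=4, maxiter=15))
        for name in res.free_names:
            lo, hi = res.search_bounds[name]
            assert lo <= res.params.to_dict()[name] <= hi


class TestFitPerParticipant:
    def test_duplicated_participant_fits_identically(self, truth_params):
        rng = np.random.default_rng(0)
        rows = []
        for tta0, d0 in [(4.0, 90.0), (6.0, 150.0)]:
            for i in range(20):
                go = rng.random() < 0.5
                rows.append((1, tta0, d0, "go" if go else "stay",
                             rng.uniform(0.5, 1.5) if go else np.nan))
        df = pd.concat([_trials(rows), _trials([(2, *r[1:]) for r in rows])])
        fixed = truth_params.to_dict()
        del fixed["theta_crit"], fixed["mu_nd"]
        results, skipped = fit_per_participant(
            df, "full", seed=4, fixed=fixed,
            de_settings=DESettings(popsize=4, maxiter=8),
        )
        assert not skipped
        assert results[1].params == results[2].params

    def test_single_condition_participant_skipped(self, truth_params):
        rows = [(9, 4.0, 90.0, "stay", np.nan)] * 10
        results, skipped = fit_per_participant(_trials(rows), "full", seed=1)
        assert skipped == [9] and not results
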