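"""Expected improvement, EI proposal search, the BO loop, and the
gradient-descent comparator."""

import numpy as np
import pytest
from scipy.stats import norm

from hilbo.gp import GPDataset, GPHyperparameters, posterior
from hilbo.optimizers import (
    BOConfig,
    EvalResult,
    GDConfig,
    expected_improvement,
    gd_step_size,
    initial_design,
    mu_best,
    propose_next,
    run_bayes_opt,
    run_gradient_descent,
)
from hilbo.protocol import SubjectEvaluator
from hilbo.simulator import SubjectProfile

HP = GPHyperparameters(sigma2=1.0, length_scale=0.2, noise2=0.04)


class TestExpectedImprovement:
    def test_zero_sd_is_zero(self):
        assert expected_improvement(5.0, 0.0, 4.0) == 0.0
        assert expected_improvement(3.0, 0.0, 4.0) == 0.0

    def test_symmetric_point_value(self):
        # mean == incumbent, sd = 1 -> EI = phi(0)
        assert expected_improvement(4.0, 1.0, 4.0) == \
            pytest.approx(norm.pdf(0.0), rel=1e-12)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(77)
        z = rng.standard_normal(10**6)
        for mean, sd, mb in [(5.0, 1.0, 4.5), (4.0, 0.3, 4.0),
                             (3.0, 2.0, 4.0), (6.0, 0.5, 4.0)]:
            draws = mean + sd * z
            imp = np.maximum(mb - draws, 0.0)
            mc, se = np.mean(imp), np.std(imp) / 1000.0
            assert abs(expected_improvement(mean, sd, mb) - mc) < 3 * se + 1e-12

    def test_translation_and_scale_invariance(self):
        ei = expected_improvement(5.0, 1.2, 4.4)
        assert expected_improvement(5.0 + 10, 1.2, 4.4 + 10) == \
            pytest.approx(ei, rel=1e-12)
        s = 7.0
        assert expected_improvement(5.0 * s, 1.2 * s, 4.4 * s) == \
            pytest.approx(ei * s, rel=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(8)
        m = rng.normal(0, 5, 200)
        s = rng.uniform(0, 2, 200)
        assert np.all(expected_improvement(m, s, 0.0) >= 0)


class TestMuBest:
    def test_single_datum(self):
        assert mu_best(GPDataset([1.8], [4.2]), HP) == pytest.approx(4.2)

    def test_interpolation_limit_equals_min_y(self):
        hp = GPHyperparameters(1.0, 0.2, 1e-12)
        data = GPDataset([1.5, 1.8, 2.1], [5.0, 4.0, 4.5])
        assert mu_best(data, hp) == pytest.approx(4.0, abs=1e-6)

    def test_duplicate_noisy_observations_shrink(self):
        data = GPDataset([1.8, 1.8], [3.0, 5.0])
        mb = mu_best(data, HP)
        assert 3.0 < mb < 5.0
        post = posterior(data, HP)
        assert mb == pytest.approx(float(post.mean(1.8)), rel=1e-12)


class TestProposeNext:
    def test_beats_dense_grid(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            r = np.random.default_rng(seed)
            data = GPDataset(r.uniform(1.4, 2.2, 6), r.normal(4, 0.5, 6))
            x = propose_next(data, HP, (1.35, 2.25), rng=r)
            post = posterior(data, HP)
            mb = float(np.min(post.mean(data.X)))
            grid = np.linspace(1.35, 2.25, 1000)
            ei_grid = expected_improvement(post.mean(grid), post.sd(grid), mb)
            ei_x = expected_improvement(post.mean(np.array([x])),
                                        post.sd(np.array([x])), mb)[0]
            assert ei_x >= ei_grid.max() - 1e-9
            assert 1.35 <= x <= 2.25

    def test_explores_away_from_equal_data(self):
        data = GPDataset([1.7, 1.9], [4.0, 4.0])
        x = propose_next(data, HP, (1.35, 2.25), rng=0)
        # proposal should sit in unexplored high-variance territory
        assert min(abs(x - 1.7), abs(x - 1.9)) > 0.05

    def test_symmetric_data_tie_breaks_low(self):
        center = 1.8
        data = GPDataset([center - 0.15, center + 0.15], [4.0, 4.0])
        x = propose_next(data, HP, (center - 0.45, center + 0.45), rng=3)
        post = posterior(data, HP)
        mb = float(np.min(post.mean(data.X)))

        def ei(z):
            return expected_improvement(post.mean(np.array([z])),
                                        post.sd(np.array([z])), mb)[0]

        assert ei(x) == pytest.approx(ei(2 * center - x), rel=1e-5)
        assert x <= center  # lowest-frequency tie rule

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        data = GPDataset(rng.uniform(1.4, 2.2, 5), rng.normal(4, 0.5, 5))
        assert propose_next(data, HP, (1.35, 2.25), rng=42) == \
            propose_next(data, HP, (1.35, 2.25), rng=42)


class TestInitialDesign:
    def test_draws_fall_in_thirds(self):
        x_pref = 2.0
        edges = np.array([0.75, 0.75 + 0.5 / 3, 1.25 - 0.5 / 3, 1.25]) * x_pref
        for seed in range(20):
            d = np.sort(initial_design(x_pref, seed))
            for k in range(3):
                assert edges[k] <= d[k] <= edges[k + 1]

    def test_deterministic(self):
        np.testing.assert_array_equal(initial_design(1.8, 9),
                                      initial_design(1.8, 9))

    def test_per_interval_uniformity(self):
        x_pref = 1.8
        rng = np.random.default_rng(0)
        draws = np.sort([initial_design(x_pref, rng) for _ in range(10_000)],
                        axis=1)
        edges = np.linspace(0.75, 1.25, 4) * x_pref
        for k in range(3):
            lo, hi = edges[k], edges[k + 1]
            se = (hi - lo) / np.sqrt(12 * 10_000)
            assert abs(np.mean(draws[:, k]) - (lo + hi) / 2) < 3 * se


class TestGDStepSize:
    def test_schedule_values(self):
        cfg = GDConfig()
        assert gd_step_size(0, cfg) == pytest.approx(4e-4)
        assert gd_step_size(3, cfg) == pytest.approx(4e-4 / 2)

    def test_monotone_decreasing_to_zero(self):
        cfg = GDConfig()
        vals = [gd_step_size(n, cfg) for n in range(100)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert gd_step_size(10**6, cfg) < 1e-8


def quad_subject(x_opt_frac=1.05):
    """Noiseless subject whose landscape argmin is offset from preferred."""
    return SubjectProfile(x_pref=1.8, x_opt=1.8 * x_opt_frac).noiseless()


class TestGradientDescent:
    def test_matches_closed_form_recursion(self):
        """Iterates equal x_{n+1} = x_n - alpha_n*2a(x_n - x_opt) on a
        noiseless quadratic, to machine precision."""
        subj = quad_subject(0.95)
        cfg = GDConfig(cost_units="watt", seed=11)
        ev = SubjectEvaluator(subj, gd_cost_units="watt", evals_per_bout=None)
        traj = run_gradient_descent(ev, cfg)
        a_q = subj.mass * subj.curvature / subj.x_pref**2  # W/Hz^2
        # reproduce the seeded initialization
        rng = np.random.default_rng(cfg.seed)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        x = (1.0 + sign * 0.20) * subj.x_pref
        lo, hi = cfg.domain(subj.x_pref)
        for n, step in enumerate(traj.steps):
            assert step.x_cmd == pytest.approx(x, rel=1e-9)
            x = np.clip(x - gd_step_size(n, cfg) * 2 * a_q * (x - subj.x_opt),
                        lo, hi)

    def test_stationary_at_optimum(self):
        subj = quad_subject(1.0)
        cfg = GDConfig(cost_units="watt", init_offset=0.0, n_iterations=5)
        ev = SubjectEvaluator(subj, gd_cost_units="watt")
        traj = run_gradient_descent(ev, cfg)
        np.testing.assert_allclose(traj.x_cmd, subj.x_pref, rtol=1e-9)

    def test_linear_cost_gives_constant_slope(self):
        class LinearEvaluator:
            x_pref = 1.8

            def evaluate_gradient(self, x_cmd, delta, rng):
                from hilbo.optimizers import GradientEvalResult
                from hilbo.respiratory import CostModel
                return GradientEvalResult(
                    model=CostModel(lambda1=50.0, lambda0=10.0),
                    x_meas=x_cmd, duration_s=240.0, cost_units="watt")

        cfg = GDConfig(cost_units="watt", seed=2, n_iterations=6)
        traj = run_gradient_descent(LinearEvaluator(), cfg)
        x = traj.x_cmd
        steps = -np.diff(x)
        alphas = np.array([gd_step_size(n, cfg) for n in range(5)])
        np.testing.assert_allclose(steps, alphas * 50.0, rtol=1e-12)

    def test_commands_stay_in_domain(self):
        subj = SubjectProfile(x_pref=1.8)  # noisy
        cfg = GDConfig(seed=5)
        ev = SubjectEvaluator(subj)
        traj = run_gradient_descent(ev, cfg)
        lo, hi = cfg.domain(subj.x_pref)
        assert np.all(traj.x_cmd >= lo - 1e-12)
        assert np.all(traj.x_cmd <= hi + 1e-12)

    def test_monotone_convergence_on_contractive_quadratic(self):
        subj = quad_subject(0.95)
        cfg = GDConfig(cost_units="watt", seed=1, n_iterations=10)
        ev = SubjectEvaluator(subj, gd_cost_units="watt")
        traj = run_gradient_descent(ev, cfg)
        err = np.abs(traj.x_cmd - subj.x_opt)
        a_q = subj.mass * subj.curvature / subj.x_pref**2
        contractive = np.array(
            [gd_step_size(n, cfg) * 2 * a_q < 1 for n in range(len(err) - 1)])
        dec = np.diff(err) <= 1e-12
        assert np.all(dec[contractive])


class TestBayesOpt:
    def test_noiseless_quadratic_recovery(self):
        subj = quad_subject(1.05)
        cfg = BOConfig(n_iterations=6, seed=3)
        ev = SubjectEvaluator(subj)
        traj = run_bayes_opt(ev, cfg)
        ei_steps = [s for s in traj.steps if s.phase == "ei"]
        best = min(ei_steps, key=lambda s: s.cost)
        assert abs(best.x_cmd - subj.x_opt) / subj.x_pref < 0.01

    def test_constant_evaluator_stays_in_domain(self):
        class ConstantEvaluator:
            x_pref = 1.8

            def evaluate(self, x_cmd, rng):
                return EvalResult(cost=4.0, x_meas=x_cmd, duration_s=120.0)

        cfg = BOConfig(n_iterations=4, seed=1)
        traj = run_bayes_opt(ConstantEvaluator(), cfg)
        assert len(traj) == 3 + 4
        lo, hi = cfg.domain(1.8)
        assert np.all(traj.x_cmd >= lo - 1e-12)
        assert np.all(traj.x_cmd <= hi + 1e-12)

    def test_replay_determinism(self):
        subj = SubjectProfile(x_pref=1.9)
        cfg = BOConfig(n_iterations=4, seed=21)
        t1 = run_bayes_opt(SubjectEvaluator(subj), cfg)
        t2 = run_bayes_opt(SubjectEvaluator(subj), cfg)
        np.testing.assert_array_equal(t1.x_cmd, t2.x_cmd)
        np.testing.assert_array_equal(t1.costs, t2.costs)

    def test_monotone_incumbent_on_noiseless_landscapes(self):
        """Best-so-far true cost is non-increasing across iterations."""
        from hilbo.simulator import true_cost

        for seed in range(20):
            subj = SubjectProfile(
                x_pref=float(np.random.default_rng(seed).uniform(1.7, 2.0))
            ).noiseless()
            cfg = BOConfig(n_iterations=4, seed=seed)
            traj = run_bayes_opt(SubjectEvaluator(subj), cfg)
            truth = true_cost(subj, traj.x_cmd)
            running = np.minimum.accumulate(truth)
            assert np.all(np.diff(running) <= 1e-12)

    def test_hyperparameters_recorded_after_second_evaluation(self):
        subj = SubjectProfile()
        cfg = BOConfig(n_iterations=2, seed=4)
        traj = run_bayes_opt(SubjectEvaluator(subj), cfg)
        assert traj.steps[0].hp is None
        assert all(s.hp is not None for s in traj.steps[1:])
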