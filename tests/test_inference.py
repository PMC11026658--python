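"""MAP estimation, null models and information criteria.

The key correctness checks compare the L-BFGS-B optima against dense
grid-search oracles of the same MAP objective, and exercise the nesting and
prior-shrinkage behaviour the estimators must satisfy.
"""

import math

import numpy as np
import pytest

from blt.inference import (
    DEFAULT_PRIORS,
    PriorSpec,
    bayes_factor,
    fit_binary,
    fit_continuous,
    fit_dual,
    fit_null,
    information_criteria,
    pool_fits,
)
from blt.models import (
    binary_loglik,
    continuous_loglik,
    rw_trajectory,
)
from blt.recovery import simulate_binary, simulate_continuous
from blt.task import build_schedule


def _binary_map_objective(yb, schedule, alpha, beta, priors=DEFAULT_PRIORS):
    traj = rw_trajectory(schedule.o, alpha)
    return (
        binary_loglik(yb, traj, beta)
        + float(priors["alpha"].logpdf(alpha))
        + float(priors["beta"].logpdf(beta))
    )


def _continuous_map_objective(y, schedule, alpha, phi, priors=DEFAULT_PRIORS):
    traj = rw_trajectory(schedule.o, alpha)
    return continuous_loglik(y, traj, phi) + float(
        priors["alpha"].logpdf(alpha)
    )


class TestInformationCriteria:
    def test_aic_direct_substitution(self):
        bic, aic = information_criteria(-100.0, 2, 80)
        assert aic == pytest.approx(204.0)
        assert bic == pytest.approx(200.0 + 2.0 * math.log(80))

    def test_no_parameters_no_penalty(self):
        bic, aic = information_criteria(-50.0, 0, 80)
        assert bic == aic == pytest.approx(100.0)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            information_criteria(-1.0, 1, 0)


class TestBayesFactor:
    def test_printed_worked_example(self):
        # scores reported to the nearest integer carry +/-0.5 slack each,
        # i.e. a factor of up to e^0.5 on the Bayes factor
        bf = bayes_factor(1691.0, 1253.0)
        assert bf == pytest.approx(math.exp(219.0), rel=1e-12)
        assert math.log(bf) == pytest.approx(math.log(1.36e95), abs=0.5)

    def test_equal_scores_no_preference(self):
        assert bayes_factor(-500.0, -500.0) == 1.0

    def test_moderate_difference(self):
        assert bayes_factor(-1298.0, -1315.0) == pytest.approx(
            math.exp(8.5), rel=1e-12
        )

    def test_decisive_difference_saturates_to_inf(self):
        assert bayes_factor(0.0, -5000.0) == math.inf


class TestBinaryFit:
    def test_recovers_generating_rate_at_low_noise(self):
        schedule = build_schedule(seed=5)
        yb = simulate_binary(0.3, 50.0, schedule, seed=6)
        (fit,) = fit_binary(yb, schedule)
        assert fit.converged
        assert fit.estimates["alpha"] == pytest.approx(0.3, abs=0.1)
        assert fit.kappa == 2
        assert fit.n_obs == 80

    def test_matches_grid_oracle(self):
        schedule = build_schedule(seed=5)
        yb = simulate_binary(0.45, 4.0, schedule, seed=8)
        (fit,) = fit_binary(yb, schedule)
        alphas = np.linspace(0, 1, 101)
        betas = np.linspace(0.2, 12, 60)
        grid_best = max(
            _binary_map_objective(yb, schedule, a, b)
            for a in alphas
            for b in betas
        )
        # the optimiser must do at least as well as the dense grid
        assert fit.log_posterior >= grid_best - 1e-6
        best_a = max(
            alphas,
            key=lambda a: max(
                _binary_map_objective(yb, schedule, a, b) for b in betas
            ),
        )
        assert fit.estimates["alpha"] == pytest.approx(best_a, abs=0.02)

    def test_uninformative_data_shrinks_to_prior_mean(self):
        # constant responses carry no information about learning dynamics,
        # so the posterior in alpha is dominated by the prior
        schedule = build_schedule(seed=5)
        yb = np.ones(80)
        (fit,) = fit_binary(yb, schedule)
        alphas = np.linspace(0, 1, 401)
        grid_alpha = max(
            alphas,
            key=lambda a: _binary_map_objective(
                yb, schedule, a, fit.estimates["beta"]
            ),
        )
        assert fit.estimates["alpha"] == pytest.approx(grid_alpha, abs=0.01)

    def test_objective_no_worse_than_start(self):
        schedule = build_schedule(seed=5)
        yb = simulate_binary(0.7, 2.0, schedule, seed=9)
        (fit,) = fit_binary(yb, schedule)
        start = _binary_map_objective(yb, schedule, 0.34, 4.21)
        assert fit.log_posterior >= start - 1e-9

    def test_estimates_respect_bounds(self):
        schedule = build_schedule(seed=5)
        Y = simulate_binary(
            np.array([0.0, 0.5, 1.0]), 1.0, schedule, seed=10
        )
        for fit in fit_binary(Y, schedule):
            assert 0.0 <= fit.estimates["alpha"] <= 1.0
            assert fit.estimates["beta"] > 0


class TestContinuousFit:
    def test_noise_free_single_subject(self):
        schedule = build_schedule(seed=5)
        y = simulate_continuous(0.2, 0.0, schedule, seed=0)
        fit = fit_continuous(y, schedule)
        assert fit.estimates["alpha"][0] == pytest.approx(0.2, abs=0.01)
        assert fit.estimates["phi"] > 100  # noise-free: phi driven very high
        assert fit.kappa == 2  # one alpha + shared phi
        assert fit.converged

    def test_matches_grid_oracle_single_subject(self):
        schedule = build_schedule(seed=5)
        y = simulate_continuous(0.35, 0.15, schedule, seed=3)
        fit = fit_continuous(y, schedule)
        alphas = np.linspace(0, 1, 81)
        phis = np.geomspace(0.5, 400, 80)
        grid_best = max(
            _continuous_map_objective(y, schedule, a, p)
            for a in alphas
            for p in phis
        )
        assert fit.log_posterior >= grid_best - 1e-6

    def test_identical_subjects_get_identical_estimates(self):
        schedule = build_schedule(seed=5)
        y = simulate_continuous(0.3, 0.1, schedule, seed=4)
        fit = fit_continuous(np.vstack([y, y]), schedule)
        a = fit.estimates["alpha"]
        assert a[0] == pytest.approx(a[1], abs=1e-5)

    def test_recovered_phi_decreases_with_noise(self):
        schedule = build_schedule(seed=5)
        rng = np.random.default_rng(2)
        from blt.recovery import draw_alpha

        alpha = draw_alpha(60, seed=rng)
        phis = []
        for sigma in (0.05, 0.1, 0.2, 0.4):
            Y = simulate_continuous(alpha, sigma, schedule, rng)
            phis.append(fit_continuous(Y, schedule).estimates["phi"])
        assert np.all(np.diff(phis) < 0)

    def test_missing_responses_tolerated(self):
        schedule = build_schedule(seed=5)
        y = simulate_continuous(0.25, 0.1, schedule, seed=5)
        y[::7] = np.nan
        fit = fit_continuous(y, schedule)
        assert fit.n_obs == int(np.isfinite(y).sum())


class TestDualFit:
    def test_equal_rate_data_gives_similar_estimates(self):
        schedule = build_schedule(seed=5)
        y = simulate_continuous(0.3, 0.05, schedule, seed=6)
        fit = fit_dual(y, schedule, model="continuous")
        assert fit.estimates["alpha_p"][0] == pytest.approx(
            fit.estimates["alpha_n"][0], abs=0.12
        )

    def test_dual_nests_single_loglik(self):
        schedule = build_schedule(seed=5)
        rng = np.random.default_rng(3)
        from blt.recovery import draw_alpha

        alpha = draw_alpha(20, seed=rng)
        Y = simulate_continuous(alpha, 0.2, schedule, rng)
        single = fit_continuous(Y, schedule)
        dual = fit_dual(Y, schedule, model="continuous")
        # evaluate the dual likelihood at the single-rate solution: it can
        # only improve at the dual optimum
        from blt.models import rw_dual_traj_grad
        from blt.inference import _PHI_MAX  # noqa: F401

        assert dual.loglik >= single.loglik - 0.5
        assert dual.kappa == 2 * 20 + 1

    def test_binary_dual_variant(self):
        schedule = build_schedule(seed=5)
        yb = simulate_binary(0.4, 6.0, schedule, seed=11)
        (fit,) = fit_dual(yb, schedule, model="binary")
        assert set(fit.estimates) == {"alpha_p", "alpha_n", "beta"}
        assert fit.kappa == 3


class TestNullModels:
    def test_binary_null_closed_form(self):
        schedule = build_schedule(seed=5)
        yb = simulate_binary(0.3, 3.0, schedule, seed=12)
        null = fit_null(yb, schedule, "binary")
        assert null.loglik == pytest.approx(80 * math.log(0.5))
        assert null.loglik == pytest.approx(-55.4518, abs=1e-4)
        assert null.kappa == 1

    def test_continuous_null_matches_grid_oracle(self):
        schedule = build_schedule(seed=5)
        y = simulate_continuous(0.2, 0.2, schedule, seed=13)
        null = fit_null(y, schedule, "continuous")
        phis = np.geomspace(1e-3, 500, 4000)
        traj = rw_trajectory(schedule.o, 0.0)
        grid = [continuous_loglik(y, traj, p) for p in phis]
        assert null.loglik >= max(grid) - 1e-6
        assert null.estimates["phi"] == pytest.approx(
            phis[int(np.argmax(grid))], rel=0.01
        )

    def test_null_never_beats_learning_model(self):
        schedule = build_schedule(seed=5)
        rng = np.random.default_rng(4)
        from blt.recovery import draw_alpha

        alpha = draw_alpha(15, seed=rng)
        Y = simulate_continuous(alpha, 0.15, schedule, rng)
        null = fit_null(Y, schedule, "continuous")
        full = fit_continuous(Y, schedule)
        assert null.loglik <= full.loglik
        assert full.bic < null.bic  # learning clearly present

        YB = simulate_binary(alpha, 5.0, schedule, rng)
        null_b = fit_null(YB, schedule, "binary")
        full_b = pool_fits(fit_binary(YB, schedule))
        assert null_b.loglik <= full_b.loglik

    def test_unknown_model_rejected(self):
        schedule = build_schedule(seed=5)
        with pytest.raises(ValueError):
            fit_null(np.full(80, 0.5), schedule, "gaussian")


class TestPriorSpec:
    def test_flat_prior_contributes_nothing(self):
        p = PriorSpec(None, None, 0.0, 10.0)
        assert float(p.logpdf(3.0)) == 0.0
        assert float(p.dlogpdf(3.0)) == 0.0

    def test_gaussian_logpdf_shape(self):
        p = PriorSpec(0.34, 0.88, 0.0, 1.0)
        assert float(p.logpdf(0.34)) == 0.0
        assert float(p.logpdf(0.9)) < 0.0

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(0.0, -1.0)


def test_pool_fits_sums_components():
    schedule = build_schedule(seed=5)
    Y = simulate_binary(np.array([0.2, 0.6]), 4.0, schedule, seed=14)
    fits = fit_binary(Y, schedule)
    pooled = pool_fits(fits)
    assert pooled.loglik == pytest.approx(sum(f.loglik for f in fits))
    assert pooled.kappa == 4
    assert pooled.n_obs == 160
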