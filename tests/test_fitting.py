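"""Least-squares objective, chi-square, model fits and bootstrap errors."""

import math

import numpy as np
import pytest

from radiocsc import (
    CombinedModel,
    FitConfig,
    IMKParameters,
    LQParameters,
    MixtureModel,
    NTEParameters,
    SimulationConfig,
    SurvivalDataset,
    SurvivalObservation,
    chi_square,
    fit_lq,
    fit_mixture,
    fit_nte,
    microdosimetric_factor,
    mixture_log_survival,
    objective,
    simulate_survival,
    standard_errors,
)

FAST = FitConfig(n_samples=2_000, polish_starts=10, seed=0)


def noise_free(truth, spec, doses=(0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0), seed=0):
    return simulate_survival(
        SimulationConfig(
            truth=truth, spec=spec, doses=doses, n_replicates=1, sigma_log=0.0, seed=seed
        )
    )


class TestObjective:
    def test_zero_for_generating_parameters(self, du145_mixture, spec):
        ds = noise_free(du145_mixture, spec)
        assert objective(du145_mixture, ds, spec) == pytest.approx(0.0, abs=1e-20)

    def test_single_point_unit_deviation(self):
        # model gives S = e^-2 at 2 Gy, observation is e^-1 -> (1)^2
        ds = SurvivalDataset("x", [SurvivalObservation(2.0, math.exp(-1.0))])
        assert objective(LQParameters(1.0, 0.0), ds) == pytest.approx(1.0)

    def test_truth_beats_perturbed_parameters_under_noise(self, du145_mixture, spec):
        wins = 0
        for seed in range(100):
            ds = simulate_survival(
                SimulationConfig(
                    truth=du145_mixture,
                    spec=spec,
                    n_replicates=3,
                    sigma_log=0.05,
                    seed=seed,
                )
            )
            at_truth = objective(du145_mixture, ds, spec)
            perturbed = MixtureModel(
                pc=IMKParameters(du145_mixture.pc.alpha0 * 1.2, du145_mixture.pc.beta0 * 0.8),
                csc=du145_mixture.csc,
                f_csc=du145_mixture.f_csc,
            )
            if at_truth < objective(perturbed, ds, spec):
                wins += 1
        assert wins >= 95


class TestChiSquare:
    def test_exact_model_gives_zero(self, du145_mixture, spec):
        ds = simulate_survival(
            SimulationConfig(truth=du145_mixture, spec=spec, n_replicates=3, sigma_log=0.1, seed=0)
        )
        assert chi_square(ds.survival, ds) == pytest.approx(0.0)

    def test_single_point(self):
        ds = SurvivalDataset("x", [SurvivalObservation(2.0, 0.5, sd=0.1)])
        assert chi_square([0.4], ds) == pytest.approx(1.0)

    def test_two_points_averaged(self):
        ds = SurvivalDataset(
            "x",
            [
                SurvivalObservation(2.0, 0.5, sd=1.0),
                SurvivalObservation(4.0, 0.8, sd=1.0),
            ],
        )
        assert chi_square([0.6, 0.5], ds) == pytest.approx(0.05)

    def test_zero_sd_points_excluded_with_warning(self):
        ds = SurvivalDataset(
            "x",
            [
                SurvivalObservation(2.0, 0.5, sd=0.1),
                SurvivalObservation(4.0, 0.2, sd=0.0),
            ],
        )
        with pytest.warns(UserWarning, match="excluded"):
            value = chi_square([0.4, 0.1], ds)
        assert value == pytest.approx(1.0)

    def test_all_zero_sd_undefined(self):
        ds = SurvivalDataset("x", [SurvivalObservation(2.0, 0.5, sd=0.0)])
        with pytest.raises(ValueError, match="undefined"):
            chi_square([0.4], ds)


class TestFitLQ:
    def test_noise_free_recovery(self, spec):
        truth = LQParameters(0.5, 0.02)
        ds = noise_free(truth, spec, doses=(0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0))
        res = fit_lq(ds, FAST)
        assert res.theta.alpha == pytest.approx(0.5, rel=1e-2)
        assert res.theta.beta == pytest.approx(0.02, rel=1e-2)
        assert res.objective < 1e-10

    def test_pure_linear_pins_beta_at_zero(self, spec):
        ds = noise_free(LQParameters(0.4, 0.0), spec)
        res = fit_lq(ds, FAST)
        assert res.theta.beta == pytest.approx(0.0, abs=1e-8)

    def test_median_alpha_error_under_noise(self, spec):
        truth = LQParameters(0.5, 0.02)
        errors = []
        for seed in range(50):
            ds = simulate_survival(
                SimulationConfig(
                    truth=truth,
                    spec=spec,
                    doses=(0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0),
                    n_replicates=3,
                    sigma_log=0.1,
                    seed=seed,
                )
            )
            res = fit_lq(ds, FitConfig(n_samples=1_000, polish_starts=5, seed=seed))
            errors.append(abs(res.theta.alpha / truth.alpha - 1.0))
        assert np.median(errors) < 0.10

    def test_deterministic_in_seed(self, spec):
        ds = simulate_survival(
            SimulationConfig(truth=LQParameters(0.6, 0.01), spec=spec, sigma_log=0.1, seed=2)
        )
        r1, r2 = fit_lq(ds, FAST), fit_lq(ds, FAST)
        assert r1.theta == r2.theta and r1.objective == r2.objective


class TestFitMixture:
    def test_constraint_always_satisfied(self, spec, du145_mixture):
        for seed in range(5):
            ds = simulate_survival(
                SimulationConfig(
                    truth=du145_mixture, spec=spec, n_replicates=3, sigma_log=0.15, seed=seed
                )
            )
            res = fit_mixture(ds, spec, FitConfig(n_samples=5_000, polish_starts=20, seed=seed))
            assert res.theta.csc.alpha0 <= res.theta.pc.alpha0 + 1e-12
            assert res.theta.csc.beta0 <= res.theta.pc.beta0 + 1e-12
            assert 0.0 <= res.theta.f_csc <= 1.0

    def test_noise_free_recovery_and_fraction_bracket(self, spec, du145_mixture):
        doses = tuple(np.arange(0.0, 10.5, 0.5))
        ds = noise_free(du145_mixture, spec, doses=doses)
        res = fit_mixture(ds, spec, FitConfig(n_samples=20_000, seed=1))
        assert res.objective < 1e-6
        # weakly identifiable fraction: assert bracketing, not equality
        assert 0.0005 <= res.theta.f_csc <= 0.005
        pred = np.exp(np.asarray(mixture_log_survival(res.theta, spec, ds.doses)))
        np.testing.assert_allclose(pred, ds.survival, rtol=1e-3)

    def test_single_population_data_degenerates_cleanly(self, spec):
        single = IMKParameters(0.3, 0.05)
        ds = noise_free(single, spec)
        res = fit_mixture(ds, spec, FitConfig(n_samples=10_000, seed=0))
        # nested-model degeneracy: matches the single-population optimum
        assert res.objective < 1e-10
        embedded = MixtureModel(pc=single, csc=single, f_csc=0.0)
        assert res.objective <= objective(embedded, ds, spec) + 1e-10


class TestFitNTE:
    def test_noise_free_recovery(self, spec):
        truth = CombinedModel(
            te=IMKParameters(0.9, 0.02),
            nte=NTEParameters(
                delta=1.0, alpha_b=1.0, beta_b=0.02, gamma=microdosimetric_factor(spec)
            ),
        )
        ds = noise_free(truth, spec)
        res = fit_nte(ds, spec, FitConfig(n_samples=20_000, seed=0))
        assert res.objective < 1e-6

    def test_pure_targeted_data_yields_negligible_bystander_term(self, spec):
        from radiocsc import nte_log_survival

        te = IMKParameters(0.3, 0.05)
        truth = CombinedModel(te=te, nte=NTEParameters(0.0, 0.0, 0.0, 0.954))
        ds = noise_free(truth, spec)
        res = fit_nte(ds, spec, FitConfig(n_samples=10_000, seed=1))
        assert res.objective < 1e-10
        bystander = np.asarray(
            nte_log_survival(res.theta.nte, np.linspace(0.0, 10.0, 41))
        )
        assert np.max(bystander) < 1e-6

    def test_low_dose_hypersensitivity_needs_bystander_term(self, spec):
        """Data with extra low-dose kill: the bystander-extended fit beats
        the targeted-effect-only fit (delta pinned at zero)."""
        truth = CombinedModel(
            te=IMKParameters(0.9, 0.02),
            nte=NTEParameters(
                delta=1.0, alpha_b=1.0, beta_b=0.02, gamma=microdosimetric_factor(spec)
            ),
        )
        ds = noise_free(truth, spec)
        full = fit_nte(ds, spec, FitConfig(n_samples=20_000, seed=0))
        te_only = fit_nte(ds, spec, FitConfig(n_samples=20_000, seed=0, delta_max=0.0))
        assert full.objective < te_only.objective


class TestNestedModelOrdering:
    def test_mixture_objective_beats_embedded_lq_fit(self, spec):
        """Any LQ curve with alpha >= z*beta embeds as an f=0 mixture, so
        the mixture fit can only improve on such an embedded optimum."""
        z = microdosimetric_factor(spec)
        truth = LQParameters(0.658, 0.002)  # alpha >> z*beta
        ds = simulate_survival(
            SimulationConfig(truth=truth, spec=spec, n_replicates=3, sigma_log=0.1, seed=3)
        )
        lq = fit_lq(ds, FitConfig(n_samples=10_000, seed=0))
        single = IMKParameters(lq.theta.alpha - z * lq.theta.beta, lq.theta.beta)
        embedded = MixtureModel(pc=single, csc=single, f_csc=0.0)
        mix = fit_mixture(ds, spec, FitConfig(n_samples=10_000, seed=0))
        assert mix.objective <= objective(embedded, ds, spec) + 1e-9


class TestStandardErrors:
    def test_noise_free_errors_vanish(self, spec):
        ds = noise_free(LQParameters(0.5, 0.02), spec)
        res = fit_lq(ds, FAST)
        ses = standard_errors(
            res, ds, FitConfig(n_samples=1_000, polish_starts=5, seed=0, n_bootstrap=50)
        )
        assert ses["alpha"] == pytest.approx(0.0, abs=1e-6)
        assert ses["beta"] == pytest.approx(0.0, abs=1e-6)

    def test_identical_seed_identical_errors(self, spec):
        ds = simulate_survival(
            SimulationConfig(truth=LQParameters(0.5, 0.02), spec=spec, sigma_log=0.1, seed=4)
        )
        res = fit_lq(ds, FAST)
        cfg = FitConfig(n_samples=1_000, polish_starts=5, seed=7, n_bootstrap=30)
        assert standard_errors(res, ds, cfg) == standard_errors(res, ds, cfg)

    def test_bootstrap_calibrated_within_factor_three(self, spec):
        """Bootstrap SE of alpha agrees with the across-realisation SD of
        fitted alpha from fresh datasets, within a factor of three."""
        truth = LQParameters(0.5, 0.02)
        doses = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
        cfg = FitConfig(n_samples=1_000, polish_starts=5, seed=0)
        fresh = []
        for seed in range(50):
            ds = simulate_survival(
                SimulationConfig(
                    truth=truth, spec=spec, doses=doses, n_replicates=3, sigma_log=0.1, seed=seed
                )
            )
            fresh.append(fit_lq(ds, cfg).theta.alpha)
        true_sd = np.std(fresh, ddof=1)
        ds0 = simulate_survival(
            SimulationConfig(
                truth=truth, spec=spec, doses=doses, n_replicates=3, sigma_log=0.1, seed=0
            )
        )
        res = fit_lq(ds0, cfg)
        se = standard_errors(
            res, ds0, FitConfig(n_samples=1_000, polish_starts=5, seed=1, n_bootstrap=100)
        )["alpha"]
        assert true_sd / 3 <= se <= true_sd * 3

    def test_too_few_resamples_rejected(self, spec):
        ds = noise_free(LQParameters(0.5, 0.02), spec)
        res = fit_lq(ds, FAST)
        with pytest.raises(ValueError):
            standard_errors(res, ds, FitConfig(n_bootstrap=1))
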