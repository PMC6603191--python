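"""MCMC inference: likelihood, sampler, summaries, goodness of fit."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imk import (
    FieldConfig, FitContext, GeneratorConfig, PriorSpec, SurvivalDataset,
    chi_squared, generate_dose_response, log_likelihood, nte_params,
    posterior_summary, r_squared, run_mcmc, te_params,
)
from imk.errors import DiagnosticError, ValidationError
from imk.inference import PARAM_NAMES, NormalPrior, log_posterior

TRUTH = {"alpha0": 0.363, "alpha_b": 0.388, "beta_b": 0.031, "delta": 0.617}
GUESS = {"alpha0": 0.4, "alpha_b": 0.4, "beta_b": 0.03, "delta": 0.6}
THETA_TRUE = np.array([TRUTH[p] for p in PARAM_NAMES])


def make_data(seed=1, noise_sd=0.0, doses=tuple(np.arange(0, 10.5, 0.5)),
              n_replicates=3):
    """Three-region dose-response data generated from the AGO1522
    modulated-field parameter set (all regions share its TE coefficients)."""
    cfg = GeneratorConfig(
        seed=seed, cell_line="AGO1522", a_if=0.5, noise_sd=noise_sd,
        n_replicates=n_replicates, doses=doses,
        regions=("in_field", "out_of_field", "uniform"),
        te_condition="half_field", idealized=False,
    )
    return generate_dose_response(cfg)


def make_context(sigma=0.05):
    return FitContext(field=FieldConfig(a_if=0.5), beta0=0.011,
                      a_plus_c=0.034, sigma_lns=sigma)


class TestLogLikelihood:
    def test_perfect_fit_leaves_only_normalization(self):
        data = make_data()
        ctx = make_context(sigma=0.05)
        ll = log_likelihood(THETA_TRUE, ctx, data)
        norm = len(data) * (-np.log(0.05) - 0.5 * np.log(2 * np.pi))
        assert ll == pytest.approx(norm, abs=1e-6)

    @pytest.mark.parametrize("index", range(4))
    def test_any_parameter_perturbation_lowers_likelihood(self, index):
        data = make_data()
        ctx = make_context()
        at_truth = log_likelihood(THETA_TRUE, ctx, data)
        for bump in (0.9, 1.1):
            theta = THETA_TRUE.copy()
            theta[index] *= bump
            assert log_likelihood(theta, ctx, data) < at_truth

    def test_duplicated_record_contributes_twice(self):
        data = make_data(doses=(2.0, 4.0))
        one = SurvivalDataset(data.records.iloc[[1]])
        two = SurvivalDataset(pd.concat([one.records, one.records],
                                        ignore_index=True))
        ctx = make_context()
        theta = THETA_TRUE * 1.05
        assert log_likelihood(theta, ctx, two) == pytest.approx(
            2 * log_likelihood(theta, ctx, one), rel=1e-12
        )

    def test_record_order_is_irrelevant(self):
        data = make_data(noise_sd=0.1)
        shuffled = SurvivalDataset(
            data.records.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        ctx = make_context()
        theta = THETA_TRUE * 0.97
        assert log_likelihood(theta, ctx, shuffled) == pytest.approx(
            log_likelihood(theta, ctx, data), rel=1e-12
        )

    def test_records_without_sd_need_global_sigma(self):
        data = make_data(noise_sd=0.0)  # sd column all zero
        ctx = FitContext(field=FieldConfig(a_if=0.5), beta0=0.011)
        with pytest.raises(ValidationError, match="sigma"):
            log_likelihood(THETA_TRUE, ctx, data)


class TestSampler:
    def test_same_seed_gives_identical_chains(self):
        data = make_data(doses=(0.0, 2.0, 4.0, 8.0))
        ctx = make_context()
        priors = PriorSpec.from_guess(GUESS)
        a = run_mcmc(data, ctx, priors, n_draws=800, n_burn=200, seed=5)
        b = run_mcmc(data, ctx, priors, n_draws=800, n_burn=200, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.log_posterior, b.log_posterior)

    def test_draws_respect_nonnegativity(self):
        data = make_data(doses=(0.0, 2.0, 4.0))
        samples = run_mcmc(data, make_context(), PriorSpec.from_guess(GUESS),
                           n_draws=600, n_burn=100, seed=2)
        assert np.all(samples.draws >= 0)
        assert 0 < samples.acceptance_rate <= 1

    def test_prior_only_chain_recovers_truncated_normal_mean(self):
        empty = SurvivalDataset(make_data().records.iloc[0:0])
        priors = PriorSpec(priors={
            "alpha0": NormalPrior(0.5, 0.1),
            "alpha_b": NormalPrior(0.4, 0.2),
            "beta_b": NormalPrior(0.05, 0.05),
            "delta": NormalPrior(0.6, 0.3),
        })
        samples = run_mcmc(empty, make_context(), priors,
                           n_draws=30_000, n_burn=5_000, seed=9)
        for j, name in enumerate(PARAM_NAMES):
            expected = priors.priors[name].truncated_mean
            mc_sd = samples.draws[:, j].std() / 30  # generous ESS guess
            assert samples.draws[:, j].mean() == pytest.approx(
                expected, abs=6 * mc_sd + 0.01
            )

    def test_zero_noise_posterior_concentrates_on_truth(self):
        """Dense noiseless data: posterior sd < 5% of each generating value."""
        data = make_data(doses=tuple(np.arange(0.0, 10.25, 0.25)))
        ctx = make_context(sigma=0.001)
        samples = run_mcmc(data, ctx, PriorSpec.from_guess(GUESS),
                           n_draws=20_000, n_burn=5_000, seed=17)
        for j, name in enumerate(PARAM_NAMES):
            mean = samples.draws[:, j].mean()
            sd = samples.draws[:, j].std(ddof=1)
            assert sd < 0.05 * TRUTH[name]
            assert abs(mean - TRUTH[name]) < 2.5 * sd + 0.01 * TRUTH[name]

    def test_invalid_draw_budget_rejected(self):
        with pytest.raises(ValidationError):
            run_mcmc(make_data(doses=(2.0,)), make_context(),
                     PriorSpec.from_guess(GUESS), n_draws=100, n_burn=100)

    @pytest.mark.parametrize("cell,cond", [
        ("AGO1522", "half_field"), ("AGO1522", "uniform"),
        ("DU145", "half_field"), ("DU145", "uniform"),
    ])
    def test_parameter_recovery_under_default_noise(self, cell, cond):
        """Posterior means within 2 sd of the generating preset values."""
        te = te_params(cell, cond)
        nte = nte_params(cell)
        cfg = GeneratorConfig(
            seed=42, cell_line=cell, a_if=0.5, noise_sd=0.1, n_replicates=3,
            doses=tuple(np.arange(0, 10.5, 0.5)),
            regions=("in_field", "out_of_field", "uniform"),
            te_condition=cond, idealized=False,
        )
        data = generate_dose_response(cfg)
        ctx = FitContext(field=FieldConfig(a_if=0.5), beta0=te.beta0,
                         a_plus_c=te.a_plus_c, sigma_lns=0.1 / np.sqrt(3))
        guess = {"alpha0": max(te.alpha0, 0.05), "alpha_b": max(nte.alpha_b, 0.05),
                 "beta_b": max(nte.beta_b, 0.01), "delta": max(nte.delta, 0.1)}
        samples = run_mcmc(data, ctx, PriorSpec.from_guess(guess),
                           n_draws=12_000, n_burn=3_000, seed=7)
        truth = {"alpha0": te.alpha0, "alpha_b": nte.alpha_b,
                 "beta_b": nte.beta_b, "delta": nte.delta}
        for j, name in enumerate(PARAM_NAMES):
            mean = samples.draws[:, j].mean()
            sd = samples.draws[:, j].std(ddof=1)
            assert abs(mean - truth[name]) <= 2.0 * sd, (
                f"{cell}/{cond} {name}: mean {mean:.4f}, truth {truth[name]}, sd {sd:.4f}"
            )

    def test_cross_check_against_ensemble_sampler(self):
        """Independent affine-invariant sampler agrees on posterior moments."""
        emcee = pytest.importorskip("emcee")
        data = make_data(noise_sd=0.1, seed=3)
        ctx = make_context(sigma=0.1 / np.sqrt(3))
        priors = PriorSpec.from_guess(GUESS)
        mine = run_mcmc(data, ctx, priors, n_draws=15_000, n_burn=5_000, seed=21)

        def logp(theta):
            return log_posterior(theta, ctx, data, priors)

        rng = np.random.default_rng(21)
        nwalkers = 32
        p0 = np.abs(THETA_TRUE * (1 + 0.05 * rng.standard_normal((nwalkers, 4))))
        sampler = emcee.EnsembleSampler(nwalkers, 4, logp)
        state = sampler.run_mcmc(p0, 400, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, 1200, progress=False)
        ref = sampler.get_chain(flat=True)
        for j, name in enumerate(PARAM_NAMES):
            sd = ref[:, j].std()
            assert mine.draws[:, j].mean() == pytest.approx(
                ref[:, j].mean(), abs=0.25 * sd + 0.01
            )


class TestPosteriorSummary:
    def test_degenerate_chain_collapses_band_to_mean_curve(self):
        data = make_data(doses=(0.0, 2.0, 4.0))
        ctx = make_context()
        samples = run_mcmc(data, ctx, PriorSpec.from_guess(GUESS),
                           n_draws=400, n_burn=100, seed=4)
        samples.draws[:] = THETA_TRUE  # force degeneracy
        summary = posterior_summary(samples, data, ctx, np.linspace(0, 8, 9))
        np.testing.assert_allclose(summary.band["lower"], summary.band["mean"],
                                   rtol=1e-12)
        np.testing.assert_allclose(summary.band["upper"], summary.band["mean"],
                                   rtol=1e-12)

    def test_band_ordering_and_coverage_of_mean(self):
        data = make_data(noise_sd=0.1)
        ctx = make_context(sigma=0.1 / np.sqrt(3))
        samples = run_mcmc(data, ctx, PriorSpec.from_guess(GUESS),
                           n_draws=4_000, n_burn=1_000, seed=6)
        summary = posterior_summary(samples, data, ctx, np.linspace(0, 10, 11))
        band = summary.band
        assert (band["lower"] <= band["mean"] + 1e-12).all()
        assert (band["mean"] <= band["upper"] + 1e-12).all()

    def test_band_widens_with_noisier_likelihood(self):
        data = make_data(noise_sd=0.1)
        priors = PriorSpec.from_guess(GUESS)
        widths = {}
        for sigma in (0.05, 0.10):
            ctx = make_context(sigma=sigma)
            samples = run_mcmc(data, ctx, priors, n_draws=6_000, n_burn=2_000,
                               seed=8)
            summary = posterior_summary(samples, data, ctx, np.linspace(0, 10, 11))
            widths[sigma] = float(
                (summary.band["upper"] - summary.band["lower"]).mean()
            )
        assert widths[0.10] > widths[0.05]

    def test_too_few_draws_is_diagnosed(self):
        data = make_data(doses=(0.0, 2.0))
        ctx = make_context()
        samples = run_mcmc(data, ctx, PriorSpec.from_guess(GUESS),
                           n_draws=260, n_burn=200, seed=4)
        with pytest.raises(DiagnosticError, match="100"):
            posterior_summary(samples, data, ctx, [0, 2, 4])

    def test_band_covers_generating_curve(self):
        """The 95.4% band contains the truth at >= 85% of grid points."""
        priors = PriorSpec.from_guess(GUESS)
        doses = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
        grid = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 10.0])
        hits = total = 0
        for seed in range(20):
            data = make_data(seed=seed, noise_sd=0.1, doses=doses)
            ctx = make_context(sigma=0.1 / np.sqrt(3))
            samples = run_mcmc(data, ctx, priors, n_draws=5_000, n_burn=1_500,
                               seed=seed + 100)
            summary = posterior_summary(samples, data, ctx, grid)
            truth_data = make_data(seed=0, noise_sd=0.0, doses=tuple(grid))
            merged = summary.band.merge(
                truth_data.records, on=["region", "dose_Gy"]
            )
            inside = (
                (merged.surviving_fraction >= merged.lower)
                & (merged.surviving_fraction <= merged.upper)
            )
            hits += int(inside.sum())
            total += len(inside)
        assert total > 0
        assert hits / total >= 0.85


class TestGoodnessOfFit:
    def test_perfect_fit_statistics(self):
        obs = np.array([0.5, 0.2, 0.05])
        assert r_squared(obs, obs) == 1.0
        assert chi_squared(obs, obs, np.full(3, 0.1)) == 0.0

    def test_two_point_reference_values(self):
        obs = np.array([0.5, 0.1])
        cal = np.array([0.4, 0.1])
        assert r_squared(obs, cal) == pytest.approx(0.875)
        assert chi_squared(obs, cal, np.array([0.05, 0.02])) == pytest.approx(2.0)

    def test_mean_predictor_scores_zero(self):
        obs = np.array([0.5, 0.1, 0.3])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_constant_observations_rejected(self):
        with pytest.raises(ValidationError):
            r_squared([0.3, 0.3], [0.2, 0.4])

    def test_sd_scaling_homogeneity(self):
        obs = np.array([0.5, 0.1])
        cal = np.array([0.4, 0.12])
        sd = np.array([0.05, 0.02])
        assert chi_squared(obs, cal, 2 * sd) == pytest.approx(
            chi_squared(obs, cal, sd) / 4.0
        )

    def test_zero_sd_points_excluded_with_warning(self):
        obs = np.array([0.5, 0.1])
        cal = np.array([0.4, 0.1])
        with pytest.warns(UserWarning, match="sd = 0"):
            value = chi_squared(obs, cal, np.array([0.05, 0.0]))
        assert value == pytest.approx(4.0)

    def test_all_zero_sd_rejected(self):
        with pytest.raises(ValidationError):
            chi_squared([0.5, 0.1], [0.4, 0.1], [0.0, 0.0])

    def test_chi_squared_near_one_for_correct_model(self):
        """Correctly-specified noisy data gives reduced chi2 in [0.5, 1.7]."""
        for seed in (1, 2, 3):
            data = make_data(seed=seed, noise_sd=0.1, n_replicates=10)
            nonzero = SurvivalDataset(data.records[data.records.dose_Gy > 0])
            truth = nonzero.records.copy()
            cal = [
                float(
                    make_data(seed=0, noise_sd=0.0, doses=(d,)).subset(
                        region=r
                    ).records.surviving_fraction.iloc[0]
                )
                for d, r in zip(truth.dose_Gy, truth.region)
            ]
            assert len(truth) >= 20
            chi2 = chi_squared(truth.surviving_fraction, cal, truth.sd)
            assert 0.5 < chi2 < 1.7, f"seed {seed}: chi2={chi2}"
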