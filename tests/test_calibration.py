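"""Lognormal-error calibration: likelihood, sampler, bands, CSAFs."""

import math

import numpy as np
import pandas as pd
import pytest

from qivive import calibration as cal
from qivive.calibration import (
    credible_band,
    csaf_quantile_ratio,
    gelman_rubin,
    log_likelihood,
    run_mcmc,
)
from qivive.priors import DistributionSpec, PriorSet


class TestLogLikelihood:
    def test_single_observation_closed_form(self):
        # hand computation of one lognormal log-density
        obs, pred, sd = 3.0, 2.0, 0.4
        expected = (
            -0.5 * ((math.log(obs) - math.log(pred)) / sd) ** 2
            - math.log(sd) - math.log(obs) - 0.5 * math.log(2 * math.pi)
        )
        assert log_likelihood([pred], [obs], sd) == pytest.approx(expected)

    def test_perfect_prediction_attains_maximum(self):
        obs = np.array([2.0, 5.0, 9.0])
        sd = 0.3
        at_mode = log_likelihood(obs, obs, sd)
        expected = -np.sum(np.log(obs * sd * math.sqrt(2 * math.pi)))
        assert at_mode == pytest.approx(expected)
        assert log_likelihood(obs * 1.1, obs, sd) < at_mode

    def test_joint_rescaling_changes_only_jacobian(self):
        obs = np.array([2.0, 5.0])
        pred = np.array([2.4, 4.0])
        sd = 0.5
        base = log_likelihood(pred, obs, sd)
        scaled = log_likelihood(10 * pred, 10 * obs, sd)
        assert scaled - base == pytest.approx(-len(obs) * math.log(10.0))

    def test_nonpositive_prediction_is_rejected(self):
        assert log_likelihood([0.0], [1.0], 0.3) == -math.inf
        assert log_likelihood([-2.0], [1.0], 0.3) == -math.inf


class TestGelmanRubin:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(4, 2000))
        assert gelman_rubin(chains) == pytest.approx(1.0, abs=0.02)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 1000)) + np.array([[0.0], [5.0]])
        assert gelman_rubin(chains) > 1.5


def _toy_priors():
    ps = PriorSet()
    ps.add(DistributionSpec("mu", "normal", 5.0, 2.0, 1.0, 9.0))
    return ps


def _toy_data(n=20, truth=4.0, sd=0.2, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "group": "g",
            "exposed_dw_ugL": 1.0,
            "time_h": 0.0,
            "serum_ugL": truth * np.exp(rng.normal(0, sd, n)),
        }
    )


class TestRunMCMC:
    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            run_mcmc(_toy_priors(), _toy_data(), lambda p: np.full(20, p["mu"]), chains=1)

    def test_empty_likelihood_returns_the_prior(self):
        """With no observations the posterior must reproduce the prior."""
        data = _toy_data(0).iloc[:0]
        post = run_mcmc(
            _toy_priors(), data, lambda p: np.array([]),
            iterations=4000, chains=2, seed=2,
        )
        from qivive.priors import quantile_truncated

        spec = _toy_priors()["mu"]
        draws = post.draws["mu"]
        for p in (0.25, 0.5, 0.75):
            assert np.quantile(draws, p) == pytest.approx(
                quantile_truncated(spec, p), abs=0.15
            )

    def test_location_recovery_on_toy_model(self):
        data = _toy_data(n=40, truth=4.0, sd=0.2, seed=3)
        post = run_mcmc(
            _toy_priors(), data, lambda p: np.full(len(data), p["mu"]),
            iterations=2500, chains=2, seed=4,
        )
        assert np.median(post.draws["mu"]) == pytest.approx(4.0, rel=0.1)
        assert np.median(post.draws["error_sd"]) == pytest.approx(0.2, rel=0.4)
        assert post.rhat["mu"] < 1.1

    def test_pbk_recovery_medians_and_convergence(self, calibrated_posterior):
        """Synthetic biomonitoring at known parameters: the identifiable
        clearance parameters come back within 20% with converged chains."""
        truth, _, _, posterior = calibrated_posterior
        for name in ("Free", "GFRC", "KurineC"):
            med = float(np.median(posterior.draws[name]))
            assert med == pytest.approx(getattr(truth.params, name), rel=0.2), name
        assert max(posterior.rhat.values()) < 1.1

    def test_posterior_narrower_than_prior_for_informed_parameters(
        self, calibrated_posterior, pfoa_priors
    ):
        from qivive.priors import quantile_truncated

        _, _, priors, posterior = calibrated_posterior
        # error_sd aside, every calibrated parameter's CI must not exceed
        # its prior CI; informed ones (error scale ~ Free/GFRC) must shrink
        summary = posterior.summary().set_index("parameter")
        shrunk = 0
        for name in priors.names:
            prior_width = quantile_truncated(priors[name], 0.975) - quantile_truncated(
                priors[name], 0.025
            )
            post_width = summary.loc[name, "q97.5"] - summary.loc[name, "q2.5"]
            assert post_width <= prior_width * 1.05, name
            if post_width < prior_width * 0.9:
                shrunk += 1
        assert shrunk >= 1

    def test_correlation_report_shape(self, calibrated_posterior):
        _, _, _, posterior = calibrated_posterior
        pairs = posterior.correlations(threshold=0.3)
        assert set(pairs.columns) == {"param_a", "param_b", "r"}


class TestCredibleBand:
    def test_single_vector_band_collapses_to_mode(self):
        draws = pd.DataFrame(
            {"mu": [4.0], "error_sd": [0.1], "log_post": [0.0], "chain": [0], "iteration": [0]}
        )
        post = cal.PosteriorSample(draws, {}, {}, ["mu"])
        band = credible_band(post, lambda p, t: np.full(len(t), p["mu"]), np.arange(3.0))
        np.testing.assert_allclose(band["lower"], band["mode"])
        np.testing.assert_allclose(band["upper"], band["mode"])

    def test_band_covers_noise_free_truth(self, calibrated_posterior):
        from qivive.pbk import ExposureScenario, steady_state
        from qivive.pipeline import DEFAULT_CONFIG
        from qivive.pbk import PBKParameters

        truth, _, _, posterior = calibrated_posterior

        def predict_curve(params, grid):
            p = PBKParameters.from_draw(params)
            s = ExposureScenario(
                exposed_dw_ugL=1.0, dw_total_Lday=DEFAULT_CONFIG["dw_total_Lday"]
            )
            return np.full(len(grid), float(steady_state(p, s).CA[0]))

        grid = np.linspace(100_000, 120_000, 5)
        band = credible_band(posterior, predict_curve, grid, max_draws=200, seed=1)
        true_curve = predict_curve(
            {f.name: getattr(truth.params, f.name) for f in __import__("dataclasses").fields(truth.params)},
            grid,
        )
        covered = (band["lower"] <= true_curve) & (true_curve <= band["upper"])
        assert covered.mean() >= 0.9

    def test_group_mode_curves_are_ordered(self, calibrated_posterior):
        """Higher drinking-water concentration must give a higher serum
        mode curve, with no crossings."""
        from qivive.pbk import ExposureScenario, PBKParameters, steady_state
        from qivive.pipeline import DEFAULT_CONFIG

        _, _, _, posterior = calibrated_posterior
        grid = np.linspace(100_000, 120_000, 4)
        curves = []
        for conc in (0.04, 1.0, 4.9):
            def predict_curve(params, t, conc=conc):
                p = PBKParameters.from_draw(params)
                s = ExposureScenario(
                    exposed_dw_ugL=conc, dw_total_Lday=DEFAULT_CONFIG["dw_total_Lday"]
                )
                return np.full(len(t), float(steady_state(p, s).CA[0]))

            curves.append(
                credible_band(posterior, predict_curve, grid, max_draws=50, seed=2)["mode"].to_numpy()
            )
        assert (curves[0] < curves[1]).all() and (curves[1] < curves[2]).all()


class TestCSAF:
    def test_constant_sample_gives_unity(self):
        assert csaf_quantile_ratio(np.full(100, 3.3)) == pytest.approx(1.0)

    def test_lognormal_closed_form(self):
        rng = np.random.default_rng(5)
        sigma = 0.25
        x = np.exp(rng.normal(0.0, sigma, 200_000))
        assert csaf_quantile_ratio(x) == pytest.approx(math.exp(1.645 * sigma), rel=0.01)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            csaf_quantile_ratio([1.0, 0.0])

    def test_steady_state_band_ratio_is_modest(self, calibrated_posterior):
        """The posterior steady-state serum spread gives a kinetic CSAF of
        order 1.1-2, not 10 (the rationale for chemical-specific factors)."""
        from qivive.pbk import ExposureScenario, PBKParameters, steady_state
        from qivive.pipeline import DEFAULT_CONFIG

        _, _, _, posterior = calibrated_posterior
        rows = posterior.draws.sample(200, random_state=0)
        preds = []
        for _, row in rows.iterrows():
            p = PBKParameters.from_draw(row.to_dict())
            s = ExposureScenario(
                exposed_dw_ugL=1.0, dw_total_Lday=DEFAULT_CONFIG["dw_total_Lday"]
            )
            preds.append(float(steady_state(p, s).CA[0]))
        ratio = csaf_quantile_ratio(np.array(preds))
        assert 1.0 < ratio < 3.0
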