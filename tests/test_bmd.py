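"""Continuous benchmark-dose modelling: fits, BMD/BMDL, model selection."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from qivive.bmd import (
    DoseResponseDataset,
    apply_adjustment,
    bmd_from_fit,
    bmdl_profile,
    compare_reference,
    fit_all,
    fit_model,
    select_model,
)

DOSES7 = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0])


def hill(x, a=1.0, c=3.0, k=50.0, d=2.0):
    x = np.asarray(x, dtype=float)
    return a * (1.0 + (c - 1.0) * x**d / (k**d + x**d))


class TestDataset:
    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseDataset([0, 1, 2], [1, 1, 1])

    def test_nonpositive_response_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseDataset([0, 1, 2, 3], [1, 1, 0, 1])

    def test_trend_direction(self):
        up = DoseResponseDataset(DOSES7, np.linspace(1, 3, 7))
        down = DoseResponseDataset(DOSES7, np.linspace(3, 1, 7))
        assert up.increasing and not down.increasing


class TestFitModel:
    def test_flat_data_maximised_by_null_model(self):
        data = DoseResponseDataset(DOSES7, np.full(7, 2.0))
        fits = {m: fit_model(data, m) for m in ("exp1", "exp2", "exp3")}
        assert fits["exp1"].loglik == pytest.approx(fits["exp2"].loglik, abs=1e-5)
        assert fits["exp2"].loglik >= fits["exp1"].loglik - 1e-9

    def test_exp2_exact_fit_matches_log_linear_algebra(self):
        a_true, b_true = 1.4, 0.012
        y = a_true * np.exp(b_true * DOSES7[1:5])
        data = DoseResponseDataset(DOSES7[1:5], y)
        fit = fit_model(data, "exp2")
        # closed form: log-linear regression through exact points
        assert fit.theta[0] == pytest.approx(a_true, rel=1e-4)
        assert fit.theta[1] == pytest.approx(b_true, rel=1e-3)
        assert fit.sigma < 1e-5

    def test_nested_exponential_likelihood_is_monotone(self):
        rng = np.random.default_rng(2)
        y = hill(DOSES7) * np.exp(rng.normal(0, 0.05, 7))
        data = DoseResponseDataset(DOSES7, y)
        lls = [fit_model(data, m).loglik for m in ("exp1", "exp2", "exp3", "exp5")]
        assert lls == sorted(lls) or all(
            b >= a - 1e-6 for a, b in zip(lls, lls[1:])
        )

    def test_hill_parameter_recovery_at_five_percent_noise(self):
        """AC50 comes back within 15% from 7 doses x 3 replicates."""
        rng = np.random.default_rng(7)
        doses = np.repeat(DOSES7, 3)
        y = hill(doses, k=50.0) * np.exp(rng.normal(0, 0.05, doses.size))
        order = np.argsort(doses, kind="stable")
        data = DoseResponseDataset(doses[order], y[order])
        fit = fit_model(data, "hill")
        assert fit.theta[1] == pytest.approx(50.0, rel=0.15)

    def test_unknown_model_rejected(self):
        data = DoseResponseDataset(DOSES7, np.ones(7))
        with pytest.raises(ValueError):
            fit_model(data, "probit")


class TestBMD:
    def test_exp2_closed_form(self):
        y = 1.2 * np.exp(0.01 * DOSES7)
        fit = fit_model(DoseResponseDataset(DOSES7, y), "exp2")
        bmd = bmd_from_fit(fit, bmr=0.05)
        assert bmd == pytest.approx(math.log(1.05) / 0.01, rel=1e-3)

    def test_bmd_vanishes_with_the_benchmark_response(self):
        y = 1.2 * np.exp(0.01 * DOSES7)
        fit = fit_model(DoseResponseDataset(DOSES7, y), "exp2")
        bmds = [bmd_from_fit(fit, bmr) for bmr in (0.05, 0.01, 0.001)]
        assert bmds[0] > bmds[1] > bmds[2]
        assert bmds[2] < 0.5

    def test_hill_closed_form_matches_bracketed_root(self):
        y = hill(DOSES7)
        fit = fit_model(DoseResponseDataset(DOSES7, y), "hill")
        bmd = bmd_from_fit(fit, bmr=0.05)
        f0 = fit.predict(np.array([0.0]))[0]
        root = brentq(
            lambda x: fit.predict(np.array([x]))[0] / f0 - 1.05, 1e-9, 300.0,
            xtol=1e-12,
        )
        assert bmd == pytest.approx(root, abs=1e-8)

    def test_null_model_has_no_bmd(self):
        data = DoseResponseDataset(DOSES7, np.full(7, 2.0))
        fit = fit_model(data, "exp1")
        assert bmd_from_fit(fit) is None

    def test_dose_rescaling_rescales_bmd_and_bmdl(self):
        rng = np.random.default_rng(3)
        y = 1.1 * np.exp(0.008 * DOSES7) * np.exp(rng.normal(0, 0.03, 7))
        base = fit_model(DoseResponseDataset(DOSES7, y), "exp2")
        scaled = fit_model(DoseResponseDataset(DOSES7 * 10.0, y), "exp2")
        bmd_b, bmd_s = bmd_from_fit(base), bmd_from_fit(scaled)
        assert bmd_s == pytest.approx(10.0 * bmd_b, rel=1e-4)
        bmdl_b, _ = bmdl_profile(base)
        bmdl_s, _ = bmdl_profile(scaled)
        assert bmdl_s == pytest.approx(10.0 * bmdl_b, rel=1e-3)


class TestBMDL:
    def test_bmdl_below_bmd_below_bmdu(self):
        rng = np.random.default_rng(5)
        y = hill(DOSES7) * np.exp(rng.normal(0, 0.05, 7))
        for model in ("exp2", "exp3", "hill"):
            fit = fit_model(DoseResponseDataset(DOSES7, y), model)
            bmd = bmd_from_fit(fit)
            if bmd is None:
                continue
            fit.bmd = bmd
            bmdl, bmdu = bmdl_profile(fit)
            assert bmdl <= bmd <= bmdu, model

    def test_bmdl_approaches_bmd_as_noise_vanishes(self):
        rng = np.random.default_rng(6)
        widths = []
        for sd in (0.05, 0.005):
            y = 1.2 * np.exp(0.01 * DOSES7) * np.exp(rng.normal(0, sd, 7))
            fit = fit_model(DoseResponseDataset(DOSES7, y), "exp2")
            fit.bmd = bmd_from_fit(fit)
            bmdl, _ = bmdl_profile(fit)
            widths.append((fit.bmd - bmdl) / fit.bmd)
        assert widths[1] < widths[0]
        assert widths[1] < 0.1

    def test_bmdl_coverage_over_replicates(self):
        """BMDL is a one-sided 95% bound: over repeated noisy datasets it
        must fall below the true BMD in >= 90% of replicates."""
        b_true = 0.01
        true_bmd = math.log(1.05) / b_true
        doses = np.repeat(DOSES7, 3)
        order = np.argsort(doses, kind="stable")
        rng = np.random.default_rng(11)
        below = 0
        n_rep = 200
        for _ in range(n_rep):
            y = 1.2 * np.exp(b_true * doses) * np.exp(rng.normal(0, 0.05, doses.size))
            fit = fit_model(DoseResponseDataset(doses[order], y[order]), "exp2")
            fit.bmd = bmd_from_fit(fit)
            bmdl, _ = bmdl_profile(fit)
            below += int(bmdl <= true_bmd)
        assert below / n_rep >= 0.90


class TestSelection:
    def test_single_adequate_model_is_selected(self):
        y = 1.2 * np.exp(0.01 * DOSES7)
        fits = fit_all(DoseResponseDataset(DOSES7, y))
        result = select_model(fits)
        assert result.verdict == "selected"
        assert result.selected_bmdl is not None

    def test_lowest_bmdl_wins_among_adequate(self):
        rng = np.random.default_rng(8)
        y = hill(DOSES7) * np.exp(rng.normal(0, 0.05, 7))
        result = select_model(fit_all(DoseResponseDataset(DOSES7, y)))
        adequate = [f for f in result.fits if f.adequate and f.bmdl is not None]
        assert result.selected_bmdl == min(f.bmdl for f in adequate)

    def test_flat_data_yields_no_dose_response_verdict(self):
        rng = np.random.default_rng(9)
        y = 2.0 * np.exp(rng.normal(0, 0.02, 7))
        result = select_model(fit_all(DoseResponseDataset(DOSES7, y)))
        assert result.verdict == "no dose-response"
        assert result.selected is None

    def test_result_table_shape(self):
        y = 1.2 * np.exp(0.01 * DOSES7)
        result = select_model(fit_all(DoseResponseDataset(DOSES7, y)))
        frame = result.to_frame()
        assert {"model", "loglik", "aic", "bmd", "bmdl", "bmdu"} <= set(frame.columns)
        assert len(frame) == 6


class TestAdjustments:
    def test_csaf_division(self):
        assert apply_adjustment(6.88, 1.4) == pytest.approx(4.91, abs=0.005)

    def test_default_uncertainty_factor(self):
        assert apply_adjustment(6.46, 10.0) == pytest.approx(0.65, abs=0.005)

    def test_identity_factor(self):
        assert apply_adjustment(3.3, 1.0) == 3.3

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            apply_adjustment(1.0, 0.5)

    def test_reference_ratio(self):
        assert compare_reference(6.88 / 1.4, 1.14) == pytest.approx(4.31, abs=0.005)

    def test_fold_difference(self):
        assert compare_reference(0.0855, 5.0, fold=True) == pytest.approx(58.5, abs=0.05)

    def test_equal_inputs_give_unity(self):
        assert compare_reference(2.0, 2.0) == 1.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            compare_reference(1.0, 0.0)
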