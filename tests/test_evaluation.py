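"""Evaluation analytics: metric identities and fitted-model behaviour."""

import numpy as np
import pytest

from glucotwin import (
    SCENARIOS,
    glycemic_metrics,
    peak_si_fractions,
    posthoc_meal_regression,
    prediction_eval,
    replay_variability,
    rmse_posterior_mean,
)


class TestGlycemicMetrics:
    @pytest.mark.parametrize("trace,expected", [
        (np.full(100, 100.0), (100.0, 100.0, 0.0, 0.0)),
        (np.full(100, 60.0), (60.0, 0.0, 100.0, 0.0)),
        (np.r_[np.full(50, 60.0), np.full(50, 200.0)], (130.0, 0.0, 50.0, 50.0)),
    ])
    def test_printed_examples(self, trace, expected):
        g = glycemic_metrics(trace)
        assert (g.mean_bg, g.tir, g.tbr, g.tar) == expected

    def test_partition_sums_to_100_exactly(self):
        rng = np.random.default_rng(0)
        g = glycemic_metrics(rng.uniform(40, 400, size=10_000))
        assert g.tir + g.tbr + g.tar == 100.0

    def test_thresholds_respected(self):
        g = glycemic_metrics(np.full(10, 150.0), lo=160.0, hi=200.0)
        assert g.tbr == 100.0


class TestFittedAnalytics:
    def test_rmse_near_injected_noise_floor(self, scaled_fit):
        """With sigma=10 mg/dL injected noise and a converged fit the cohort
        RMSE sits in [0.5 sigma, 1.5 sigma]."""
        truth, model, fit = scaled_fit
        table = rmse_posterior_mean(fit, model, n_draws=100, seed=3, n_boot=2000)
        cohort = table["rmse"].mean()
        assert 5.0 <= cohort <= 15.0
        assert np.all(table["ci_lo"] <= table["rmse"]) and np.all(table["rmse"] <= table["ci_hi"])

    def test_peak_fractions_sum_to_100(self, scaled_fit):
        truth, model, fit = scaled_fit
        table = peak_si_fractions(fit, model, n_draws=400, seed=1)
        assert np.allclose(table[["B", "L", "D"]].sum(axis=1), 100.0)

    def test_peak_period_closed_form_binning(self, scaled_fit):
        """Phases placed deterministically land in the expected periods."""
        import unittest.mock as mock

        from glucotwin.svi import sample_posterior as sp

        truth, model, fit = scaled_fit
        draws = sp(fit, model, 50, seed=0)
        # the sinusoid peaks at time-of-day (0.25 - phi) mod 1
        for hour, period in ((4.0, "B"), (19.0, "D"), (13.0, "L")):
            phi = 0.25 - hour / 24.0
            for p in range(model.shape.n_patients):
                for s in range(model.shape.n_samples[p]):
                    draws.Z[:, model.sites.index[f"SIphi.p{p}.s{s}"]] = phi
                    draws.Z[:, model.sites.index[f"SIA.p{p}.s{s}"]] = 0.2
            with mock.patch("glucotwin.evaluation.sample_posterior", return_value=draws):
                tab = peak_si_fractions(fit, model, n_draws=50, seed=0)
            assert np.allclose(tab[period], 100.0)

    def test_intraday_resampling_keeps_mean_bg(self, scaled_fit):
        """The sinusoid integrates to zero over a day, so redrawing its
        amplitude/phase shifts mean glucose by only a few mg/dL."""
        truth, model, fit = scaled_fit
        out = replay_variability(fit, model, mode="interday", n=60, seed=2)
        m = out["metrics"]
        assert np.all(np.abs(m["intraday_mean_bg"] - m["cgm_mean_bg"]) < 15.0)
        for col in ("cgm", "intraday", "interday"):
            assert np.allclose(m[f"{col}_tir"] + m[f"{col}_tbr"] + m[f"{col}_tar"], 100.0)

    def test_interday_bands_contain_intraday_bands(self, scaled_fit):
        truth, model, fit = scaled_fit
        out = replay_variability(fit, model, mode="interday", n=60, seed=4)
        widths = [(b["interday_width"], b["intraday_width"]) for b in out["bands"]]
        inter, intra = map(np.array, zip(*widths))
        assert np.median(inter - intra) > 0.0

    def test_prediction_error_grows_with_horizon(self, scaled_fit):
        truth, model, fit = scaled_fit
        t1 = prediction_eval(fit, model, SCENARIOS[1], n_draws=30, seed=0, origin_stride=120.0)
        r30 = t1[t1.horizon_min == 30.0]["rmse"].iloc[0]
        r60 = t1[t1.horizon_min == 60.0]["rmse"].iloc[0]
        assert r60 >= r30

    def test_posthoc_regression_layout_and_invariance(self, scaled_fit):
        truth, model, fit = scaled_fit
        tables = posthoc_meal_regression(fit, model, n_draws=100, seed=0)
        assert set(tables) == {"tauD2", "TD", "MA"}
        for t in tables.values():
            assert list(t["variable"]) == ["Intercept", "Carbs", "Fat", "Protein", "dCGM"]
            assert np.all(t["ci_lo"] <= t["coeff"]) and np.all(t["coeff"] <= t["ci_hi"])

    def test_posthoc_refuses_too_few_meals(self, priors):
        import pandas as pd

        from glucotwin import FitConfig, HierModel, fit_svi
        from tests.test_hierarchy import tiny_sample

        sm = tiny_sample(meals=1)
        model = HierModel([[sm]], priors=priors, dt=5.0)
        fit = fit_svi(model, FitConfig(n_particles=1, n_iterations=2, seed=0))
        with pytest.raises(ValueError, match="10 meals"):
            posthoc_meal_regression(fit, model, n_draws=10, seed=0)
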