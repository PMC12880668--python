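"""Hierarchy structure, prior sampling, the EGP-SI linkage and the joint
density against an independently summed oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glucotwin import HierModel, Sample24h, egp_for_sample, sample_latents
from glucotwin.hierarchy import CohortShape, HierarchySpec, build_sites

EVENT_TAG = {"meal": "m", "bolus": "b", "exercise": "x"}


def tiny_sample(n_cgm=3, meals=1, boluses=1, exercises=0):
    cgm_t = np.arange(n_cgm) * 5.0
    return Sample24h(
        patient_id="t", start=pd.Timestamp("2024-05-01"), cgm_t=cgm_t,
        cgm=np.array([120.0, 131.0, 124.0])[:n_cgm],
        hr_t=np.arange(0.0, 1440.0, 5.0), hr_bpm=np.full(288, 66.0),
        meals=[{"t_report": 400.0 + 200 * j, "carbs": 50.0} for j in range(meals)],
        boluses=[{"t_report": 395.0 + 200 * j, "dose": 5.0} for j in range(boluses)],
        exercises=[{"t_report": 900.0, "duration": 30.0} for _ in range(exercises)],
        basal_rate=24.0 / 1440.0, g0=120.0, day_frac0=0.0, hr_rest=62.0)


class TestStructure:
    def test_sites_exist_exactly_at_declared_levels(self, priors):
        shape = CohortShape(n_samples=[2, 1], n_events=[[(2, 1, 1), (1, 1, 0)], [(2, 2, 0)]])
        sites = build_sites(priors, shape)
        names = set(sites.names)
        for latent in priors.names():
            levels = priors.levels_of(latent)
            assert (f"{latent}.c" in names) == ("cohort" in levels)
            assert (f"{latent}.p0" in names) == ("patient" in levels or levels == ("patient",))
            assert (f"{latent}.p0.s0" in names) == ("sample" in levels)
            for kind, tag in EVENT_TAG.items():
                assert (f"{latent}.p0.s0.{tag}0" in names) == (kind in levels)
        # per-event multiplicity: patient 0 sample 0 has 2 meals
        assert "MA.p0.s0.m1" in names and "MA.p0.s0.m2" not in names
        assert "tauP_long.p0.s0.x0" in names and "tauP_long.p1.s0.x0" not in names

    def test_hierarchy_spec_covers_every_latent_once(self, priors):
        shape = CohortShape(n_samples=[1], n_events=[[(1, 1, 0)]])
        spec = HierarchySpec.from_priors(priors, shape)
        assert sorted(spec.levels) == sorted(priors.names())


class TestSampling:
    def test_draws_respect_all_supports(self, priors):
        shape = CohortShape(n_samples=[2], n_events=[[(2, 1, 1), (1, 1, 0)]])
        draws = sample_latents(priors, shape, seed=0, n_draws=2000)
        sites = draws.sites
        assert np.all(draws.Z >= sites.lo) and np.all(draws.Z <= sites.hi)

    def test_exponential_hyper_mean(self, priors):
        shape = CohortShape(n_samples=[1], n_events=[[(0, 0, 0)]])
        draws = sample_latents(priors, shape, seed=1, n_draws=100_000)
        x = draws.col("sd_EGP.p0")
        assert abs(x.mean() - priors["sd_EGP"].root.scale) / priors["sd_EGP"].root.scale < 0.02

    def test_degenerate_hierarchy_shares_values(self, priors):
        shape = CohortShape(n_samples=[1], n_events=[[(1, 0, 0)]])
        draws = sample_latents(priors, shape, seed=2, n_draws=5)
        # one patient, one sample: patient-level values are drawn once and
        # reused by everything below (structurally: the sample's parent)
        sites = draws.sites
        i = sites.index["SIE.p0.s0"]
        assert sites.parent_idx[i] == sites.index["SIE.p0"]

    def test_seed_reproducibility(self, priors):
        shape = CohortShape(n_samples=[2], n_events=[[(2, 1, 0), (2, 1, 0)]])
        a = sample_latents(priors, shape, seed=7, n_draws=10)
        b = sample_latents(priors, shape, seed=7, n_draws=10)
        assert np.array_equal(a.Z, b.Z)


class TestEgpLinkage:
    def test_degenerate_sd_recovers_linear_mean(self):
        out = egp_for_sample(1.0, 0.8, 0.5, sd_EGP=1e-9, seed=0)
        assert abs(out - (1.0 + 0.8 * 0.5)) < 1e-6

    def test_zero_slope_decorrelates(self):
        rng = np.random.default_rng(0)
        sie = rng.uniform(0.2, 0.8, size=4000)
        egp = egp_for_sample(1.0, 0.0, sie, sd_EGP=0.3, seed=1)
        assert abs(np.corrcoef(sie, egp)[0, 1]) < 0.05

    def test_positive_slope_correlates(self):
        rng = np.random.default_rng(0)
        sie = rng.uniform(0.2, 0.8, size=4000)
        egp = egp_for_sample(1.0, 1.5, sie, sd_EGP=0.3, seed=1)
        assert np.corrcoef(sie, egp)[0, 1] > 0.4

    def test_linkage_visible_across_sampled_days(self, priors):
        shape = CohortShape(n_samples=[200], n_events=[[(0, 0, 0)] * 200])
        draws = sample_latents(priors, shape, seed=3, n_draws=1)
        sie = np.array([draws.value("SIE", 0, s)[0] for s in range(200)])
        egp = np.array([draws.value("EGP", 0, s)[0] for s in range(200)])
        egpm = draws.value("EGPm", 0)[0]
        if egpm > 0.2:
            assert np.corrcoef(sie, egp)[0, 1] > 0.0

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            egp_for_sample(1.0, 1.0, 0.5, sd_EGP=0.0)


class TestLogJoint:
    def test_matches_hand_summed_oracle(self, priors):
        """Prior + likelihood on a 3-point toy window, summed independently
        with scipy.stats, agrees to 1e-10."""
        sm = tiny_sample()
        model = HierModel([[sm]], priors=priors, dt=5.0)
        draws = sample_latents(priors, model.shape, seed=11, n_draws=1)
        Z = draws.Z
        got = model.log_joint(Z)[0]

        sites = model.sites
        lp = 0.0
        for i in range(sites.D):
            x = Z[0, i]
            if sites.loc_kind[i] == 1:
                loc = Z[0, sites.parent_idx[i]]
            elif sites.loc_kind[i] == 2:
                k = int(np.nonzero(sites.egp_sites == i)[0][0])
                t = sites.egp_triples[k]
                loc = Z[0, t[0]] + Z[0, t[1]] * Z[0, t[2]]
            else:
                loc = sites.loc_const[i]
            scale = Z[0, sites.scale_idx[i]] if sites.scale_kind[i] == 1 else sites.scale_const[i]
            if sites.family[i] == 1:
                lp += stats.uniform(sites.lo[i], sites.hi[i] - sites.lo[i]).logpdf(x)
            elif sites.family[i] == 2:
                lp += stats.expon(scale=scale).logpdf(x)
            else:
                a = (sites.lo[i] - loc) / scale
                b = (sites.hi[i] - loc) / scale
                lp += stats.truncnorm(a, b, loc=loc, scale=scale).logpdf(x)

        from glucotwin import simulate_sample

        params, events = model.assemble_sample_params(draws, 0, 0)
        tb = simulate_sample(params, events, sm.hr_t, sm.hr_bpm,
                             t_grid=np.arange(0.0, 1442.5, 5.0))
        sg = tb.sg_at(sm.cgm_t)
        lp += stats.norm(sg, params.sigma).logpdf(sm.cgm).sum()
        assert abs(got - lp) < 1e-10

    def test_single_point_at_mode(self, priors):
        """A CGM point equal to simulated SG contributes -log(sigma sqrt(2 pi))."""
        sm = tiny_sample(n_cgm=1)
        model = HierModel([[sm]], priors=priors, dt=5.0)
        draws = sample_latents(priors, model.shape, seed=4, n_draws=1)
        sm.cgm[0] = sm.g0  # SG at t=0 equals g0 by construction
        sigma = float(np.exp(draws.col("log_sigma.p0.s0")[0]))
        ll = model.log_lik(draws.Z)[0]
        assert abs(ll - (-np.log(sigma * np.sqrt(2 * np.pi)))) < 1e-12

    def test_sigma_doubling_identity(self, priors):
        sm = tiny_sample()
        model = HierModel([[sm]], priors=priors, dt=5.0)
        draws = sample_latents(priors, model.shape, seed=5, n_draws=1)
        i = model.sites.index["log_sigma.p0.s0"]
        ll1 = model.log_lik(draws.Z)[0]
        sigma1 = np.exp(draws.Z[0, i])
        # residuals from the first evaluation
        r2 = 2.0 * (-(ll1) - sm.cgm_t.size * np.log(sigma1 * np.sqrt(2 * np.pi))) * sigma1 ** 2
        Z2 = draws.Z.copy()
        Z2[0, i] += np.log(2.0)
        ll2 = model.log_lik(Z2)[0]
        want = -0.5 * r2 / (2 * sigma1) ** 2 - sm.cgm_t.size * np.log(2 * sigma1 * np.sqrt(2 * np.pi))
        assert abs(ll2 - want) < 1e-9

    def test_out_of_support_is_minus_inf_not_exception(self, priors):
        sm = tiny_sample()
        model = HierModel([[sm]], priors=priors, dt=5.0)
        draws = sample_latents(priors, model.shape, seed=6, n_draws=1)
        Z = draws.Z.copy()
        Z[0, model.sites.index["VG.p0"]] = -10.0
        assert model.log_joint(Z)[0] == -np.inf


class TestAssembly:
    def test_two_samples_share_patient_level_but_not_sample_level(self, priors):
        sms = [tiny_sample(), tiny_sample()]
        model = HierModel([sms], priors=priors, dt=5.0)
        draws = sample_latents(priors, model.shape, seed=8, n_draws=1)
        p0, _ = model.assemble_sample_params(draws, 0, 0)
        p1, _ = model.assemble_sample_params(draws, 0, 1)
        assert p0.VG == p1.VG and p0.tauI2 == p1.tauI2
        assert p0.SIE != p1.SIE and p0.EGP != p1.EGP

    def test_event_level_ma_differs_between_meals(self, priors):
        sm = tiny_sample(meals=2)
        model = HierModel([[sm]], priors=priors, dt=5.0)
        draws = sample_latents(priors, model.shape, seed=9, n_draws=1)
        _, events = model.assemble_sample_params(draws, 0, 0)
        assert events.meals[0].MA != events.meals[1].MA
        assert events.meals[0].tauD1 == events.meals[1].tauD1  # patient level

    def test_assemble_scatter_round_trip(self, priors):
        sm = tiny_sample(meals=2, boluses=1, exercises=1)
        model = HierModel([[sm]], priors=priors, dt=5.0)
        draws = sample_latents(priors, model.shape, seed=10, n_draws=1)
        params, events = model.assemble_sample_params(draws, 0, 0)
        other = sample_latents(priors, model.shape, seed=99, n_draws=1)
        model.scatter_sample_params(other, 0, 0, params, events)
        params2, events2 = model.assemble_sample_params(other, 0, 0)
        for field in ("VG", "GEZI", "EGP", "SIE", "SIA", "tauG", "tauI2", "tauI3",
                      "tauI4", "tauE", "SE", "H", "Gth", "sigma"):
            assert np.isclose(getattr(params2, field), getattr(params, field))
        assert [m.MA for m in events2.meals] == [m.MA for m in events.meals]
        assert [b.tauI1 for b in events2.boluses] == [b.tauI1 for b in events.boluses]
        assert [e.P_long for e in events2.exercises] == [e.P_long for e in events.exercises]

    def test_index_out_of_range(self, priors):
        sm = tiny_sample()
        model = HierModel([[sm]], priors=priors, dt=5.0)
        draws = sample_latents(priors, model.shape, seed=0, n_draws=1)
        with pytest.raises(IndexError):
            model.assemble_sample_params(draws, 1, 0)
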