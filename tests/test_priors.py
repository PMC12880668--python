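"""Prior families, the default table, and config round-trips."""

import math

import numpy as np
import pytest
from scipy import stats

from glucotwin import PriorSpec, PriorTable, build_priors


class TestPriorSpec:
    @pytest.mark.parametrize("spec,dist", [
        (PriorSpec("truncated_normal", loc=1.0, scale=0.5, lower=0.0, upper=2.0),
         stats.truncnorm(-2.0, 2.0, loc=1.0, scale=0.5)),
        (PriorSpec("half_normal", scale=2.0), stats.halfnorm(scale=2.0)),
        (PriorSpec("exponential", scale=3.0), stats.expon(scale=3.0)),
        (PriorSpec("uniform", lower=1.0, upper=4.0), stats.uniform(1.0, 3.0)),
        (PriorSpec("log_normal", loc=1.0, scale=0.5), stats.lognorm(0.5, scale=math.e)),
    ])
    def test_logpdf_and_median_match_scipy(self, spec, dist):
        x = np.linspace(dist.ppf(0.01), dist.ppf(0.99), 25)
        assert np.abs(spec.logpdf(x) - dist.logpdf(x)).max() < 1e-9
        assert abs(spec.median() - dist.median()) < 1e-9

    def test_sampling_respects_support_and_mean(self):
        rng = np.random.default_rng(0)
        spec = PriorSpec("exponential", scale=2.5)
        x = spec.sample(rng, size=100_000)
        assert np.all(x >= 0)
        assert abs(x.mean() - 2.5) / 2.5 < 0.02

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec("beta")


class TestDefaultTable:
    def test_published_constraints_present(self, priors):
        assert priors["tauD1"].hi == 10.0
        assert (priors["SIA"].lo, priors["SIA"].hi) == (0.0, 0.5)
        assert priors["MA"].root.scale == 0.2
        assert (priors["tauG"].lo, priors["tauG"].hi) == (5.0, 30.0)
        assert priors["GEZI"].lo == 1e-3
        assert (priors["tauP_short"].lo, priors["tauP_short"].hi) == (5.0, 120.0)
        assert priors["SIphi"].root.family == "uniform"

    def test_every_level_set_is_wellformed(self, priors):
        allowed = {"cohort", "patient", "sample", "meal", "bolus", "exercise"}
        for name in priors.names():
            levels = priors.levels_of(name)
            assert len(levels) >= 1
            assert set(levels) <= allowed

    def test_sd_hyper_references_resolve(self, priors):
        for name in priors.names():
            for v in priors[name].sds.values():
                if isinstance(v, str):
                    assert v in priors


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, priors, tmp_path):
        path = tmp_path / "priors.yaml"
        priors.to_yaml(path)
        back = PriorTable.from_yaml(path)
        assert back.names() == priors.names()
        for name in priors.names():
            assert back[name].root.to_dict() == priors[name].root.to_dict()
            assert back[name].levels == priors[name].levels

    def test_overrides_applied(self):
        table = build_priors({"SIE": {"root": {"loc": 0.6}, "sds": {"sample": 0.05}}})
        assert table["SIE"].root.loc == 0.6
        assert table["SIE"].sds["sample"] == 0.05
        assert table["SIE"].sds["patient"] == build_priors()["SIE"].sds["patient"]

    def test_unknown_latent_rejected(self):
        with pytest.raises(KeyError):
            build_priors({"nope": {}})
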