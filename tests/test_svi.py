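"""The SVI engine: guide algebra, ELBO, conjugate recovery, checkpoints."""

import numpy as np
import pytest

from glucotwin import FitConfig, GuideState, elbo_estimate, fit_svi, sample_posterior
from glucotwin.svi import load_checkpoint


class ToyNormal:
    """Normal prior N(mu0, tau^2), data y ~ N(theta, s^2): closed-form posterior."""

    def __init__(self, y, mu0=0.0, tau=2.0, s=1.0):
        self.y = np.asarray(y, dtype=float)
        self.mu0, self.tau, self.s = mu0, tau, s
        self.D = 1

    def log_joint(self, Z):
        Z = np.atleast_2d(Z)
        th = Z[:, 0]
        lp = -0.5 * ((th - self.mu0) / self.tau) ** 2
        ll = -0.5 * ((self.y[None, :] - th[:, None]) / self.s) ** 2
        return lp + ll.sum(axis=1)

    def posterior(self):
        prec = 1 / self.tau ** 2 + self.y.size / self.s ** 2
        var = 1 / prec
        mean = var * (self.mu0 / self.tau ** 2 + self.y.sum() / self.s ** 2)
        return mean, np.sqrt(var)


class StandardNormal:
    def __init__(self, D=2):
        self.D = D

    def log_joint(self, Z):
        Z = np.atleast_2d(Z)
        return -0.5 * (Z ** 2).sum(axis=1) - 0.5 * self.D * np.log(2 * np.pi)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(5)
    return ToyNormal(rng.normal(1.5, 1.0, size=20))


class TestGuide:
    def test_covariance_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        D, r = 6, 2
        guide = GuideState(loc=rng.normal(size=D), log_diag=rng.normal(scale=0.3, size=D),
                           cov_factor=0.5 * rng.normal(size=(D, r)))
        z = guide.sample(np.random.default_rng(1), 100_000)
        emp = np.cov(z.T)
        want = guide.covariance()
        assert np.linalg.norm(emp - want) / np.linalg.norm(want) < 0.03

    def test_log_prob_matches_dense_gaussian(self):
        rng = np.random.default_rng(2)
        D, r = 5, 2
        guide = GuideState(loc=rng.normal(size=D), log_diag=rng.normal(scale=0.2, size=D),
                           cov_factor=0.4 * rng.normal(size=(D, r)))
        from scipy.stats import multivariate_normal

        z = guide.sample(rng, 50)
        want = multivariate_normal(guide.loc, guide.covariance()).logpdf(z)
        assert np.abs(guide.log_prob(z) - want).max() < 1e-9

    def test_entropy_matches_dense_formula(self):
        rng = np.random.default_rng(3)
        D, r = 4, 1
        guide = GuideState(loc=np.zeros(D), log_diag=rng.normal(scale=0.2, size=D),
                           cov_factor=0.3 * rng.normal(size=(D, r)))
        sign, logdet = np.linalg.slogdet(guide.covariance())
        want = 0.5 * (logdet + D * (1 + np.log(2 * np.pi)))
        assert abs(guide.entropy() - want) < 1e-10


class TestElbo:
    def test_zero_kl_gives_zero_elbo(self):
        guide = GuideState(loc=np.zeros(2), log_diag=np.zeros(2), cov_factor=np.zeros((2, 0)))
        val = elbo_estimate(guide, StandardNormal(2), n_particles=4000, seed=1)
        assert abs(val) < 0.01

    def test_shifted_guide_elbo_deficit_is_half_delta_squared(self):
        delta = 0.7
        guide = GuideState(loc=np.array([delta]), log_diag=np.zeros(1),
                           cov_factor=np.zeros((1, 0)))
        val = elbo_estimate(guide, StandardNormal(1), n_particles=60_000, seed=2)
        assert abs(val - (-0.5 * delta ** 2)) < 0.01

    def test_seed_reproducible(self, toy):
        guide = GuideState(loc=np.zeros(1), log_diag=np.zeros(1), cov_factor=np.zeros((1, 0)))
        assert elbo_estimate(guide, toy, 50, seed=3) == elbo_estimate(guide, toy, 50, seed=3)


class TestFit:
    def test_conjugate_recovery_within_two_percent(self, toy):
        fit = fit_svi(toy, FitConfig(n_particles=4, n_iterations=3000, rank=0, seed=0,
                                     lr=0.02, lr_min=0.002))
        mean, sd = toy.posterior()
        assert abs(fit.guide.loc[0] - mean) / abs(mean) < 0.02
        assert abs(fit.guide.diag_scale[0] - sd) / sd < 0.02
        assert fit.elbo_trace.size == 3000

    def test_rank_zero_equals_mean_field(self, toy):
        cfg = dict(n_particles=3, n_iterations=300, seed=4, lr=0.02, lr_min=0.002)
        f0 = fit_svi(toy, FitConfig(rank=0, **cfg))
        # a rank-1 guide whose factor stays exactly zero gives the same path
        # only if the factor receives zero gradient; instead check the
        # degenerate factor has no effect on the density
        g = GuideState(loc=f0.guide.loc, log_diag=f0.guide.log_diag,
                       cov_factor=np.zeros((1, 3)))
        z = np.array([[0.3], [1.9]])
        assert np.allclose(g.log_prob(z), f0.guide.log_prob(z))
        assert abs(g.entropy() - f0.guide.entropy()) < 1e-12

    def test_smoothed_elbo_nondecreasing_late_in_training(self, toy):
        fit = fit_svi(toy, FitConfig(n_particles=4, n_iterations=2000, rank=0, seed=6,
                                     lr=0.02, lr_min=0.002))
        k = 200
        sm = np.convolve(fit.elbo_trace, np.ones(k) / k, mode="valid")
        half = sm[sm.size // 2:]
        # monotone up to small stochastic wiggle
        assert half[-1] >= half[0] - 1.0
        assert np.min(half[-200:]) >= half.max() - 2.0

    def test_checkpoint_resume(self, toy, tmp_path):
        path = str(tmp_path / "ck.npz")
        cfg = FitConfig(n_particles=3, n_iterations=200, seed=7, rank=1,
                        checkpoint_path=path, checkpoint_every=100)
        fit = fit_svi(toy, cfg)
        loaded = load_checkpoint(path, cfg)
        assert np.array_equal(loaded.guide.loc, fit.guide.loc)
        resumed = fit_svi(toy, FitConfig(n_particles=3, n_iterations=100, seed=8, rank=1),
                          resume=loaded)
        assert resumed.elbo_trace.size == 300


class TestPosteriorDraws:
    def test_empty_draws(self, toy):
        fit = fit_svi(toy, FitConfig(n_particles=2, n_iterations=50, rank=0, seed=9))
        z = fit.guide.sample(np.random.default_rng(0), 0)
        assert z.shape == (0, 1)

    def test_draws_respect_support_and_reproduce(self, scaled_fit):
        truth, model, fit = scaled_fit
        a = sample_posterior(fit, model, 64, seed=5)
        b = sample_posterior(fit, model, 64, seed=5)
        assert np.array_equal(a.Z, b.Z)
        assert np.all(a.Z >= model.sites.lo) and np.all(a.Z <= model.sites.hi)
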