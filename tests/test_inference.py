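"""Posterior machinery: HDI, split-PSRF, ESS and the adaptive sampler."""

import numpy as np
import pytest
from scipy import stats

from acwr_bayes.inference import (
    ConvergenceError,
    InitializationError,
    LogDensityModel,
    check_convergence,
    ess,
    hdi,
    psrf,
    sample_posterior,
)


class TestHDI:
    def test_standard_normal_matches_central_interval(self, rng):
        draws = rng.standard_normal(1_000_000)
        lo, hi = hdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_uniform_width(self, rng):
        lo, hi = hdi(rng.uniform(0, 1, 100_000), 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_constant_draws_degenerate(self):
        lo, hi = hdi(np.full(500, 3.25))
        assert (lo, hi) == (3.25, 3.25)

    def test_monotone_in_mass(self, rng):
        draws = rng.gamma(2.0, 1.0, 50_000)
        lo95, hi95 = hdi(draws, 0.95)
        lo99, hi99 = hdi(draws, 0.99)
        assert lo99 <= lo95 and hi99 >= hi95

    def test_skewed_hdi_narrower_than_central(self, rng):
        draws = rng.exponential(1.0, 200_000)
        lo, hi = hdi(draws, 0.95)
        central = np.percentile(draws, [2.5, 97.5])
        assert hi - lo < central[1] - central[0]
        assert lo == pytest.approx(0.0, abs=0.01)

    @pytest.mark.parametrize("mass", [0.0, 1.0, 1.2])
    def test_invalid_mass(self, mass, rng):
        with pytest.raises(ValueError):
            hdi(rng.standard_normal(1000), mass)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hdi(np.arange(50))


class TestPSRF:
    def test_iid_chains_near_one(self, rng):
        chains = rng.standard_normal((4, 10_000))
        assert psrf(chains) == pytest.approx(1.0, abs=0.01)

    def test_disjoint_chains_large(self, rng):
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert psrf(chains) > 1.1

    def test_duplicated_chain_near_one(self, rng):
        c = rng.standard_normal(1000)
        assert psrf(np.stack([c, c])) == pytest.approx(1.0, abs=0.01)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            psrf(rng.standard_normal((1, 1000)))

    def test_matches_arviz_rhat(self, rng):
        az = pytest.importorskip("arviz")
        # mildly autocorrelated chains
        chains = np.cumsum(rng.standard_normal((4, 5000)), axis=1) * 0.02 + rng.standard_normal(
            (4, 5000)
        )
        assert psrf(chains) == pytest.approx(float(az.rhat(chains)), abs=0.05)


class TestESS:
    def test_iid_near_n(self, rng):
        x = rng.standard_normal(20_000)
        assert ess(x) == pytest.approx(20_000, rel=0.10)

    @pytest.mark.parametrize("phi", [0.5, 0.8])
    def test_ar1_closed_form(self, phi, rng):
        n = 200_000
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        expected = n * (1 - phi) / (1 + phi)
        assert ess(x) == pytest.approx(expected, rel=0.15)

    def test_multichain_sums(self, rng):
        chains = rng.standard_normal((4, 5000))
        assert ess(chains) == pytest.approx(4 * 5000, rel=0.10)

    def test_constant_chain_undefined(self):
        with pytest.raises(ValueError):
            ess(np.ones(1000))

    def test_same_order_as_arviz(self, rng):
        az = pytest.importorskip("arviz")
        phi = 0.7
        eps = rng.standard_normal((4, 20_000))
        x = np.empty_like(eps)
        x[:, 0] = eps[:, 0]
        for i in range(1, x.shape[1]):
            x[:, i] = phi * x[:, i - 1] + eps[:, i]
        assert ess(x) == pytest.approx(float(az.ess(x)), rel=0.25)


def _beta_binomial_model(a, b, k, n):
    def logden(theta):
        x = theta[:, 0]
        p = 1.0 / (1.0 + np.exp(-x))
        return (k + a) * np.log(p) + (n - k + b) * np.log1p(-p)

    return LogDensityModel(
        names=("logit_p",),
        log_density=logden,
        initial=lambda rng, m: rng.normal(0, 1, (m, 1)),
        transform=lambda t: {"p": 1.0 / (1.0 + np.exp(-t[..., 0]))},
    )


class TestSamplePosterior:
    def test_beta_binomial_conjugate(self):
        a, b, k, n = 2.0, 3.0, 7, 20
        samples = sample_posterior(_beta_binomial_model(a, b, k, n), seed=1, check=True)
        p = samples.pooled("p")
        closed_form = (a + k) / (a + b + n)
        mcse = p.std() / np.sqrt(ess(samples.draws["p"]))
        assert abs(p.mean() - closed_form) < 3 * mcse

    def test_normal_known_sigma_conjugate(self, rng):
        sigma, tau0, m0 = 2.0, 5.0, 1.0
        y = rng.normal(3.0, sigma, 50)
        prec = 1 / tau0**2 + y.size / sigma**2
        post_mean = (m0 / tau0**2 + y.sum() / sigma**2) / prec
        post_sd = np.sqrt(1 / prec)

        def logden(theta):
            mu = theta[:, 0]
            ll = -0.5 * ((y[None, :] - mu[:, None]) ** 2).sum(axis=1) / sigma**2
            return ll - 0.5 * (mu - m0) ** 2 / tau0**2

        model = LogDensityModel(("mu",), logden, lambda r, m: r.normal(0, 1, (m, 1)))
        samples = sample_posterior(model, seed=2, check=True)
        mu = samples.pooled("mu")
        mcse = mu.std() / np.sqrt(ess(samples.draws["mu"]))
        assert abs(mu.mean() - post_mean) < 3 * mcse
        assert mu.std() == pytest.approx(post_sd, rel=0.05)

    def test_zero_data_recovers_prior(self):
        # no likelihood term: posterior == prior N(2, 3^2)
        def logden(theta):
            return -0.5 * (theta[:, 0] - 2.0) ** 2 / 9.0

        model = LogDensityModel(("x",), logden, lambda r, m: r.normal(0, 1, (m, 1)))
        samples = sample_posterior(model, seed=3, check=True)
        x = samples.pooled("x")
        qs = np.percentile(x, [5, 25, 50, 75, 95])
        expected = stats.norm(2, 3).ppf([0.05, 0.25, 0.5, 0.75, 0.95])
        # tail quantiles of an MCMC stream carry larger Monte-Carlo error
        assert np.allclose(qs, expected, atol=0.3)
        assert x.mean() == pytest.approx(2.0, abs=0.15)
        assert x.std() == pytest.approx(3.0, rel=0.05)

    def test_deterministic_given_seed(self):
        model = _beta_binomial_model(1, 1, 5, 10)
        a = sample_posterior(model, n_iterations=500, warmup=300, seed=5)
        b = sample_posterior(model, n_iterations=500, warmup=300, seed=5)
        assert np.array_equal(a.draws["p"], b.draws["p"])

    def test_nonfinite_initialization_fails(self):
        model = LogDensityModel(
            ("x",),
            lambda t: np.full(t.shape[0], -np.inf),
            lambda r, m: r.normal(0, 1, (m, 1)),
        )
        with pytest.raises(InitializationError):
            sample_posterior(model, seed=1)

    def test_check_convergence_raises_with_partial_results(self, rng):
        # two stationary chains centered 10 apart can never satisfy PSRF
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        from acwr_bayes.inference import PosteriorSamples

        samples = PosteriorSamples(draws={"x": chains})
        with pytest.raises(ConvergenceError) as err:
            check_convergence(samples)
        assert err.value.samples is samples
        assert "x" in err.value.summary.index
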