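"""Likelihood oracles, GP covariance, priors and sampler correctness."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from invade.models import (ModelData, ModelSpec, build_model_data,
                           gp_covariance, log_posterior, nb_loglik,
                           night_loglik, occupancy_loglik, sample_posterior,
                           standardize_covariates)
from invade.models import _ModelCore
from invade.sampler import ess, hmc_sample, split_rhat


# --- standardization ---------------------------------------------------------

def test_standardize_basic_and_idempotent():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "lunar": [0.1, 0.5, 0.9]})
    out, scaling = standardize_covariates(df, exclude=["lunar"])
    np.testing.assert_allclose(out["a"], [-1.0, 0.0, 1.0])
    assert scaling["a"] == (2.0, 1.0)
    assert "lunar" not in scaling
    np.testing.assert_allclose(out["lunar"], df["lunar"])  # untouched
    out2, _ = standardize_covariates(out, exclude=["lunar"])
    np.testing.assert_allclose(out2["a"], out["a"], atol=1e-12)


def test_standardize_zero_variance_named():
    df = pd.DataFrame({"flat": [3.0, 3.0, 3.0]})
    with pytest.raises(ValueError, match="flat"):
        standardize_covariates(df)


# --- GP covariance -----------------------------------------------------------

def test_gp_covariance_structure():
    coords = np.array([[0.0, 0.0], [0.0, 1000.0], [10000.0, 0.0]])
    K = gp_covariance(coords, eta=0.7, rho=1000.0, jitter=1e-6)
    assert K[0, 0] == pytest.approx(0.49 + 1e-6)
    np.testing.assert_allclose(K, K.T)
    np.linalg.cholesky(K)  # must be positive definite
    # ratio d/rho = 10 -> correlation factor < 1e-21
    assert K[0, 2] < 0.49 * 1e-21


def test_gp_covariance_eta_zero_is_jitter_identity():
    coords = np.random.default_rng(0).uniform(0, 100, (5, 2))
    K = gp_covariance(coords, eta=0.0, rho=50.0, jitter=1e-4)
    np.testing.assert_allclose(K, 1e-4 * np.eye(5), atol=1e-15)


def test_gp_covariance_rejects_bad_input():
    with pytest.raises(ValueError):
        gp_covariance(np.array([[np.nan, 0.0]]), 1.0, 1.0)
    with pytest.raises(ValueError):
        gp_covariance(np.zeros((2, 2)), 1.0, -1.0)


# --- occupancy likelihood ----------------------------------------------------

def test_occupancy_single_day_closed_forms():
    psi, p = np.array([0.3]), np.array([[0.7]])
    assert occupancy_loglik(np.array([[1.0]]), psi, p) == pytest.approx(
        math.log(0.3 * 0.7), abs=1e-12
    )
    assert occupancy_loglik(np.array([[0.0]]), psi, p) == pytest.approx(
        math.log(0.3 * 0.3 + 0.7), abs=1e-12
    )


def _occupancy_enumeration_oracle(y, psi, p):
    """Sum over every latent occupancy configuration z in {0,1}^sites."""
    n_sites = len(psi)
    total = 0.0
    for z in itertools.product([0, 1], repeat=n_sites):
        prob = 1.0
        for i in range(n_sites):
            prob *= psi[i] if z[i] else 1 - psi[i]
            for j in range(y.shape[1]):
                if np.isnan(y[i, j]):
                    continue
                pij = p[i, j] * z[i]
                prob *= pij if y[i, j] == 1 else 1 - pij
        total += prob
    return math.log(total)


def test_occupancy_matches_latent_enumeration():
    rng = np.random.default_rng(5)
    for _ in range(10):
        n_sites, n_days = rng.integers(1, 4), rng.integers(1, 5)
        psi = rng.uniform(0.05, 0.95, n_sites)
        p = rng.uniform(0.05, 0.95, (n_sites, n_days))
        z = rng.random(n_sites) < psi
        y = ((rng.random((n_sites, n_days)) < p) & z[:, None]).astype(float)
        y[rng.random(y.shape) < 0.2] = np.nan
        got = occupancy_loglik(y, psi, p)
        want = _occupancy_enumeration_oracle(y, psi, p)
        assert got == pytest.approx(want, abs=1e-10)


def test_occupancy_with_perfect_detection_collapses_to_bernoulli():
    # p -> 1: the marginal likelihood becomes plain Bernoulli(z = any
    # detection | psi) logistic-regression likelihood
    rng = np.random.default_rng(6)
    psi = rng.uniform(0.2, 0.8, 6)
    y = (rng.random((6, 4)) < 0.4).astype(float)
    p = np.full((6, 4), 1 - 1e-12)
    z = y.max(axis=1)
    want = float(np.sum(z * np.log(psi) + (1 - z) * np.log1p(-psi)))
    # detected sites: log psi + log p... ~ log psi; undetected: need y all 0
    y0 = np.where(y.max(axis=1)[:, None] > 0, y, 0.0)
    got = occupancy_loglik(y0, psi, p)
    # days with y=0 at occupied sites contribute log(1-p) ~ -inf unless no
    # detection days conflict; use all-or-nothing histories instead
    y_all = np.tile(z[:, None], (1, 1))
    got = occupancy_loglik(y_all, psi, np.full((6, 1), 1 - 1e-12))
    assert got == pytest.approx(want, abs=1e-6)


def test_occupancy_rejects_invalid_probs():
    with pytest.raises(ValueError):
        occupancy_loglik(np.array([[1.0]]), np.array([1.0]), np.array([[0.5]]))


# --- negative binomial -------------------------------------------------------

def test_nb_matches_poisson_limit():
    counts = np.arange(0, 15, dtype=float).reshape(3, 5)
    mu = 2.7
    got = nb_loglik(counts, mu, 1e8)
    want = float(stats.poisson.logpmf(counts, mu).sum())
    assert got == pytest.approx(want, abs=1e-4)


def test_nb_closed_form_zero_count():
    # NB(0 | mu=1, phi=1) = (phi/(phi+mu))^phi = 1/2
    assert nb_loglik(np.array([0.0]), 1.0, 1.0) == pytest.approx(math.log(0.5), abs=1e-12)


def test_nb_pmf_normalizes():
    mu, phi = 3.0, 0.5
    n = np.arange(0, 10_000, dtype=float)
    total = np.exp([nb_loglik(np.array([k]), mu, phi) for k in n]).sum()
    assert total == pytest.approx(1.0, abs=1e-8)


def test_nb_matches_scipy_parameterization():
    # scipy nbinom with n=phi, p=phi/(phi+mu) is the same NB2 density
    counts = np.array([0.0, 1.0, 4.0, 9.0])
    mu, phi = 2.2, 1.7
    want = float(stats.nbinom.logpmf(counts, phi, phi / (phi + mu)).sum())
    assert nb_loglik(counts, mu, phi) == pytest.approx(want, abs=1e-10)


def test_nb_rejects_bad_input():
    with pytest.raises(ValueError):
        nb_loglik(np.array([1.5]), 1.0, 1.0)
    with pytest.raises(ValueError):
        nb_loglik(np.array([1.0]), 1.0, -1.0)


# --- night binomial ----------------------------------------------------------

def test_night_zero_trials_contribute_zero():
    k = np.array([[0.0, 2.0]])
    n = np.array([[0.0, 5.0]])
    only_second = night_loglik(np.array([[2.0]]), np.array([[5.0]]), np.array([[0.0]]))
    assert night_loglik(k, n, np.zeros((1, 2))) == pytest.approx(only_second)


def test_night_closed_form():
    # k=2 of n=5 at predictor 0: C(5,2) (1/2)^5 = 10/32
    got = night_loglik(np.array([2.0]), np.array([5.0]), np.array([0.0]))
    assert got == pytest.approx(math.log(10 / 32), abs=1e-12)


def test_night_rejects_k_above_n():
    with pytest.raises(ValueError):
        night_loglik(np.array([6.0]), np.array([5.0]), np.array([0.0]))


# --- full posterior ----------------------------------------------------------

def _toy_data(rng, n=8, days=5):
    data = ModelData(
        X=rng.standard_normal((n, 2)),
        season=rng.integers(0, 2, n),
        coords=rng.uniform(0, 5000, (n, 2)),
        camera=rng.integers(0, 2, n),
        y=(rng.random((n, days)) < 0.4).astype(float),
        counts=rng.poisson(2.0, (n, days)).astype(float),
        night_counts=None,
        temp=rng.standard_normal((n, days)),
        lunar=rng.random((n, days)),
    )
    data.night_counts = np.floor(data.counts * rng.random((n, days)))
    return data


@pytest.mark.parametrize("response", ["occupancy", "count", "night"])
def test_gradients_match_finite_differences(response):
    rng = np.random.default_rng(3)
    data = _toy_data(rng)
    spec = ModelSpec(response=response, exposure="x0", covariates=("x1",), gp=True)
    core = _ModelCore(spec, data)
    th = 0.3 * rng.standard_normal(core.dim)
    aux = np.array([0.6, 2000.0])
    _, g = core.logp_grad(th, aux)
    eps = 1e-6
    for i in range(core.dim):
        tp, tm = th.copy(), th.copy()
        tp[i] += eps
        tm[i] -= eps
        num = (core.logp_grad(tp, aux)[0] - core.logp_grad(tm, aux)[0]) / (2 * eps)
        assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-5)


def test_log_posterior_with_no_data_equals_prior_density():
    # empty observation matrices: the posterior reduces to the prior, which
    # we evaluate independently with scipy densities (up to the half-normal
    # aux terms, also matched)
    rng = np.random.default_rng(4)
    n = 5
    data = ModelData(
        X=rng.standard_normal((n, 1)),
        season=np.zeros(n, int),
        coords=rng.uniform(0, 1000, (n, 2)),
        camera=np.zeros(n, int),
        counts=np.full((n, 3), np.nan),
    )
    spec = ModelSpec(response="count", exposure="x0", covariates=(), gp=True)
    core = _ModelCore(spec, data)
    alpha, beta, logphi = 0.4, -0.7, 0.2
    u = rng.standard_normal(n)
    eta, rho = 0.8, 300.0
    params = {"alpha": alpha, "beta[x0,s1]": beta, "log_phi": logphi}
    params.update({f"u[{i}]": u[i] for i in range(n)})
    got = log_posterior(spec, params, data, gp_eta=eta, gp_rho=rho)
    # the implementation drops additive normalization constants, so compare
    # log-density *differences* against independent scipy evaluations
    base = {k: 0.0 for k in params}
    got0 = log_posterior(spec, base, data, gp_eta=eta, gp_rho=rho)
    want = float(
        stats.norm.logpdf(alpha, 0, 1.5) - stats.norm.logpdf(0, 0, 1.5)
        + stats.norm.logpdf(beta, 0, 1.0) - stats.norm.logpdf(0, 0, 1.0)
        + stats.norm.logpdf(logphi, 0, 1.5) - stats.norm.logpdf(0, 0, 1.5)
        + stats.norm.logpdf(u).sum() - n * stats.norm.logpdf(0)
    )
    assert got - got0 == pytest.approx(want, abs=1e-10)
    # the aux (GP hyperparameter) prior must also enter: changing eta shifts
    # the density by the half-normal exponent difference
    got_eta = log_posterior(spec, params, data, gp_eta=1.6, gp_rho=rho)
    assert got_eta - got == pytest.approx(-0.5 * 1.6**2 + 0.5 * eta**2, abs=1e-10)


def test_duplicating_a_site_doubles_its_contribution():
    rng = np.random.default_rng(8)
    base = _toy_data(rng, n=4)
    base.season = np.zeros(4, int)  # single season: stable parameter layout
    spec = ModelSpec(response="count", exposure="x0", covariates=("x1",), gp=False)
    core1 = _ModelCore(spec, base)
    th = 0.2 * rng.standard_normal(core1.dim)
    lp1, _ = core1.logp_grad(th)

    dup = ModelData(
        X=np.vstack([base.X, base.X[:1]]),
        season=np.append(base.season, 0),
        coords=np.vstack([base.coords, base.coords[:1] + 1.0]),
        camera=np.append(base.camera, base.camera[0]),
        counts=np.vstack([base.counts, base.counts[:1]]),
    )
    lp2, _ = _ModelCore(spec, dup).logp_grad(th)

    # the duplicated site adds exactly its own NB likelihood once more
    alpha, beta = th[0], th[1:3]
    mu = math.exp(alpha + float(base.X[0] @ beta))
    phi = math.exp(th[3])
    extra = nb_loglik(base.counts[:1], mu, phi)
    assert lp2 - lp1 == pytest.approx(extra, abs=1e-10)


def test_posterior_finite_at_extreme_logits():
    rng = np.random.default_rng(9)
    data = _toy_data(rng)
    for resp in ["occupancy", "count", "night"]:
        spec = ModelSpec(response=resp, exposure="x0", covariates=("x1",), gp=False)
        core = _ModelCore(spec, data)
        th = np.zeros(core.dim)
        th[0] = 35.0
        lp, g = core.logp_grad(th)
        assert np.isfinite(lp)
        assert np.all(np.isfinite(g))


# --- diagnostics -------------------------------------------------------------

def test_rhat_and_ess_iid_chains():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((4, 1000))
    assert split_rhat(x) < 1.01
    assert ess(x) > 1000


def test_rhat_detects_disagreeing_chains():
    rng = np.random.default_rng(1)
    x = np.vstack([rng.normal(0, 0.1, (1, 500)), rng.normal(5, 0.1, (1, 500))])
    assert split_rhat(x) > 1.1


def test_rhat_chain_permutation_invariant():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((4, 300))
    assert split_rhat(x) == pytest.approx(split_rhat(x[::-1]), abs=1e-12)


def test_constant_chains_report_missing():
    x = np.ones((2, 100))
    assert math.isnan(split_rhat(x))
    assert math.isnan(ess(x))


# --- sampler correctness -----------------------------------------------------

def test_hmc_recovers_conjugate_beta_binomial_posterior():
    # y successes of n trials, Uniform(0,1) prior on p, sampled via the logit
    # transform; posterior is Beta(y+1, n-y+1) with known mean
    y, n = 27, 80

    def lg(th):
        t = float(th[0])
        p = expit(t)
        # binomial likelihood + logistic jacobian of the uniform prior,
        # written with log-expit for stability at extreme logits
        log_p = -np.logaddexp(0.0, -t)
        log_q = -np.logaddexp(0.0, t)
        lp = y * log_p + (n - y) * log_q + log_p + log_q
        grad = np.array([y - n * p + 1 - 2 * p])
        return lp, grad

    res = hmc_sample(lg, np.zeros(1), chains=2, warmup=500, iters=1000, seed=3)
    p_draws = expit(res.pooled()[:, 0])
    want = (y + 1) / (n + 2)
    mcse = p_draws.std() / math.sqrt(ess(res.draws[:, :, 0]))
    assert p_draws.mean() == pytest.approx(want, abs=4 * mcse + 1e-4)


def test_sample_posterior_deterministic_given_seed(small_sites, default_params):
    from invade.synthetic import simulate_observations

    obs, _ = simulate_observations(small_sites, default_params, days=15, seed=7)
    spec = ModelSpec(response="count", exposure="opuntia_cover_pct", covariates=(), gp=False)
    data = build_model_data(small_sites, obs, spec)
    a = sample_posterior(spec, data, chains=2, warmup=150, iters=100, seed=11, check=False)
    b = sample_posterior(spec, data, chains=2, warmup=150, iters=100, seed=11, check=False)
    np.testing.assert_array_equal(a.draws, b.draws)
    c = sample_posterior(spec, data, chains=2, warmup=150, iters=100, seed=12, check=False)
    assert not np.array_equal(a.draws, c.draws)


def test_sample_posterior_warns_on_nonconvergence():
    # absurdly short warmup on a correlated posterior should trip R-hat
    rng = np.random.default_rng(13)
    data = _toy_data(rng, n=20, days=10)
    spec = ModelSpec(response="count", exposure="x0", covariates=("x1",), gp=True)
    import warnings

    from invade.sampler import ConvergenceWarning

    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        sample_posterior(spec, data, chains=2, warmup=12, iters=30, seed=1, check=True)
    # not guaranteed to warn on every seed, but the machinery must not crash;
    # assert the warning type is what's emitted when present
    assert all(issubclass(x.category, (ConvergenceWarning, FutureWarning, UserWarning)) for x in w)
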