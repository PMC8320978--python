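import numpy as np
import pytest
from scipy import integrate, stats
from statsmodels.tools.numdiff import approx_fprime

import betamev as bm
from betamev.likelihoods import Problem, gauss_hermite_rule
from betamev.measurement_error import estimate_nuisance


# ---------------------------------------------------------------------------
# quadrature rule
# ---------------------------------------------------------------------------

def test_rule_q1_is_zeroth_hermite_moment():
    r = gauss_hermite_rule(1)
    assert r.nodes[0] == pytest.approx(0.0, abs=1e-14)
    assert r.weights[0] == pytest.approx(np.sqrt(np.pi), abs=1e-12)


def test_rule_q2_nodes_and_weights():
    r = gauss_hermite_rule(2)
    assert np.allclose(np.sort(r.nodes), [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12)
    assert np.allclose(r.weights, np.sqrt(np.pi) / 2, atol=1e-12)
    # second Gaussian moment integrated exactly at Q = 2
    assert np.sum(r.weights * r.nodes**2) == pytest.approx(np.sqrt(np.pi) / 2, abs=1e-12)


@pytest.mark.parametrize("Q", [1, 5, 20, 50, 80])
def test_rule_invariants(Q):
    r = gauss_hermite_rule(Q)
    assert np.sum(r.weights) == pytest.approx(np.sqrt(np.pi), abs=1e-10)
    assert np.allclose(np.sort(r.nodes), -np.sort(r.nodes)[::-1], atol=1e-10)
    assert np.all(r.weights > 0)
    with pytest.raises(ValueError):
        gauss_hermite_rule(0)


# ---------------------------------------------------------------------------
# plain likelihoods (naive, rc)
# ---------------------------------------------------------------------------

def _two_obs_problem():
    spec = bm.ModelSpec(bm.LinearForm(("z",)), bm.LinearForm(()), mean_has_x=True,
                        precision_has_x=False)
    ds = bm.Dataset(np.array([0.3, 0.7]), {"z": np.array([0.5, 1.0]),
                                           "w": np.array([-1.0, 1.0])})
    theta = spec.pack([0.2, 0.4], [0.3], [1.5], [])
    return spec, ds, theta


def test_naive_matches_hand_summed_density():
    spec, ds, theta = _two_obs_problem()
    eta1 = 0.2 + 0.4 * ds.columns["z"] + 0.3 * ds.columns["w"]
    mu = 1 / (1 + np.exp(-eta1))
    phi = np.exp(1.5)
    expected = sum(bm.beta_log_density(y, m, phi) for y, m in zip(ds.y, mu))
    assert bm.naive_log_likelihood(theta, spec, ds) == pytest.approx(expected, abs=1e-10)


def test_rc_equals_naive_without_measurement_error():
    spec, ds, theta = _two_obs_problem()
    nuis = estimate_nuisance(ds.columns["w"], 0.0)  # k_x = 1
    assert bm.rc_log_likelihood(theta, spec, ds, nuis) == pytest.approx(
        bm.naive_log_likelihood(theta, spec, ds), abs=1e-12)


def test_rc_hand_computation_half_reliability():
    spec, ds, theta = _two_obs_problem()
    nuis = estimate_nuisance(ds.columns["w"], 1.0)  # s_w2 = 2, k = 0.5
    assert nuis.k_x == pytest.approx(0.5)
    x_check = 0.0 + 0.5 * (ds.columns["w"] - 0.0)
    eta1 = 0.2 + 0.4 * ds.columns["z"] + 0.3 * x_check
    mu = 1 / (1 + np.exp(-eta1))
    expected = sum(bm.beta_log_density(y, m, np.exp(1.5)) for y, m in zip(ds.y, mu))
    assert bm.rc_log_likelihood(theta, spec, ds, nuis) == pytest.approx(expected, abs=1e-10)


def test_rc_full_attenuation_uses_constant_covariate():
    spec, ds, theta = _two_obs_problem()
    nuis = estimate_nuisance(ds.columns["w"], 1.0)
    nuis.sigma_x2 = 1e-12  # k_x ~ 0: substitute collapses to w-bar
    xc = bm.rc_substitute(ds.columns["w"], nuis)
    assert np.allclose(xc, np.mean(ds.columns["w"]), atol=1e-10)


def test_naive_profile_maximum_single_observation():
    # constant-mu model, phi held fixed: the profile maximizer solves the
    # first-order condition psi(mu phi) - psi((1-mu) phi) = log(y/(1-y))
    from scipy.optimize import brentq
    from scipy.special import digamma

    spec = bm.ModelSpec(bm.LinearForm(()), bm.LinearForm(()), mean_has_x=False,
                        precision_has_x=False, error_prone="w")
    y0, phi = 0.37, 5.0
    ds = bm.Dataset(np.array([y0]), {"w": np.array([0.0])})
    grid = np.linspace(-3, 3, 2001)
    vals = [bm.naive_log_likelihood(spec.pack([g], [], [np.log(phi)], []), spec, ds)
            for g in grid]
    best_mu = 1 / (1 + np.exp(-grid[np.argmax(vals)]))
    mu_hat = brentq(lambda m: digamma(m * phi) - digamma((1 - m) * phi)
                    - np.log(y0 / (1 - y0)), 1e-6, 1 - 1e-6)
    assert best_mu == pytest.approx(mu_hat, abs=0.005)


# ---------------------------------------------------------------------------
# quadrature likelihood vs oracles
# ---------------------------------------------------------------------------

def _small_me_problem(rng):
    spec = bm.ModelSpec(bm.PowerForm(("z",)), bm.LinearForm(()), mean_has_x=True,
                        precision_has_x=True)
    n = 5
    z = rng.uniform(0.2, 1.2, n)
    x = rng.normal(0.0, 1.0, n)
    w = x + rng.normal(0.0, np.sqrt(1 / 3), n)
    theta = spec.pack([-0.6, 2.4], [0.8], [2.5], [0.4])
    shell = bm.Dataset(np.full(n, 0.5), {"z": z, "w": w})
    mu, phi = spec.mu_phi(theta, shell, x=x)
    y = bm.sample_beta(rng, mu, phi)
    return spec, bm.Dataset(y, {"z": z, "w": w}), theta


def test_approximate_loglik_matches_adaptive_integration(rng):
    spec, ds, theta = _small_me_problem(rng)
    sigma_e2 = 1 / 3
    xi = (0.1, 0.9)
    rule = gauss_hermite_rule(50)
    la = bm.approximate_log_likelihood(theta, xi, spec, ds, sigma_e2, rule)

    # oracle: per-observation adaptive integration of the conditional mixture
    mu_x, sigma_x2 = xi
    v = sigma_x2 + sigma_e2
    k = sigma_x2 / v
    total = 0.0
    for t in range(ds.n):
        w_t = ds.columns["w"][t]
        m = mu_x + k * (w_t - mu_x)
        s2 = sigma_e2 * k
        total += stats.norm.logpdf(w_t, mu_x, np.sqrt(v))

        def integrand(x):
            sub = bm.Dataset(np.array([ds.y[t]]),
                             {"z": ds.columns["z"][t:t + 1], "w": np.array([x])})
            mu, phi = spec.mu_phi(theta, sub, x=np.array([x]))
            return float(np.exp(bm.beta_log_density(ds.y[t], mu[0], phi[0]))
                         * stats.norm.pdf(x, m, np.sqrt(s2)))

        val, _ = integrate.quad(integrand, m - 10 * np.sqrt(s2), m + 10 * np.sqrt(s2),
                                limit=200)
        total += np.log(val)
    assert la == pytest.approx(total, abs=1e-8)


def test_vanishing_error_variance_collapses_to_naive(scenario1_draw):
    spec, truth, ds, _ = scenario1_draw
    rule = gauss_hermite_rule(50)
    w = ds.columns["w"]
    xi = (float(np.mean(w)), float(np.var(w, ddof=1)))
    la = bm.approximate_log_likelihood(truth, xi, spec, ds, 1e-12, rule)
    l1 = bm.restricted_log_likelihood(xi, w, 1e-12)[0]
    assert la - l1 == pytest.approx(bm.naive_log_likelihood(truth, spec, ds), abs=1e-6)


def test_pseudo_equals_approximate_at_stage1_estimate(scenario2_draw):
    spec, truth, ds, cfg = scenario2_draw
    nuis = estimate_nuisance(ds.columns["w"], cfg.sigma_e2)
    rule = gauss_hermite_rule(50)
    lp = bm.pseudo_log_likelihood(truth, nuis, spec, ds, rule)
    la = bm.approximate_log_likelihood(truth, (nuis.mu_x, nuis.sigma_x2), spec, ds,
                                       cfg.sigma_e2, rule)
    assert lp == pytest.approx(la, abs=1e-10)


def test_quadrature_order_stability_and_monotone_error(scenario1_draw):
    spec, truth, ds, cfg = scenario1_draw
    nuis = estimate_nuisance(ds.columns["w"], cfg.sigma_e2)
    xi = (nuis.mu_x, nuis.sigma_x2)
    vals = {Q: bm.approximate_log_likelihood(truth, xi, spec, ds, cfg.sigma_e2,
                                             gauss_hermite_rule(Q))
            for Q in (4, 8, 12, 30, 50, 80)}
    errs = [abs(vals[Q] - vals[80]) for Q in (4, 8, 12, 30, 50)]
    assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))
    assert max(abs(vals[Q] - vals[80]) for Q in (12, 30, 50)) < 1e-4


def test_loglik_finite_at_high_precision(scenario1_draw):
    spec, _, ds, cfg = scenario1_draw
    theta = spec.pack([-0.6, 2.4], [0.8], [5.7], [])  # phi ~ 300
    nuis = estimate_nuisance(ds.columns["w"], cfg.sigma_e2)
    val = bm.pseudo_log_likelihood(theta, nuis, spec, ds, gauss_hermite_rule(50))
    assert np.isfinite(val)


def test_objectives_invariant_to_row_order(scenario2_draw, rng):
    spec, truth, ds, cfg = scenario2_draw
    perm = rng.permutation(ds.n)
    ds_perm = ds.subset(perm)
    nuis = estimate_nuisance(ds.columns["w"], cfg.sigma_e2)
    rule = gauss_hermite_rule(30)
    assert bm.naive_log_likelihood(truth, spec, ds_perm) == pytest.approx(
        bm.naive_log_likelihood(truth, spec, ds), rel=1e-12)
    assert bm.rc_log_likelihood(truth, spec, ds_perm, nuis) == pytest.approx(
        bm.rc_log_likelihood(truth, spec, ds, nuis), rel=1e-12)
    assert bm.pseudo_log_likelihood(truth, nuis, spec, ds_perm, rule) == pytest.approx(
        bm.pseudo_log_likelihood(truth, nuis, spec, ds, rule), rel=1e-12)


# ---------------------------------------------------------------------------
# analytic score vs finite differences
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("scenario_fixture", ["scenario1_draw", "scenario2_draw",
                                              "scenario3_draw"])
def test_score_matches_finite_differences(scenario_fixture, request, rng):
    spec, truth, ds, cfg = request.getfixturevalue(scenario_fixture)
    rule = gauss_hermite_rule(30)
    sigma_e2 = cfg.sigma_e2
    k = spec.n_params
    for _ in range(7):
        theta = truth + rng.normal(0, 0.08, size=k)
        xi = (rng.normal(cfg.mu_x, 0.1), cfg.sigma_x2 * rng.uniform(0.8, 1.2))
        analytic = bm.approximate_score(theta, xi, spec, ds, sigma_e2, rule)

        def f(p):
            return bm.approximate_log_likelihood(p[:k], (p[k], p[k + 1]), spec, ds,
                                                 sigma_e2, rule)

        fd = approx_fprime(np.concatenate([theta, xi]), f, centered=True)
        assert np.allclose(analytic, fd, rtol=1e-5, atol=1e-5 * (1 + np.abs(fd).max()))


def test_score_vanishes_at_maximizer(scenario1_draw):
    spec, truth, ds, cfg = scenario1_draw
    me = bm.MeasurementErrorConfig(sigma_e2=cfg.sigma_e2)
    fit = bm.fit_all(spec, ds, me, ["aml"], bm.FitOptions(Q=30))["aml"]
    score = bm.approximate_score(fit.theta, (fit.nuisance.mu_x, fit.nuisance.sigma_x2),
                                 spec, ds, cfg.sigma_e2, gauss_hermite_rule(30))
    assert np.max(np.abs(score)) < 1e-3


def test_no_lambda_block_without_error_prone_precision(scenario1_draw):
    spec, truth, ds, _ = scenario1_draw
    assert spec.s == 0
    assert "lambda1" not in spec.param_names
    assert truth.size == spec.p + spec.r + spec.q
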