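import numpy as np
import pytest
from scipy.special import digamma, polygamma

import betamev as bm
from betamev.estimation import covariance_pml
from betamev.likelihoods import Problem, gauss_hermite_rule
from betamev.measurement_error import estimate_nuisance


def test_wald_interval_values():
    lo, hi, length = bm.wald_interval(1.0, 0.0, 0.95)
    assert lo == hi == 1.0 and length == 0.0
    _, _, length = bm.wald_interval(0.0, 1.0, 0.95)
    assert length == pytest.approx(3.9199, abs=1e-4)
    with pytest.raises(ValueError):
        bm.wald_interval(0.0, 1.0, 1.5)


def test_nonconverged_fit_refuses_intervals():
    res = bm.FitResult(method="naive", theta=np.zeros(2), param_names=["a", "b"],
                       loglik=0.0, converged=False, n_iter=1, grad_norm=1.0,
                       cov=np.eye(2))
    with pytest.raises(RuntimeError):
        res.conf_int(0.95)


def test_zero_error_variance_makes_all_methods_agree():
    cfg = bm.ScenarioConfig(scenario=1, n=120, kx=0.95, R=1, seed=21)
    spec, truth = bm.scenario_model(cfg)
    ds = bm.generate_scenario(cfg, 0)
    me = bm.MeasurementErrorConfig(sigma_e2=0.0)
    fits = bm.fit_all(spec, ds, me, ["naive", "rc", "aml", "pml"],
                      bm.FitOptions(Q=30, compute_cov=False))
    base = fits["naive"].theta
    for m in ("rc", "aml", "pml"):
        assert np.allclose(fits[m].theta, base, atol=1e-4), m


def test_parameter_recovery_scenario1_fixed_seed():
    cfg = bm.ScenarioConfig(scenario=1, n=160, kx=0.95, gamma1=2.8, R=1, seed=314)
    spec, truth = bm.scenario_model(cfg)
    ds = bm.generate_scenario(cfg, 0)
    me = bm.MeasurementErrorConfig(sigma_e2=cfg.sigma_e2)
    fit = bm.fit_all(spec, ds, me, ["pml"], bm.FitOptions(Q=50))["pml"]
    assert fit.converged
    assert np.all(np.abs(fit.theta - truth) <= 3 * fit.se)


def test_observed_information_matches_expected_information(rng):
    """Intercept-only beta fit: observed-information SEs vs the expected
    information computed independently from the analytic per-observation
    score (information identity, Monte Carlo expectation)."""
    mu, phi, n = 0.3, 5.0, 800
    y = bm.sample_beta(rng, np.full(n, mu), np.full(n, phi))
    spec = bm.ModelSpec(bm.LinearForm(()), bm.LinearForm(()), mean_has_x=False,
                        precision_has_x=False, error_prone="w")
    ds = bm.Dataset(y, {"w": np.zeros(n)})
    fit = bm.fit_all(spec, ds, None, ["naive"], bm.FitOptions())["naive"]
    assert fit.converged

    # independent oracle: E[U U^T] at the truth from 200k fresh draws,
    # scores written directly from the density (eta = logit mu, gamma = log phi)
    yy = bm.sample_beta(rng, np.full(200_000, mu), np.full(200_000, phi))
    ystar = np.log(yy / (1 - yy))
    mustar = digamma(mu * phi) - digamma((1 - mu) * phi)
    u_eta = phi * (ystar - mustar) * mu * (1 - mu)
    u_gam = (mu * (ystar - mustar) + np.log1p(-yy)
             - digamma((1 - mu) * phi) + digamma(phi)) * phi
    U = np.column_stack([u_eta, u_gam])
    info = U.T @ U / len(yy) * n
    se_expected = np.sqrt(np.diag(np.linalg.inv(info)))
    assert np.allclose(fit.se, se_expected, rtol=0.10)


def test_covariance_symmetric_and_psd(scenario2_draw):
    spec, truth, ds, cfg = scenario2_draw
    me = bm.MeasurementErrorConfig(sigma_e2=cfg.sigma_e2)
    fit = bm.fit_all(spec, ds, me, ["aml"], bm.FitOptions(Q=30))["aml"]
    C = fit.cov
    assert np.allclose(C, C.T, rtol=1e-8, atol=1e-12)
    assert np.all(np.linalg.eigvalsh(C) > -1e-10)


def test_pml_sandwich_dominates_information_inverse(scenario2_draw):
    """The stage-1 correction term of the sandwich is PSD, so the sandwich
    covariance dominates the plain inverse information in the Loewner sense."""
    spec, truth, ds, cfg = scenario2_draw
    me = bm.MeasurementErrorConfig(sigma_e2=cfg.sigma_e2)
    fit = bm.fit_all(spec, ds, me, ["pml"], bm.FitOptions(Q=30))["pml"]
    prob = Problem(spec, ds)
    nuis = fit.nuisance
    rule = gauss_hermite_rule(30)
    from betamev.estimation import _hessian_from_grad

    def grad_theta(th):
        return prob.quad(th, nuis.mu_x, nuis.sigma_x2, nuis.sigma_e2, rule,
                         need_grad=True)[1]

    I_tt = -_hessian_from_grad(grad_theta, fit.theta)
    diff = fit.cov - np.linalg.inv(I_tt)
    assert np.all(np.linalg.eigvalsh(0.5 * (diff + diff.T)) > -1e-8)


def test_pml_standard_errors_track_monte_carlo_sd():
    cfg = bm.ScenarioConfig(scenario=1, n=160, kx=0.75, gamma1=2.8, R=150, seed=88)
    metrics = bm.run_monte_carlo(cfg, ["pml"], compute_intervals=True,
                                 keep_estimates=True)
    mc_sd = metrics.estimates["pml"].std(axis=0)
    avg_len = metrics.tables["pml"]["length"].to_numpy()
    implied_se = avg_len / (2 * 1.959964)
    # average reported SE within 25% of the Monte Carlo spread
    assert np.all(np.abs(implied_se / mc_sd - 1.0) < 0.25)


def test_warm_start_never_decreases_objective(scenario1_draw):
    spec, truth, ds, cfg = scenario1_draw
    me = bm.MeasurementErrorConfig(sigma_e2=cfg.sigma_e2)
    fits = bm.fit_all(spec, ds, me, ["rc", "pml"], bm.FitOptions(Q=30))
    nuis = fits["pml"].nuisance
    rule = gauss_hermite_rule(30)
    start_val = bm.pseudo_log_likelihood(fits["rc"].theta, nuis, spec, ds, rule)
    assert fits["pml"].loglik >= start_val - 1e-8
    # maximizer property: fitted objective beats the truth
    assert fits["pml"].loglik >= bm.pseudo_log_likelihood(truth, nuis, spec, ds,
                                                          rule) - 1e-8


def test_estimates_invariant_to_row_order(scenario1_draw, rng):
    spec, truth, ds, cfg = scenario1_draw
    me = bm.MeasurementErrorConfig(sigma_e2=cfg.sigma_e2)
    perm = rng.permutation(ds.n)
    f1 = bm.fit_all(spec, ds, me, ["pml"], bm.FitOptions(Q=30, compute_cov=False))
    f2 = bm.fit_all(spec, ds.subset(perm), me,
                    ["pml"], bm.FitOptions(Q=30, compute_cov=False))
    assert np.allclose(f1["pml"].theta, f2["pml"].theta, atol=1e-6)


def test_affine_recoding_of_error_free_covariate_compensates(rng):
    """Linear mean form: recoding u -> 2u + 1 changes coefficients but not
    the fitted means."""
    n = 120
    u = rng.uniform(0.0, 1.0, n)
    w = rng.normal(0.0, 1.0, n)
    eta = 0.3 + 0.8 * u + 0.5 * w
    mu = 1 / (1 + np.exp(-eta))
    y = bm.sample_beta(rng, mu, np.full(n, 30.0))
    spec = bm.ModelSpec(bm.LinearForm(("u",)), bm.LinearForm(()), mean_has_x=True,
                        precision_has_x=False)
    ds1 = bm.Dataset(y, {"u": u, "w": w})
    ds2 = bm.Dataset(y, {"u": 2 * u + 1, "w": w})
    f1 = bm.fit_all(spec, ds1, None, ["naive"], bm.FitOptions(compute_cov=False))["naive"]
    f2 = bm.fit_all(spec, ds2, None, ["naive"], bm.FitOptions(compute_cov=False))["naive"]
    mu1 = spec.mu_phi(f1.theta, ds1)[0]
    mu2 = spec.mu_phi(f2.theta, ds2)[0]
    assert np.allclose(mu1, mu2, atol=1e-5)
    assert f2.theta[1] == pytest.approx(f1.theta[1] / 2, abs=1e-4)


def test_bootstrap_rc_seeded_and_stable():
    cfg = bm.ScenarioConfig(scenario=1, n=40, kx=0.75, gamma1=2.8, R=1, seed=17)
    spec, truth = bm.scenario_model(cfg)
    ds = bm.generate_scenario(cfg, 0)
    me = bm.MeasurementErrorConfig(sigma_e2=cfg.sigma_e2)
    se_a, fail_a = bm.bootstrap_rc(spec, ds, me, B=500, seed=5)
    se_b, _ = bm.bootstrap_rc(spec, ds, me, B=500, seed=5)
    assert np.array_equal(se_a, se_b)  # bit-reproducible under a fixed seed
    se_c, _ = bm.bootstrap_rc(spec, ds, me, B=1000, seed=5)
    assert np.all(np.abs(se_c / se_a - 1.0) < 0.10)  # stable in B
    with pytest.raises(ValueError):
        bm.bootstrap_rc(spec, ds, me, B=50, seed=5)


def test_fit_options_validation():
    with pytest.raises(ValueError):
        bm.FitOptions(method="mle")
    with pytest.raises(ValueError):
        bm.FitOptions(Q=2)
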