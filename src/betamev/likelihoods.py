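"""Objective functions for the four estimators.

naive  : ordinary nonlinear beta log-likelihood with the observed w used as x
rc     : same likelihood with the regression-calibration substitute E(x | w)
aml    : Gauss-Hermite approximation to the joint marginal log-likelihood of
         (y, w), a function of (theta, mu_x, sigma_x2) with sigma_e2 known
pml    : the same quadrature objective with the nuisance xi frozen at its
         stage-1 estimate, a function of theta only

The latent covariate is integrated out with the physicists' Gauss-Hermite
rule after the standardizing change of variable
x = mu_{x|w} + sqrt(2 sigma^2_{x|w}) u, so node covariates are
x*_tq = mu_{x_t|w_t} + sqrt(2 sigma^2_{x|w}) s_q.  Inner quadrature sums are
evaluated in log space (log-sum-exp), which keeps the objective finite for
precisions up to several hundred where the literal product form under- or
overflows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import digamma, gammaln, logsumexp

from .measurement_error import NuisanceEstimate, rc_substitute
from .model import Dataset, ModelSpec

DEFAULT_Q = 50


@dataclass(frozen=True)
class QuadratureRule:
    """Physicists' Gauss-Hermite rule: int e^{-u^2} h(u) du ~ sum nu_q h(s_q)."""

    Q: int
    nodes: np.ndarray
    weights: np.ndarray

    @property
    def log_norm_weights(self) -> np.ndarray:
        """log(nu_q / sqrt(pi)); the normalized weights sum to one."""
        return np.log(self.weights) - 0.5 * np.log(np.pi)


def gauss_hermite_rule(Q: int) -> QuadratureRule:
    if Q < 1:
        raise ValueError("quadrature order Q must be >= 1")
    nodes, weights = np.polynomial.hermite.hermgauss(int(Q))
    return QuadratureRule(int(Q), nodes, weights)


class Problem:
    """Precompiled view of (spec, dataset): numpy arrays ready for repeated
    objective evaluation.  ``w`` may be overridden with a standardized proxy."""

    def __init__(self, spec: ModelSpec, dataset: Dataset, w: Optional[np.ndarray] = None):
        self.spec = spec
        self.dataset = dataset
        self.y = dataset.y
        self.logy = np.log(self.y)
        self.log1my = np.log1p(-self.y)
        self.ystar = self.logy - self.log1my
        self.Z1 = dataset.matrix(spec.mean_form.covariates)
        self.Z2 = dataset.matrix(spec.precision_form.covariates)
        if w is None:
            w = dataset.columns.get(spec.error_prone)
        self.w = None if w is None else np.asarray(w, dtype=float)
        self.n = dataset.n

    # ---- plain (no quadrature) beta log-likelihood --------------------
    def plain(self, theta: np.ndarray, x: np.ndarray, need_grad: bool = False):
        """Sum_t log f(y_t; mu_t, phi_t) with x plugged in as an error-free
        covariate; optionally the analytic score over theta."""
        spec = self.spec
        parts = spec.unpack(theta)
        with np.errstate(over="ignore", invalid="ignore"):
            eta1 = spec.mean_form.free(parts["alpha"], self.Z1)
            eta2 = spec.precision_form.free(parts["gamma"], self.Z2)
            if spec.mean_has_x:
                eta1 = eta1 + parts["beta"][0] * x
            if spec.precision_has_x:
                eta2 = eta2 + parts["lambda"][0] * x
            mu = spec._g1.inverse(eta1)
            phi = spec._g2.inverse(eta2)
            mphi = mu * phi
            cphi = phi - mphi
            ll_t = (
                gammaln(phi) - gammaln(mphi) - gammaln(cphi)
                + (mphi - 1.0) * self.logy + (cphi - 1.0) * self.log1my
            )
        ll = float(np.sum(ll_t))
        if not need_grad:
            return ll, None
        with np.errstate(over="ignore", invalid="ignore"):
            mustar = digamma(mphi) - digamma(cphi)
            gm = phi * (self.ystar - mustar) * spec._g1.dinv(mu)
            ga = (
                mu * (self.ystar - mustar) + self.log1my
                - digamma(cphi) + digamma(phi)
            ) * spec._g2.dinv(phi)
        grad = np.empty(spec.n_params)
        sls = spec.slices
        grad[sls["alpha"]] = spec.mean_form.free_jac(parts["alpha"], self.Z1).T @ gm
        if spec.mean_has_x:
            grad[sls["beta"]] = gm @ x
        grad[sls["gamma"]] = spec.precision_form.free_jac(parts["gamma"], self.Z2).T @ ga
        if spec.precision_has_x:
            grad[sls["lambda"]] = ga @ x
        return ll, grad

    # ---- Gauss-Hermite marginal log-likelihood -------------------------
    def quad(self, theta: np.ndarray, mu_x: float, sigma_x2: float, sigma_e2: float,
             rule: QuadratureRule, need_grad: bool = False, need_xi_grad: bool = False,
             check_finite: bool = False):
        """l_a evaluated at (theta, xi): the Gaussian marginal term of w plus
        the log-sum-exp quadrature term per observation.

        Returns (ll, grad_theta | None, grad_xi | None); grad_xi is with
        respect to (mu_x, sigma_x2) on the natural scale.
        """
        spec = self.spec
        if self.w is None:
            raise ValueError("model has no error-prone covariate column")
        if sigma_x2 <= 0.0:
            raise ValueError("sigma_x2 must be positive")
        parts = spec.unpack(theta)
        w = self.w
        v = sigma_x2 + sigma_e2
        k = sigma_x2 / v
        dev = w - mu_x
        cond_mean = mu_x + k * dev
        cond_sd2 = np.sqrt(2.0 * sigma_e2 * k)
        xs = cond_mean[:, None] + cond_sd2 * rule.nodes[None, :]  # (n, Q)

        with np.errstate(over="ignore", invalid="ignore"):
            eta1 = spec.mean_form.free(parts["alpha"], self.Z1)[:, None]
            if spec.mean_has_x:
                eta1 = eta1 + parts["beta"][0] * xs
            eta2 = spec.precision_form.free(parts["gamma"], self.Z2)
            if spec.precision_has_x:
                eta2 = eta2[:, None] + parts["lambda"][0] * xs
            mu = spec._g1.inverse(eta1)
            phi = spec._g2.inverse(eta2)
            if phi.ndim == 1:
                phi = phi[:, None]
            mphi = mu * phi
            cphi = phi - mphi
            ll_tq = (
                gammaln(phi) - gammaln(mphi) - gammaln(cphi)
                + (mphi - 1.0) * self.logy[:, None] + (cphi - 1.0) * self.log1my[:, None]
            )
        if check_finite and not np.all(np.isfinite(ll_tq)):
            t, q = np.argwhere(~np.isfinite(ll_tq))[0]
            raise FloatingPointError(
                f"non-finite node log-density at observation t={t}, node q={q}"
            )
        lw = rule.log_norm_weights[None, :] + ll_tq
        l2 = logsumexp(lw, axis=1)
        l1 = -0.5 * np.log(2.0 * np.pi * v) - dev**2 / (2.0 * v)
        ll = float(np.sum(l1) + np.sum(l2))
        if not need_grad and not need_xi_grad:
            return ll, None, None

        om = np.exp(lw - l2[:, None])  # normalized node weights, rows sum to 1
        with np.errstate(over="ignore", invalid="ignore"):
            mustar = digamma(mphi) - digamma(cphi)
            resid = self.ystar[:, None] - mustar
            gm = phi * resid * spec._g1.dinv(mu)  # d l_tq / d eta1
            ga = (
                mu * resid + self.log1my[:, None] - digamma(cphi) + digamma(phi)
            ) * spec._g2.dinv(phi)  # d l_tq / d eta2

        grad_theta = None
        if need_grad:
            wm = om * gm  # weighted mean-submodel signal
            wa = om * ga
            grad_theta = np.empty(spec.n_params)
            sls = spec.slices
            grad_theta[sls["alpha"]] = (
                spec.mean_form.free_jac(parts["alpha"], self.Z1).T @ wm.sum(axis=1)
            )
            if spec.mean_has_x:
                grad_theta[sls["beta"]] = float(np.sum(wm * xs))
            grad_theta[sls["gamma"]] = (
                spec.precision_form.free_jac(parts["gamma"], self.Z2).T @ wa.sum(axis=1)
            )
            if spec.precision_has_x:
                grad_theta[sls["lambda"]] = float(np.sum(wa * xs))

        grad_xi = None
        if need_xi_grad:
            # chain through the node covariates x*_tq
            deta_sum = np.zeros_like(om)
            if spec.mean_has_x:
                deta_sum += om * gm * parts["beta"][0]
            if spec.precision_has_x:
                deta_sum += om * ga * parts["lambda"][0]
            dk = sigma_e2 / v**2  # d k / d sigma_x2
            # d x*/d mu_x = 1 - k (all t, q); d x*/d sigma_x2 below
            dxs_dmx = 1.0 - k
            dsd = 0.0 if sigma_e2 == 0.0 else np.sqrt(2.0 * sigma_e2) * dk / (2.0 * np.sqrt(k))
            dxs_dsx2 = dk * dev[:, None] + dsd * rule.nodes[None, :]
            g_mu = float(np.sum(dev) / v + np.sum(deta_sum) * dxs_dmx)
            g_sx2 = float(
                -0.5 * self.n / v + float(np.sum(dev**2)) / (2.0 * v**2)
                + np.sum(deta_sum * dxs_dsx2)
            )
            grad_xi = np.array([g_mu, g_sx2])
        return ll, grad_theta, grad_xi


# ---------------------------------------------------------------------------
# public objective functions
# ---------------------------------------------------------------------------

def naive_log_likelihood(theta, spec: ModelSpec, dataset: Dataset) -> float:
    """Traditional beta log-likelihood with x := w verbatim."""
    prob = Problem(spec, dataset)
    return prob.plain(np.asarray(theta, float), prob.w)[0]


def rc_log_likelihood(theta, spec: ModelSpec, dataset: Dataset,
                      nuis: NuisanceEstimate) -> float:
    """Beta log-likelihood with the regression-calibration covariate
    x-check* = w-bar + k_x (w - w-bar) plugged into both submodels."""
    prob = Problem(spec, dataset)
    return prob.plain(np.asarray(theta, float), rc_substitute(prob.w, nuis))[0]


def approximate_log_likelihood(theta, xi, spec: ModelSpec, dataset: Dataset,
                               sigma_e2: float,
                               rule: Optional[QuadratureRule] = None) -> float:
    """Gauss-Hermite approximate log-likelihood l_a(theta, xi) of (y, w)."""
    rule = rule or gauss_hermite_rule(DEFAULT_Q)
    mu_x, sigma_x2 = float(xi[0]), float(xi[1])
    prob = Problem(spec, dataset)
    return prob.quad(np.asarray(theta, float), mu_x, sigma_x2, sigma_e2, rule,
                     check_finite=True)[0]


def pseudo_log_likelihood(theta, nuis: NuisanceEstimate, spec: ModelSpec,
                          dataset: Dataset,
                          rule: Optional[QuadratureRule] = None) -> float:
    """Approximate pseudo log-likelihood l_p(theta, xi-hat): identical
    numerics to l_a with xi frozen at the stage-1 estimate."""
    rule = rule or gauss_hermite_rule(DEFAULT_Q)
    prob = Problem(spec, dataset)
    return prob.quad(np.asarray(theta, float), nuis.mu_x, nuis.sigma_x2,
                     nuis.sigma_e2, rule, check_finite=True)[0]


def approximate_score(theta, xi, spec: ModelSpec, dataset: Dataset,
                      sigma_e2: float,
                      rule: Optional[QuadratureRule] = None) -> np.ndarray:
    """Analytic score of l_a over (theta, mu_x, sigma_x2), assembled from the
    per-node quantities (normalized node weights, mean/precision signals and
    the chain terms of the node covariates through xi)."""
    rule = rule or gauss_hermite_rule(DEFAULT_Q)
    mu_x, sigma_x2 = float(xi[0]), float(xi[1])
    prob = Problem(spec, dataset)
    _, g_theta, g_xi = prob.quad(np.asarray(theta, float), mu_x, sigma_x2,
                                 sigma_e2, rule, need_grad=True, need_xi_grad=True)
    return np.concatenate([g_theta, g_xi])


def restricted_log_likelihood(xi, w, sigma_e2: float,
                              need_grad: bool = False) -> Tuple[float, Optional[np.ndarray]]:
    """l_r(xi) = Sum_t l_1t(xi): the Gaussian marginal log-likelihood of w
    (used by the stage-1 fit and the pseudo-likelihood sandwich)."""
    mu_x, sigma_x2 = float(xi[0]), float(xi[1])
    w = np.asarray(w, dtype=float)
    v = sigma_x2 + sigma_e2
    if v <= 0.0:
        raise ValueError("sigma_x2 + sigma_e2 must be positive")
    dev = w - mu_x
    ll = float(np.sum(-0.5 * np.log(2.0 * np.pi * v) - dev**2 / (2.0 * v)))
    if not need_grad:
        return ll, None
    g = np.array([
        float(np.sum(dev) / v),
        float(-0.5 * w.size / v + np.sum(dev**2) / (2.0 * v**2)),
    ])
    return ll, g
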