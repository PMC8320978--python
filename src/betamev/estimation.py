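"""Optimizer drivers for the four estimators and their covariance estimators.

All methods maximize their objective with a quasi-Newton (BFGS) iteration fed
the analytic score.  Warm starting follows the chain
naive -> rc -> pml -> aml: the naive fit starts from link-scale least squares,
each corrected method starts from the previous one, and the aml nuisance
block starts at the stage-1 closed-form estimate.

Covariance estimators
---------------------
naive / rc : inverse observed information of the respective log-likelihood
             (the calibrated covariate treated as fixed); nonparametric
             bootstrap available for rc via :func:`bootstrap_rc`.
aml        : inverse observed information of l_a over the joint (theta, xi).
pml        : sandwich  I_tt^-1 + I_tt^-1 I_tx S_xx^-1 I_tx^T I_tt^-1  with
             I_tt = -d2 l_p/d theta2, I_tx = -d2 l_p/d theta d xi at
             (theta-hat, xi-hat) and S_xx the observed information of the
             stage-1 Gaussian likelihood of w; all blocks by central finite
             differences of the analytic scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .likelihoods import (DEFAULT_Q, Problem, QuadratureRule, gauss_hermite_rule,
                          restricted_log_likelihood)
from .measurement_error import (MeasurementErrorConfig, NuisanceEstimate,
                                estimate_nuisance, rc_substitute)
from .model import Dataset, ModelSpec

METHODS = ("naive", "rc", "aml", "pml")

# a BFGS run that stops on precision loss is still accepted as converged when
# the final score is this small in inf-norm
_ACCEPT_GRAD = 1e-3


@dataclass
class FitOptions:
    method: str = "pml"
    Q: int = DEFAULT_Q
    maxiter: int = 500
    gtol: float = 1e-6
    start: str = "naive_warm_start"  # or "user_supplied"
    theta0: Optional[np.ndarray] = None
    compute_cov: bool = True
    B: int = 1000  # bootstrap replications (rc standard errors on request)
    seed: Optional[int] = None
    levels: Tuple[float, ...] = (0.95,)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.Q < 4:
            raise ValueError("Q must be >= 4")
        if self.gtol <= 0.0:
            raise ValueError("gtol must be positive")


@dataclass
class FitResult:
    method: str
    theta: np.ndarray
    param_names: List[str]
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    nuisance: Optional[NuisanceEstimate] = None
    cov: Optional[np.ndarray] = None
    cov_xi: Optional[np.ndarray] = None
    cov_note: str = ""
    Q: Optional[int] = None

    @property
    def se(self) -> Optional[np.ndarray]:
        if self.cov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """(k, 2) Wald interval bounds; refuses on a non-converged fit."""
        if not self.converged:
            raise RuntimeError("refusing confidence intervals: fit did not converge")
        if self.cov is None:
            raise RuntimeError("no covariance available for this fit")
        lo, hi, _ = wald_interval(self.theta, self.se, level)
        return np.column_stack([lo, hi])

    def to_frame(self, levels: Sequence[float] = (0.95,)) -> pd.DataFrame:
        data = {"estimate": self.theta}
        if self.cov is not None:
            data["se"] = self.se
            if self.converged:
                for lv in levels:
                    lo, hi, _ = wald_interval(self.theta, self.se, lv)
                    data[f"lower{int(round(lv * 100))}"] = lo
                    data[f"upper{int(round(lv * 100))}"] = hi
        return pd.DataFrame(data, index=self.param_names)

    def summary(self, levels: Sequence[float] = (0.95,)) -> str:
        lines = [
            f"method: {self.method}" + (f" (Q={self.Q})" if self.Q else ""),
            f"log-likelihood: {self.loglik:.6f}",
            f"converged: {self.converged} (iterations={self.n_iter}, "
            f"|score|_inf={self.grad_norm:.3g})",
        ]
        if self.nuisance is not None:
            nu = self.nuisance
            lines.append(
                f"nuisance: mu_x={nu.mu_x:.6g}, sigma_x2={nu.sigma_x2:.6g}, "
                f"sigma_e2={nu.sigma_e2:.6g}, k_x={nu.k_x:.4f}"
            )
        if self.cov_note:
            lines.append(f"note: {self.cov_note}")
        lines.append(self.to_frame(levels).to_string(float_format=lambda v: f"{v:.5f}"))
        return "\n".join(lines)


def wald_interval(estimate, standard_error, level: float):
    """estimate +/- z_{1-(1-level)/2} * SE; returns (lower, upper, length)."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(standard_error, dtype=float)
    if np.any(~np.isfinite(se)):
        raise ValueError("non-finite standard error")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    lo = estimate - z * se
    hi = estimate + z * se
    return lo, hi, hi - lo


# ---------------------------------------------------------------------------
# numerical utilities
# ---------------------------------------------------------------------------

def _maximize(fg: Callable[[np.ndarray], Tuple[float, np.ndarray]], x0: np.ndarray,
              gtol: float, maxiter: int):
    """BFGS maximization of an (f, grad) callable; returns an OptimizeResult
    on the maximization scale."""

    def neg(x):
        f, g = fg(x)
        if not np.isfinite(f):
            return 1e12, np.zeros_like(x)
        return -f, -g

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(neg, np.asarray(x0, dtype=float), jac=True,
                                method="BFGS",
                                options={"gtol": gtol, "maxiter": maxiter})
    res.fun = -res.fun
    res.jac = -res.jac
    return res


def _hessian_from_grad(grad_fn: Callable[[np.ndarray], np.ndarray], x0: np.ndarray,
                       rel_step: float = 6e-6) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient (2*dim calls)."""
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    H = np.empty((dim, dim))
    for j in range(dim):
        h = rel_step * max(1.0, abs(x0[j]))
        xp = x0.copy(); xp[j] += h
        xm = x0.copy(); xm[j] -= h
        H[:, j] = (grad_fn(xp) - grad_fn(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _safe_inv(A: np.ndarray) -> Tuple[np.ndarray, str]:
    try:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError
        return np.linalg.inv(A), ""
    except np.linalg.LinAlgError:
        return np.linalg.pinv(A), "information matrix near-singular; pseudo-inverse used"


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _ols(y_link, X):
    X1 = np.column_stack([np.ones(len(y_link)), X]) if X.size else np.ones((len(y_link), 1))
    coef, *_ = np.linalg.lstsq(X1, y_link, rcond=None)
    fitted = X1 @ coef
    return coef, fitted


def _mean_start(spec: ModelSpec, prob: Problem, x: np.ndarray) -> List[np.ndarray]:
    """Candidate alpha/beta starts from link-scale least squares."""
    g1 = spec._g1
    yl = g1.apply(np.clip(prob.y, 1e-4, 1.0 - 1e-4))
    form = spec.mean_form
    Zcols = [prob.Z1[:, j] for j in range(prob.Z1.shape[1])]
    design = Zcols + ([x] if spec.mean_has_x else [])
    coef, fitted = _ols(yl, np.column_stack(design) if design else np.empty((prob.n, 0)))
    beta0 = [coef[1 + len(Zcols)]] if spec.mean_has_x else []
    cands: List[Tuple[np.ndarray, List[float]]] = []
    if form.kind == "linear":
        cands.append((np.concatenate([[coef[0]], coef[1:1 + len(Zcols)]]), beta0))
    elif form.kind == "power":
        # exponent 1 start; intercept absorbs the unit slope mismatch
        z = Zcols[0]
        a1 = coef[0] + (coef[1] - 1.0) * float(np.mean(z))
        cands.append((np.array([a1, 1.0]), beta0))
    elif form.kind == "rational":
        z1 = Zcols[0]
        zbar = float(np.mean(z1))
        c0, c1, c2 = coef[0], coef[1], coef[2]
        for a3 in (2.0 * float(np.max(np.abs(z1))) + 1.0,
                   -(2.0 * float(np.max(np.abs(z1))) + 1.0)):
            # match the local slope of the saturating term at z1-bar
            a2 = c1 * (zbar + a3) ** 2 / a3
            a1 = c0 + c1 * zbar - a2 * zbar / (zbar + a3)
            cands.append((np.array([a1, a2, a3, c2]), beta0))
    else:  # custom: zeros with the intercept guess in slot 0
        a = np.zeros(form.n_free)
        a[0] = coef[0]
        cands.append((a, beta0))
    return [(a, b, fitted) for (a, b) in cands]


def _precision_start(spec: ModelSpec, prob: Problem, fitted_eta1: np.ndarray) -> np.ndarray:
    mu0 = spec._g1.inverse(fitted_eta1)
    resid_var = float(np.var(prob.y - mu0)) or 1e-4
    phi0 = float(np.clip(np.mean(mu0 * (1.0 - mu0)) / resid_var - 1.0, 1.5, 5e3))
    g0 = spec._g2.apply(phi0)
    form = spec.precision_form
    gamma = np.zeros(form.n_free)
    if form.kind == "power":
        vbar = float(np.mean(prob.Z2[:, 0]))
        gamma[:] = [float(g0) - vbar, 1.0]
    else:
        gamma[0] = float(g0)
    return gamma


def candidate_starts(spec: ModelSpec, prob: Problem, x: np.ndarray) -> List[np.ndarray]:
    out = []
    for alpha, beta, fitted in _mean_start(spec, prob, x):
        gamma = _precision_start(spec, prob, fitted)
        lam = [0.0] if spec.precision_has_x else []
        out.append(spec.pack(alpha, beta, gamma, lam))
    return out


# ---------------------------------------------------------------------------
# the four fits
# ---------------------------------------------------------------------------

def _run(fg, starts: Iterable[np.ndarray], opts: FitOptions,
         rng: Optional[np.random.Generator]):
    """Try each start (plus jittered retries) until one converges; keep the
    best objective seen."""
    best = None
    tried = list(starts)
    for attempt, x0 in enumerate(tried):
        res = _maximize(fg, x0, opts.gtol, opts.maxiter)
        gnorm = float(np.max(np.abs(res.jac))) if res.jac.size else 0.0
        conv = bool(res.success) or gnorm < _ACCEPT_GRAD
        if best is None or (conv and not best[2]) or (conv == best[2] and res.fun > best[0].fun):
            best = (res, gnorm, conv)
        if conv:
            break
    if not best[2] and rng is not None:
        for _ in range(2):
            x0 = best[0].x + 0.2 * rng.standard_normal(best[0].x.size) * (
                1.0 + np.abs(best[0].x))
            res = _maximize(fg, x0, opts.gtol, opts.maxiter)
            gnorm = float(np.max(np.abs(res.jac))) if res.jac.size else 0.0
            conv = bool(res.success) or gnorm < _ACCEPT_GRAD
            if conv or res.fun > best[0].fun:
                best = (res, gnorm, conv)
            if conv:
                break
    return best


def _plain_fit(method: str, spec: ModelSpec, prob: Problem, x: np.ndarray,
               opts: FitOptions, rng, starts=None, nuis=None) -> FitResult:
    def fg(theta):
        return prob.plain(theta, x, need_grad=True)

    if starts is None:
        starts = candidate_starts(spec, prob, x)
    res, gnorm, conv = _run(fg, starts, opts, rng)
    fit = FitResult(method=method, theta=res.x, param_names=spec.param_names,
                    loglik=float(res.fun), converged=conv,
                    n_iter=int(res.nit), grad_norm=gnorm, nuisance=nuis)
    if opts.compute_cov:
        H = _hessian_from_grad(lambda th: prob.plain(th, x, need_grad=True)[1], res.x)
        fit.cov, fit.cov_note = _safe_inv(-H)
    return fit


def _pml_fit(spec: ModelSpec, prob: Problem, nuis: NuisanceEstimate,
             rule: QuadratureRule, opts: FitOptions, rng, starts) -> FitResult:
    def fg(theta):
        ll, g, _ = prob.quad(theta, nuis.mu_x, nuis.sigma_x2, nuis.sigma_e2,
                             rule, need_grad=True)
        return ll, g

    res, gnorm, conv = _run(fg, starts, opts, rng)
    fit = FitResult(method="pml", theta=res.x, param_names=spec.param_names,
                    loglik=float(res.fun), converged=conv, n_iter=int(res.nit),
                    grad_norm=gnorm, nuisance=nuis, Q=rule.Q)
    if opts.compute_cov:
        fit.cov, fit.cov_note = covariance_pml(prob, res.x, nuis, rule)
    return fit


def _aml_fit(spec: ModelSpec, prob: Problem, nuis: NuisanceEstimate,
             rule: QuadratureRule, opts: FitOptions, rng, starts) -> FitResult:
    k = spec.n_params

    def fg(z):
        theta, mu_x, lsx2 = z[:k], z[k], z[k + 1]
        sx2 = float(np.exp(np.clip(lsx2, -30.0, 30.0)))
        ll, g, gx = prob.quad(theta, mu_x, sx2, nuis.sigma_e2, rule,
                              need_grad=True, need_xi_grad=True)
        grad = np.concatenate([g, [gx[0], gx[1] * sx2]])  # chain to log scale
        return ll, grad

    z_starts = [np.concatenate([s, [nuis.mu_x, np.log(nuis.sigma_x2)]]) for s in starts]
    res, gnorm, conv = _run(fg, z_starts, opts, rng)
    theta_hat = res.x[:k]
    xi_hat = NuisanceEstimate(mu_x=float(res.x[k]),
                              sigma_x2=float(np.exp(res.x[k + 1])),
                              sigma_e2=nuis.sigma_e2)
    fit = FitResult(method="aml", theta=theta_hat, param_names=spec.param_names,
                    loglik=float(res.fun), converged=conv, n_iter=int(res.nit),
                    grad_norm=gnorm, nuisance=xi_hat, Q=rule.Q)
    if opts.compute_cov:
        cov_full, note = covariance_aml(prob, theta_hat, xi_hat, rule)
        fit.cov = cov_full[:k, :k]
        fit.cov_xi = cov_full[k:, k:]
        fit.cov_note = note
    return fit


# ---------------------------------------------------------------------------
# covariance estimators
# ---------------------------------------------------------------------------

def covariance_aml(prob: Problem, theta: np.ndarray, xi: NuisanceEstimate,
                   rule: QuadratureRule) -> Tuple[np.ndarray, str]:
    """Inverse of the negative Hessian of l_a at (theta-hat, xi-hat); the
    Hessian comes from central finite differences of the analytic score."""
    k = theta.size

    def grad(z):
        g_t, g_x = prob.quad(z[:k], z[k], z[k + 1], xi.sigma_e2, rule,
                             need_grad=True, need_xi_grad=True)[1:]
        return np.concatenate([g_t, g_x])

    z0 = np.concatenate([theta, [xi.mu_x, xi.sigma_x2]])
    H = _hessian_from_grad(grad, z0)
    return _safe_inv(-H)


def covariance_pml(prob: Problem, theta: np.ndarray, nuis: NuisanceEstimate,
                   rule: QuadratureRule) -> Tuple[np.ndarray, str]:
    """Pseudo-likelihood sandwich over theta (see module docstring)."""
    k = theta.size

    def grad_theta_at(th, mu_x, sx2):
        return prob.quad(th, mu_x, sx2, nuis.sigma_e2, rule, need_grad=True)[1]

    I_tt = -_hessian_from_grad(lambda th: grad_theta_at(th, nuis.mu_x, nuis.sigma_x2),
                               theta)
    # cross block: finite differences of the theta-score in xi
    I_tx = np.empty((k, 2))
    for j, val in enumerate((nuis.mu_x, nuis.sigma_x2)):
        h = 6e-6 * max(1.0, abs(val))
        args_p = [nuis.mu_x, nuis.sigma_x2]; args_p[j] += h
        args_m = [nuis.mu_x, nuis.sigma_x2]; args_m[j] -= h
        I_tx[:, j] = -(grad_theta_at(theta, *args_p) - grad_theta_at(theta, *args_m)) / (2 * h)
    # observed information of the stage-1 Gaussian likelihood of w
    S_xx = -_hessian_from_grad(
        lambda xi: restricted_log_likelihood(xi, prob.w, nuis.sigma_e2, need_grad=True)[1],
        np.array([nuis.mu_x, nuis.sigma_x2]),
    )
    I_tt_inv, note1 = _safe_inv(I_tt)
    S_xx_inv, note2 = _safe_inv(S_xx)
    corr = I_tt_inv @ I_tx @ S_xx_inv @ I_tx.T @ I_tt_inv
    cov = I_tt_inv + corr
    cov = 0.5 * (cov + cov.T)
    return cov, "; ".join(s for s in (note1, note2) if s)


def bootstrap_rc(spec: ModelSpec, dataset: Dataset, me_config: MeasurementErrorConfig,
                 B: int, seed: int, options: Optional[FitOptions] = None):
    """Nonparametric bootstrap standard errors for the rc estimator.

    Rows (y, covariates, w) are resampled with replacement; the nuisance
    estimation and the rc fit are re-run per replicate.  Returns
    (se, n_failed); replicates whose nuisance estimation or optimization
    fails are dropped and counted (a warning fires above 10% failures).
    """
    if B < 100:
        raise ValueError("need at least B = 100 bootstrap replications")
    opts = replace(options or FitOptions(method="rc"), method="rc", compute_cov=False)
    rng = np.random.default_rng(seed)
    reps = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, dataset.n, size=dataset.n)
        d = dataset.subset(idx)
        try:
            prob = Problem(spec, d)
            w_star, s_e2 = me_config.standardize(prob.w)
            nuis = estimate_nuisance(w_star, s_e2)
            fit = _plain_fit("rc", spec, Problem(spec, d, w=w_star),
                             rc_substitute(w_star, nuis), opts, rng, nuis=nuis)
            if not fit.converged:
                raise RuntimeError("rc replicate did not converge")
            reps.append(fit.theta)
        except (ValueError, RuntimeError, np.linalg.LinAlgError):
            failed += 1
    if failed > 0.1 * B:
        warnings.warn(f"bootstrap_rc: {failed} of {B} replicates failed", RuntimeWarning)
    if not reps:
        raise RuntimeError("all bootstrap replicates failed")
    return np.std(np.asarray(reps), axis=0, ddof=1), failed


# ---------------------------------------------------------------------------
# public drivers
# ---------------------------------------------------------------------------

def fit_all(spec: ModelSpec, dataset: Dataset,
            me_config: Optional[MeasurementErrorConfig],
            methods: Sequence[str], options: Optional[FitOptions] = None,
            rng: Optional[np.random.Generator] = None) -> Dict[str, FitResult]:
    """Fit the requested methods on one dataset with the warm-start chain.

    Intermediate methods needed only as warm starts are computed but not
    returned.  Raises ValueError if nuisance estimation fails (callers doing
    Monte Carlo catch and count this).
    """
    opts = options or FitOptions()
    methods = list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}")
    if rng is None:
        rng = np.random.default_rng(opts.seed if opts.seed is not None else 0)
    if spec.n_params >= dataset.n:
        raise ValueError("more parameters than observations")
    prob = Problem(spec, dataset)
    out: Dict[str, FitResult] = {}

    needs_me = any(m in methods for m in ("rc", "aml", "pml"))
    w_star, s_e2 = (prob.w, None)
    if needs_me:
        if me_config is None or me_config.sigma_e2 is None:
            raise ValueError("rc/aml/pml require a measurement-error configuration "
                             "with sigma_e2 available")
        w_star, s_e2 = me_config.standardize(prob.w)
        prob = Problem(spec, dataset, w=w_star)

    user_starts = [np.asarray(opts.theta0, float)] if (
        opts.start == "user_supplied" and opts.theta0 is not None) else None

    naive_fit = _plain_fit("naive", spec, prob, prob.w, opts, rng,
                           starts=user_starts)
    if "naive" in methods:
        out["naive"] = naive_fit

    if not needs_me:
        return out

    nuis = estimate_nuisance(w_star, s_e2)
    rc_fit = _plain_fit("rc", spec, prob, rc_substitute(w_star, nuis), opts, rng,
                        starts=[naive_fit.theta], nuis=nuis)
    if "rc" in methods:
        out["rc"] = rc_fit

    if "pml" in methods or "aml" in methods:
        rule = gauss_hermite_rule(opts.Q)
        pml_starts = [rc_fit.theta, naive_fit.theta]
        pml_fit = _pml_fit(spec, prob, nuis, rule, opts, rng, pml_starts)
        if "pml" in methods:
            out["pml"] = pml_fit
        if "aml" in methods:
            out["aml"] = _aml_fit(spec, prob, nuis, rule, opts, rng,
                                  [pml_fit.theta, rc_fit.theta])
    return out


def fit(spec: ModelSpec, dataset: Dataset,
        me_config: Optional[MeasurementErrorConfig] = None,
        options: Optional[FitOptions] = None) -> FitResult:
    """Fit one method (options.method) and return its FitResult."""
    opts = options or FitOptions()
    return fit_all(spec, dataset, me_config, [opts.method], opts)[opts.method]
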