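"""Structural measurement-error layer.

The latent covariate is x ~ N(mu_x, sigma_x^2); the observed proxy is
w = x + e with e ~ N(0, sigma_e^2) independent of x.  sigma_e^2 is assumed
known (identifiability), supplied directly, estimated from a calibration
regression, or pooled from within-unit replicates.  The reliability
coefficient k_x = sigma_x^2 / (sigma_x^2 + sigma_e^2) drives both the
conditional moments of x | w and the regression-calibration substitute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import statsmodels.api as sm


@dataclass
class MeasurementErrorConfig:
    """How the error variance is obtained and whether w is an affine proxy.

    Exactly one source of sigma_e2 applies: a known value, a calibration
    file/pairs, or replicate columns.  When the affine map
    w = tau1 + tau2 * x + e is active, the observed proxy is standardized to
    w* = (w - tau1)/tau2 and sigma_e2 rescaled by tau2**-2 before fitting, so
    the additive model w* = x + e* applies downstream.
    """

    sigma_e2: Optional[float] = None
    tau1: float = 0.0
    tau2: float = 1.0

    def __post_init__(self):
        if self.sigma_e2 is not None and self.sigma_e2 < 0.0:
            raise ValueError("sigma_e2 must be nonnegative")
        if self.tau2 == 0.0:
            raise ValueError("tau2 must be nonzero")

    @property
    def affine(self) -> bool:
        return self.tau1 != 0.0 or self.tau2 != 1.0

    def standardize(self, w: np.ndarray):
        """Return (w_star, sigma_e2_star) on the additive x + e scale."""
        if self.sigma_e2 is None:
            raise ValueError("sigma_e2 is not set")
        w = np.asarray(w, dtype=float)
        return (w - self.tau1) / self.tau2, self.sigma_e2 / self.tau2**2


@dataclass
class NuisanceEstimate:
    """Nuisance parameters xi = (mu_x, sigma_x^2) plus the implied
    conditional-moment machinery of x | w."""

    mu_x: float
    sigma_x2: float
    sigma_e2: float

    def __post_init__(self):
        if self.sigma_x2 <= 0.0:
            raise ValueError("sigma_x2 must be positive")
        if self.sigma_e2 < 0.0:
            raise ValueError("sigma_e2 must be nonnegative")

    @property
    def k_x(self) -> float:
        """Reliability coefficient sigma_x^2 / (sigma_x^2 + sigma_e^2)."""
        return self.sigma_x2 / (self.sigma_x2 + self.sigma_e2)

    @property
    def cond_var(self) -> float:
        """sigma^2_{x|w} = sigma_e^2 k_x, constant over observations."""
        return self.sigma_e2 * self.k_x

    def cond_mean(self, w) -> np.ndarray:
        """mu_{x|w} = mu_x + k_x (w - mu_x)."""
        w = np.asarray(w, dtype=float)
        return self.mu_x + self.k_x * (w - self.mu_x)


def estimate_nuisance(w, sigma_e2: float) -> NuisanceEstimate:
    """Stage-1 closed-form estimators: mu_x-hat = w-bar and
    sigma_x^2-hat = s_w^2 - sigma_e^2 (sample variance, divisor n-1).

    These are the maximizers of the marginal Gaussian likelihood of w (up to
    the n vs n-1 variance divisor) and feed both regression calibration and
    the pseudo-likelihood.
    """
    w = np.asarray(w, dtype=float)
    if w.size < 2:
        raise ValueError("need at least two observations of w")
    if sigma_e2 < 0.0:
        raise ValueError("sigma_e2 must be nonnegative")
    mu_x = float(np.mean(w))
    s_w2 = float(np.var(w, ddof=1))
    sigma_x2 = s_w2 - sigma_e2
    if sigma_x2 <= 0.0:
        raise ValueError(
            "sample variance of w does not exceed sigma_e2: the structural "
            "identifiability assumption sigma_x^2 > 0 cannot hold for these data"
        )
    return NuisanceEstimate(mu_x=mu_x, sigma_x2=sigma_x2, sigma_e2=float(sigma_e2))


@dataclass
class CalibrationFit:
    tau1: float
    tau2: float
    sigma_e2: float
    r2: float
    se_tau1: float
    se_tau2: float
    n: int


def calibration_regression(x_cal, w_cal) -> CalibrationFit:
    """OLS of the observed proxy w on the reference measurement x,
    w = tau1 + tau2 x + e; sigma_e2-hat = RSS / (n - 2).

    Used when paired (x, w) calibration data exist, as in the refinery
    application where the proxy comes from a second spectrophotometric
    complex.
    """
    x = np.asarray(x_cal, dtype=float)
    w = np.asarray(w_cal, dtype=float)
    if x.size != w.size:
        raise ValueError("x_cal and w_cal must have the same length")
    if x.size < 3:
        raise ValueError("need at least three calibration pairs")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate calibration design: x_cal is constant")
    res = sm.OLS(w, sm.add_constant(x)).fit()
    rss = float(np.sum(res.resid**2))
    return CalibrationFit(
        tau1=float(res.params[0]),
        tau2=float(res.params[1]),
        sigma_e2=rss / (x.size - 2),
        r2=float(res.rsquared),
        se_tau1=float(res.bse[0]),
        se_tau2=float(res.bse[1]),
        n=int(x.size),
    )


def pooled_replicate_variance(W) -> float:
    """sigma_e2 from replicate measurements: within-unit sample variances
    (divisor m-1 per unit) averaged across units.

    ``W`` is (n_units, m) with m >= 2 replicates per unit.
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape[1] < 2:
        raise ValueError("need at least two replicates per unit")
    return float(np.mean(np.var(W, axis=1, ddof=1)))


def rc_substitute(w, nuis: NuisanceEstimate) -> np.ndarray:
    """Regression-calibration covariate x-check* = w-bar + k_x (w - w-bar),
    i.e. the estimated E(x | w), plugged into both submodels as error-free."""
    return nuis.cond_mean(w)
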