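"""Link functions for the mean and precision submodels.

The mean link maps (0, 1) -> R, the precision link (0, inf) -> R; both are
strictly monotone and twice differentiable.  Inverse links clamp their output
strictly inside the open domain (``EPS = 1e-12``) so that the beta log-density
stays finite at optimizer trial points that map outside it.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit as _sp_logit

EPS = 1e-12
# cap on the precision linear predictor: keeps phi = exp(eta) finite and the
# log-density evaluable everywhere BFGS may probe
_ETA_PHI_MAX = 30.0


class Link:
    """Abstract scalar link g with vectorized apply/inverse.

    ``dinv`` returns d g^{-1}(eta)/d eta expressed as a function of the
    *inverse-link value* (mu or phi), i.e. 1/g'(mu) -- the form the score
    function needs.
    """

    name: str = ""

    def apply(self, v):  # pragma: no cover - interface
        raise NotImplementedError

    def inverse(self, eta):  # pragma: no cover - interface
        raise NotImplementedError

    def dinv(self, value):  # pragma: no cover - interface
        raise NotImplementedError


class LogitLink(Link):
    name = "logit"

    def apply(self, v):
        v = np.asarray(v, dtype=float)
        _check_open_unit(v)
        return _sp_logit(v)

    def inverse(self, eta):
        return np.clip(expit(np.asarray(eta, dtype=float)), EPS, 1.0 - EPS)

    def dinv(self, mu):
        return mu * (1.0 - mu)


class CLogLogLink(Link):
    """Complementary log-log link, g(mu) = log(-log(1 - mu)).

    Preferred when the response concentrates near 1: it softens the influence
    of observations in the upper tail compared with the logit.
    """

    name = "cloglog"

    def apply(self, v):
        v = np.asarray(v, dtype=float)
        _check_open_unit(v)
        return np.log(-np.log1p(-v))

    def inverse(self, eta):
        eta = np.clip(np.asarray(eta, dtype=float), -_ETA_PHI_MAX, _ETA_PHI_MAX)
        return np.clip(-np.expm1(-np.exp(eta)), EPS, 1.0 - EPS)

    def dinv(self, mu):
        # 1/g'(mu) = -(1 - mu) log(1 - mu)
        return -(1.0 - mu) * np.log1p(-mu)


class LogLink(Link):
    name = "log"

    def apply(self, v):
        v = np.asarray(v, dtype=float)
        if np.any(v <= 0.0):
            raise ValueError("log link requires a positive argument")
        return np.log(v)

    def inverse(self, eta):
        eta = np.clip(np.asarray(eta, dtype=float), np.log(EPS), _ETA_PHI_MAX)
        return np.exp(eta)

    def dinv(self, phi):
        return phi


def _check_open_unit(v):
    if np.any(v <= 0.0) or np.any(v >= 1.0):
        raise ValueError("mean link requires an argument strictly inside (0, 1)")


_MEAN_LINKS = {"logit": LogitLink, "cloglog": CLogLogLink}
_PRECISION_LINKS = {"log": LogLink}


def get_mean_link(name: str) -> Link:
    try:
        return _MEAN_LINKS[name]()
    except KeyError:
        raise ValueError(f"unknown mean link {name!r}; choose from {sorted(_MEAN_LINKS)}")


def get_precision_link(name: str) -> Link:
    try:
        return _PRECISION_LINKS[name]()
    except KeyError:
        raise ValueError(
            f"unknown precision link {name!r}; choose from {sorted(_PRECISION_LINKS)}"
        )
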