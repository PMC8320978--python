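"""Beta density in the mean/precision parameterization.

A response y in (0, 1) follows Beta(mu, phi) with E(y) = mu and
Var(y) = mu (1 - mu) / (1 + phi); the usual shape parameters are
a = mu * phi and b = (1 - mu) * phi.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def beta_log_density(y, mu, phi):
    """Log-density log f(y; mu, phi) of the mean/precision beta law.

    Parameters
    ----------
    y : array_like in (0, 1)
    mu : array_like in (0, 1)
        Mean parameter.
    phi : array_like > 0
        Precision parameter.

    Returns
    -------
    ndarray or float
        ``logGamma(phi) - logGamma(mu phi) - logGamma((1-mu) phi)
        + (mu phi - 1) log y + ((1-mu) phi - 1) log(1-y)``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("y must lie strictly inside (0, 1)")
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("mu must lie strictly inside (0, 1)")
    if np.any(phi <= 0.0):
        raise ValueError("phi must be positive")
    out = (
        gammaln(phi)
        - gammaln(mu * phi)
        - gammaln((1.0 - mu) * phi)
        + (mu * phi - 1.0) * np.log(y)
        + ((1.0 - mu) * phi - 1.0) * np.log1p(-y)
    )
    return out if out.ndim else float(out)


def beta_variance(mu, phi):
    """Var(y) = mu (1 - mu) / (1 + phi)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    return mu * (1.0 - mu) / (1.0 + phi)


def sample_beta(rng: np.random.Generator, mu, phi, size=None):
    """Draw y ~ Beta(mu phi, (1-mu) phi), re-drawing any value that rounds
    to exactly 0 or 1 in floating point (the support is open)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    a = mu * phi
    b = (1.0 - mu) * phi
    y = rng.beta(a, b, size=size)
    y = np.atleast_1d(np.asarray(y, dtype=float))
    bad = (y <= 0.0) | (y >= 1.0)
    tries = 0
    while np.any(bad):
        tries += 1
        if tries > 1000:
            raise ValueError(
                "beta draws keep rounding to 0/1: (mu, phi) put essentially "
                "all mass on the boundary"
            )
        redraw = rng.beta(np.broadcast_to(a, y.shape)[bad], np.broadcast_to(b, y.shape)[bad])
        y[bad] = redraw
        bad = (y <= 0.0) | (y >= 1.0)
    return y if size is not None or y.size > 1 else float(y[0])
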