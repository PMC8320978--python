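"""Model specification: the two nonlinear submodels and parameter packing.

The model couples a mean submodel g1(mu_t) = free1(z_t; alpha) + beta x_t and
a precision submodel g2(phi_t) = free2(v_t; gamma) + lambda x_t, where x_t is
the latent error-prone covariate (observed only through w_t = x_t + e_t) and
it is shared between the two submodels.  The packed interest-parameter vector
is theta = (alpha, beta, gamma, lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .forms import PredictorForm, central_difference_jacobian
from .links import Link, get_mean_link, get_precision_link


@dataclass
class Dataset:
    """In-memory dataset: response, named covariate columns, optional latent x.

    ``columns`` holds every covariate, including the observed error-prone
    column (conventionally named ``w``).  ``latent_x`` carries the simulated
    truth for diagnostics only; estimators never read it.
    """

    y: np.ndarray
    columns: Dict[str, np.ndarray]
    latent_x: Optional[np.ndarray] = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        if np.any(self.y <= 0.0) or np.any(self.y >= 1.0):
            raise ValueError("response must lie strictly inside (0, 1)")
        self.columns = {k: np.asarray(v, dtype=float) for k, v in self.columns.items()}
        for k, v in self.columns.items():
            if v.shape != self.y.shape:
                raise ValueError(f"column {k!r} length does not match response")

    @property
    def n(self) -> int:
        return self.y.size

    def matrix(self, names: Tuple[str, ...]) -> np.ndarray:
        missing = [c for c in names if c not in self.columns]
        if missing:
            raise KeyError(f"dataset is missing column(s) {missing}")
        if not names:
            return np.empty((self.n, 0))
        return np.column_stack([self.columns[c] for c in names])

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            self.y[idx],
            {k: v[idx] for k, v in self.columns.items()},
            None if self.latent_x is None else self.latent_x[idx],
        )


@dataclass
class ModelSpec:
    """Links, predictor forms and the role of the error-prone covariate.

    p = mean_form.n_free, r = 1 if the mean submodel uses x else 0, likewise
    q (gamma) and s (lambda) for the precision submodel; theta has length
    p + r + q + s and (p+r)+(q+s) must stay below n at fit time.
    """

    mean_form: PredictorForm
    precision_form: PredictorForm
    mean_link: str = "logit"
    precision_link: str = "log"
    mean_has_x: bool = True
    precision_has_x: bool = False
    response: str = "y"
    error_prone: str = "w"

    def __post_init__(self):
        self._g1: Link = get_mean_link(self.mean_link)
        self._g2: Link = get_precision_link(self.precision_link)

    # -- packing ---------------------------------------------------------
    @property
    def p(self) -> int:
        return self.mean_form.n_free

    @property
    def r(self) -> int:
        return 1 if self.mean_has_x else 0

    @property
    def q(self) -> int:
        return self.precision_form.n_free

    @property
    def s(self) -> int:
        return 1 if self.precision_has_x else 0

    @property
    def n_params(self) -> int:
        return self.p + self.r + self.q + self.s

    @property
    def slices(self) -> Dict[str, slice]:
        p, r, q, s = self.p, self.r, self.q, self.s
        return {
            "alpha": slice(0, p),
            "beta": slice(p, p + r),
            "gamma": slice(p + r, p + r + q),
            "lambda": slice(p + r + q, p + r + q + s),
        }

    @property
    def param_names(self) -> List[str]:
        names = [f"alpha{i+1}" for i in range(self.p)]
        names += [f"beta{i+1}" for i in range(self.r)]
        names += [f"gamma{i+1}" for i in range(self.q)]
        names += [f"lambda{i+1}" for i in range(self.s)]
        return names

    def pack(self, alpha, beta=(), gamma=(), lam=()) -> np.ndarray:
        theta = np.concatenate(
            [np.atleast_1d(np.asarray(b, float)) for b in (alpha, beta, gamma, lam)]
        )
        if theta.size != self.n_params:
            raise ValueError("packed parameter vector has wrong length")
        return theta

    def unpack(self, theta: np.ndarray) -> Dict[str, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"theta must have length {self.n_params}")
        return {k: theta[sl] for k, sl in self.slices.items()}

    # -- linear predictors ----------------------------------------------
    def eta(self, theta: np.ndarray, dataset: Dataset, x: Optional[np.ndarray] = None):
        """Linear predictors (eta1, eta2).

        ``x`` overrides the error-prone covariate (it may carry a trailing
        quadrature-node axis); by default the observed column is used
        verbatim (the naive convention).
        """
        parts = self.unpack(theta)
        Z1 = dataset.matrix(self.mean_form.covariates)
        Z2 = dataset.matrix(self.precision_form.covariates)
        if x is None:
            x = dataset.columns[self.error_prone]
        eta1 = self.mean_form.free(parts["alpha"], Z1)
        eta2 = self.precision_form.free(parts["gamma"], Z2)
        if x.ndim == 2:
            eta1 = eta1[:, None]
            eta2 = eta2[:, None] if self.precision_has_x else eta2
        if self.mean_has_x:
            eta1 = eta1 + parts["beta"][0] * x
        if self.precision_has_x:
            eta2 = eta2 + parts["lambda"][0] * x
        return eta1, eta2

    def mu_phi(self, theta, dataset: Dataset, x: Optional[np.ndarray] = None):
        eta1, eta2 = self.eta(theta, dataset, x)
        return self._g1.inverse(eta1), self._g2.inverse(eta2)


def evaluate_submodels(spec: ModelSpec, theta, dataset: Dataset,
                       x: Optional[np.ndarray] = None):
    """Per-observation (mu_t, phi_t) implied by theta; mu in (0,1), phi > 0
    after the inverse-link clamping."""
    return spec.mu_phi(np.asarray(theta, float), dataset, x)


def numeric_jacobians(spec: ModelSpec, theta, dataset: Dataset,
                      x: Optional[np.ndarray] = None, warn_rank: bool = True):
    """Central-difference Jacobians F1 = d eta1/d alpha, F2 = d eta1/d beta,
    F3 = d eta2/d gamma, F4 = d eta2/d lambda.

    Returns a dict with the four matrices plus their column ranks; rank
    deficiency is reported as a warning, not a failure.
    """
    theta = np.asarray(theta, dtype=float)
    sls = spec.slices

    def eta1_of(th):
        return spec.eta(th, dataset, x)[0]

    def eta2_of(th):
        return spec.eta(th, dataset, x)[1]

    out = {}
    for name, fn in (("F1", eta1_of), ("F2", eta1_of), ("F3", eta2_of), ("F4", eta2_of)):
        sl = {"F1": "alpha", "F2": "beta", "F3": "gamma", "F4": "lambda"}[name]
        idx = np.arange(spec.n_params)[sls[sl]]
        if idx.size == 0:
            out[name] = np.zeros((dataset.n, 0))
            continue

        def restricted(sub, idx=idx):
            th = theta.copy()
            th[idx] = sub
            e = fn(th)
            return np.atleast_1d(e) * np.ones(dataset.n)

        out[name] = central_difference_jacobian(restricted, theta[idx])
    ranks = {}
    for name, F in out.items():
        ranks[name] = 0 if F.shape[1] == 0 else int(np.linalg.matrix_rank(F))
        if warn_rank and F.shape[1] > 0 and ranks[name] < F.shape[1]:
            warnings.warn(
                f"Jacobian {name} is rank deficient ({ranks[name]} < {F.shape[1]})",
                RuntimeWarning,
            )
    out["ranks"] = ranks
    return out


def precision_variability(phi) -> float:
    """Degree of precision variability delta = max phi_t / min phi_t
    (1 under constant precision)."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("empty precision vector")
    if np.any(phi <= 0.0):
        raise ValueError("phi must be positive")
    return float(phi.max() / phi.min())
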