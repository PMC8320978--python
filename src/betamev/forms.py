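"""Nonlinear predictor forms for the mean and precision submodels.

Each form describes the error-free part of a linear predictor,
``eta = free(z; a) + b * x`` where ``x`` is the (single, shared) error-prone
covariate entering linearly with coefficient ``b`` when the submodel uses it.

Built-in kinds
--------------
linear    a1 + a2 z1 + ... (intercept always included; 0 covariates = constant)
power     a1 + z ** a2               (requires z > 0)
rational  a1 + a2 z1 / (z1 + a3) + a4 z2   (Michaelis-type saturation in z1)
custom    caller-supplied evaluation + (optionally) analytic Jacobian
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class PredictorForm:
    """Base class; subclasses implement free() and free_jac()."""

    covariates: Tuple[str, ...]

    kind: str = "abstract"

    @property
    def n_free(self) -> int:  # pragma: no cover - interface
        raise NotImplementedError

    def free(self, a: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """Error-free part of eta; Z has one column per declared covariate."""
        raise NotImplementedError  # pragma: no cover

    def free_jac(self, a: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """(n, n_free) analytic Jacobian of free() w.r.t. the parameters."""
        raise NotImplementedError  # pragma: no cover

    def _check(self, a, Z):
        a = np.asarray(a, dtype=float)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != len(self.covariates):
            raise ValueError(
                f"{self.kind} form expects {len(self.covariates)} covariate "
                f"column(s), got {Z.shape[1]}"
            )
        if a.shape != (self.n_free,):
            raise ValueError(f"{self.kind} form expects {self.n_free} parameters, got {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite parameters")
        return a, Z


@dataclass(frozen=True)
class LinearForm(PredictorForm):
    kind: str = "linear"

    @property
    def n_free(self) -> int:
        return 1 + len(self.covariates)

    def free(self, a, Z):
        a, Z = self._check(a, Z)
        return a[0] + Z @ a[1:]

    def free_jac(self, a, Z):
        a, Z = self._check(a, Z)
        return np.column_stack([np.ones(Z.shape[0]), Z])


@dataclass(frozen=True)
class PowerForm(PredictorForm):
    """a1 + z ** a2 with a single positive covariate z."""

    kind: str = "power"

    def __post_init__(self):
        if len(self.covariates) != 1:
            raise ValueError("power form takes exactly one covariate")

    @property
    def n_free(self) -> int:
        return 2

    def free(self, a, Z):
        a, Z = self._check(a, Z)
        z = Z[:, 0]
        if np.any(z <= 0.0):
            raise ValueError("power form requires a strictly positive covariate")
        return a[0] + z ** a[1]

    def free_jac(self, a, Z):
        a, Z = self._check(a, Z)
        z = Z[:, 0]
        if np.any(z <= 0.0):
            raise ValueError("power form requires a strictly positive covariate")
        return np.column_stack([np.ones_like(z), z ** a[1] * np.log(z)])


@dataclass(frozen=True)
class RationalForm(PredictorForm):
    """a1 + a2 z1 / (z1 + a3) + a4 z2 (saturating effect of z1)."""

    kind: str = "rational"

    def __post_init__(self):
        if len(self.covariates) != 2:
            raise ValueError("rational form takes exactly two covariates (z1, z2)")

    @property
    def n_free(self) -> int:
        return 4

    def free(self, a, Z):
        a, Z = self._check(a, Z)
        z1, z2 = Z[:, 0], Z[:, 1]
        den = z1 + a[2]
        if np.any(den == 0.0):
            raise ValueError("rational form denominator z1 + a3 hit zero")
        return a[0] + a[1] * z1 / den + a[3] * z2

    def free_jac(self, a, Z):
        a, Z = self._check(a, Z)
        z1, z2 = Z[:, 0], Z[:, 1]
        den = z1 + a[2]
        return np.column_stack(
            [np.ones_like(z1), z1 / den, -a[1] * z1 / den**2, z2]
        )


@dataclass(frozen=True)
class CustomForm(PredictorForm):
    """Caller-supplied form: ``func(a, Z) -> eta_free``; declared parameter
    count keeps the packed order (alpha, beta, gamma, lambda) intact.  If no
    analytic Jacobian is supplied a central-difference one is used."""

    n_params: int = 0
    func: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    jac: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None
    kind: str = "custom"

    @property
    def n_free(self) -> int:
        return self.n_params

    def free(self, a, Z):
        a, Z = self._check(a, Z)
        return np.asarray(self.func(a, Z), dtype=float)

    def free_jac(self, a, Z):
        a, Z = self._check(a, Z)
        if self.jac is not None:
            return np.asarray(self.jac(a, Z), dtype=float)
        return central_difference_jacobian(lambda aa: self.func(aa, Z), a)


def central_difference_jacobian(f: Callable[[np.ndarray], np.ndarray], a: np.ndarray,
                                rel_step: Optional[float] = None) -> np.ndarray:
    """Central-difference Jacobian of a vector-valued f at a.

    Relative step defaults to cube-root machine epsilon (optimal for central
    differences of a smooth function).
    """
    a = np.asarray(a, dtype=float)
    h0 = rel_step if rel_step is not None else np.finfo(float).eps ** (1.0 / 3.0)
    cols = []
    for j in range(a.size):
        h = h0 * max(1.0, abs(a[j]))
        ap = a.copy(); ap[j] += h
        am = a.copy(); am[j] -= h
        cols.append((np.asarray(f(ap), float) - np.asarray(f(am), float)) / (2.0 * h))
    return np.column_stack(cols) if cols else np.zeros((np.asarray(f(a)).size, 0))


_FORM_KINDS = {"linear": LinearForm, "power": PowerForm, "rational": RationalForm}


def make_form(kind: str, covariates: Sequence[str], **kwargs) -> PredictorForm:
    if kind == "custom":
        return CustomForm(tuple(covariates), **kwargs)
    try:
        cls = _FORM_KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown form kind {kind!r}")
    return cls(tuple(covariates))
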