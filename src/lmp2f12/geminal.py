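"""Slater-type geminal correlation factor and the five two-electron operators.

The correlation factor is f12 = -(1/gamma) exp(-gamma r12). The integral
engine works with Gaussian kernels, so exp(-gamma r) is represented by a
6-term Gaussian-geminal expansion fitted by weighted least squares on
r in [0, 10] bohr. Derived operators reuse that expansion consistently:

* f12^2        = (1/gamma^2) exp(-2 gamma r12)  -> squared expansion
* (d1 f12)^2   = exp(-2 gamma r12)              -> gamma^2 * f12^2
* f12/r12      = -(1/gamma) exp(-gamma r12)/r12 -> gauss_r kernels
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

#: default geminal exponents per basis cardinal (bohr^-1)
GAMMA_BY_CARDINAL = {"DZ": 0.9, "TZ": 1.0, "QZ": 1.1}


class OperatorKind(str, Enum):
    coulomb = "coulomb"
    f12 = "f12"
    f12_squared = "f12_squared"
    f12_over_r12 = "f12_over_r12"
    grad_f12_squared = "grad_f12_squared"


@lru_cache(maxsize=None)
def _fit_stg(gamma: float, n_gauss: int = 6):
    """Fit exp(-gamma r) ~ sum_g c_g exp(-a_g r^2) on r in [0, 10] bohr.

    Returns (coefs, exps, max_abs_residual). Linear coefficients are solved
    exactly at each step of a log-exponent optimization; the residual is taken
    uniformly on a dense grid, so the irreducible error sits at the r=0 cusp
    (a Gaussian expansion has zero slope there).
    """
    r = np.linspace(0.0, 10.0, 800)
    w = np.ones_like(r)
    target = np.exp(-gamma * r)

    def coefs_for(al):
        g = np.exp(-np.outer(al, r ** 2))
        A = (g * w) @ g.T
        b = (g * w) @ target
        return np.linalg.solve(A + 1e-14 * np.eye(len(al)), b)

    def resid(logal):
        al = np.exp(logal)
        c = coefs_for(al)
        return (c @ np.exp(-np.outer(al, r ** 2)) - target) * np.sqrt(w)

    x0 = np.log(gamma ** 2 * np.geomspace(0.08, 110.0, n_gauss))
    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=4000)
    al = np.exp(sol.x)
    c = coefs_for(al)
    res = float(np.abs(c @ np.exp(-np.outer(al, r ** 2)) - target).max())
    order = np.argsort(al)
    return tuple(c[order]), tuple(al[order]), res


@dataclass(frozen=True)
class GeminalFactor:
    """Geminal exponent plus its Gaussian expansion of exp(-gamma r12)."""
    gamma: float
    coefs: tuple
    exps: tuple
    fit_residual: float
    fit_tolerance: float = 1e-2

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("geminal exponent must be positive")
        if self.fit_residual > self.fit_tolerance:
            raise ValueError(
                f"Gaussian-geminal fit residual {self.fit_residual:.2e} exceeds "
                f"tolerance {self.fit_tolerance:.2e}")

    @classmethod
    def from_gamma(cls, gamma: float, n_gauss: int = 6) -> "GeminalFactor":
        c, a, res = _fit_stg(float(gamma), n_gauss)
        return cls(float(gamma), c, a, res)

    def f12_value(self, r: np.ndarray) -> np.ndarray:
        """Pointwise value of the represented f12 (for diagnostics/tests)."""
        r = np.asarray(r, dtype=float)
        g = np.exp(-np.outer(self.exps, r ** 2))
        return -(1.0 / self.gamma) * np.asarray(self.coefs) @ g

    # ---- kernel-term lists consumed by the integral engine ----
    def _squared_expansion(self):
        c = np.asarray(self.coefs)
        a = np.asarray(self.exps)
        cc = np.outer(c, c).ravel()
        aa = np.add.outer(a, a).ravel()
        return cc, aa

    def kernel_terms(self, op: OperatorKind):
        if op == OperatorKind.coulomb:
            return [(1.0, "coulomb", None)]
        if op == OperatorKind.f12:
            return [(-c / self.gamma, "gauss", a)
                    for c, a in zip(self.coefs, self.exps)]
        if op == OperatorKind.f12_over_r12:
            return [(-c / self.gamma, "gauss_r", a)
                    for c, a in zip(self.coefs, self.exps)]
        cc, aa = self._squared_expansion()
        if op == OperatorKind.f12_squared:
            return [(c / self.gamma ** 2, "gauss", a) for c, a in zip(cc, aa)]
        if op == OperatorKind.grad_f12_squared:
            return [(c, "gauss", a) for c, a in zip(cc, aa)]
        raise ValueError(f"unknown operator {op}")


def make_geminal(basis_cardinal: str | None = None,
                 gamma: float | None = None) -> GeminalFactor:
    """Geminal for a basis cardinal (DZ/TZ/QZ) or an explicit gamma override."""
    if gamma is not None:
        return GeminalFactor.from_gamma(gamma)
    if basis_cardinal in GAMMA_BY_CARDINAL:
        return GeminalFactor.from_gamma(GAMMA_BY_CARDINAL[basis_cardinal])
    raise ValueError(
        f"unknown basis cardinal {basis_cardinal!r} and no explicit gamma given")
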