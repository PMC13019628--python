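"""Boys function and kernel derivative tables for Hermite (McMurchie-Davidson)
two-electron integrals.

Every two-electron kernel used here (1/r12, Gaussian geminals e^{-w r12^2},
and e^{-w r12^2}/r12) admits a closed-form fundamental integral Phi(R^2) for a
pair of s-type Hermite charge distributions. The engine only needs the
derivative table D_n = (d/dR^2)^n Phi; higher angular momenta follow from the
Hermite recurrence.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.special import gammainc, gammaln

_SQRT_PI = math.sqrt(math.pi)


def boys(nmax: int, t: np.ndarray) -> np.ndarray:
    """F_n(t) for n = 0..nmax; returns array (nmax+1,) + t.shape."""
    t = np.asarray(t, dtype=float)
    out = np.empty((nmax + 1,) + t.shape)
    small = t < 1e-13
    ts = np.where(small, 1.0, t)
    for n in range(nmax + 1):
        a = n + 0.5
        # F_n(t) = Gamma(a) * P(a, t) / (2 t^a)
        val = 0.5 * np.exp(gammaln(a) - a * np.log(ts)) * gammainc(a, ts)
        out[n] = np.where(small, 1.0 / (2 * n + 1) - t / (2 * n + 3), val)
    return out


def dn_coulomb(nmax: int, p: np.ndarray, q: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Derivative table for the Coulomb kernel 1/r12."""
    rho = p * q / (p + q)
    pref = 2.0 * math.pi ** 2.5 / (p * q * np.sqrt(p + q))
    f = boys(nmax, rho * r2)
    n = np.arange(nmax + 1).reshape((-1,) + (1,) * np.ndim(rho))
    return pref * (-rho) ** n * f


def dn_gauss(nmax: int, p: np.ndarray, q: np.ndarray, r2: np.ndarray, w: float) -> np.ndarray:
    """Derivative table for the Gaussian kernel e^{-w r12^2}."""
    denom = p * q + (p + q) * w
    theta = p * q * w / denom
    pref = math.pi ** 3 / denom ** 1.5
    base = pref * np.exp(-theta * r2)
    n = np.arange(nmax + 1).reshape((-1,) + (1,) * np.ndim(theta))
    return (-theta) ** n * base


def dn_gauss_r(nmax: int, p: np.ndarray, q: np.ndarray, r2: np.ndarray, w: float) -> np.ndarray:
    """Derivative table for the kernel e^{-w r12^2}/r12.

    Phi = C * exp(-eta R^2) * F_0(sigma R^2), with
    eta = rho w/(rho+w), sigma = rho^2/(rho+w), rho = pq/(p+q).
    """
    rho = p * q / (p + q)
    eta = rho * w / (rho + w)
    sigma = rho * rho / (rho + w)
    pref = (math.pi ** 2 / (p * q)) ** 1.5 * (2.0 / _SQRT_PI) * rho ** 1.5 / (rho + w)
    f = boys(nmax, sigma * r2)
    egauss = np.exp(-eta * r2)
    out = np.empty((nmax + 1,) + np.broadcast(p, q, r2).shape)
    for n in range(nmax + 1):
        acc = 0.0
        for k in range(n + 1):
            acc = acc + math.comb(n, k) * (-eta) ** (n - k) * (-sigma) ** k * f[k]
        out[n] = pref * egauss * acc
    return out


def dn_point_charge(nmax: int, p: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Derivative table for the one-electron Coulomb attraction kernel."""
    pref = 2.0 * math.pi / p
    f = boys(nmax, p * r2)
    n = np.arange(nmax + 1).reshape((-1,) + (1,) * np.ndim(p))
    return pref * (-p) ** n * f
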