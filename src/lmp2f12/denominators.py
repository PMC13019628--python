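"""Cholesky / Laplace factorization of orbital-energy denominators.

The Cauchy-like matrix D_{(ai),(bj)} = 1/(x_ai + x_bj) over positive
occupied->virtual gaps x_ai is factorized as D ~ sum_w e_w e_w^T. The factors
replace explicit energy denominators in all domain evaluations, which removes
the need for a canonical (diagonal-Fock) occupied index and uncouples the
domain equations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

CD_THRESHOLD = 1e-4   # hartree^-1, max diagonal residual


@dataclass
class OmegaVectors:
    mode: str                 # "CD" | "Laplace"
    vectors: np.ndarray       # (n_omega, n_composite)
    gaps: np.ndarray          # composite gaps x (n_composite,)
    threshold: float | None = None

    @property
    def n_omega(self) -> int:
        return self.vectors.shape[0]

    def reconstruct(self) -> np.ndarray:
        return np.einsum("wx,wy->xy", self.vectors, self.vectors)

    def max_diag_residual(self) -> float:
        d = 1.0 / (self.gaps[:, None] + self.gaps[None, :])
        return float(np.abs(d - self.reconstruct()).max())


def cd_denominator(gaps: np.ndarray, cd_threshold: float = CD_THRESHOLD) -> OmegaVectors:
    """Pivoted Cholesky of 1/(x_a+x_b) down to a diagonal residual threshold."""
    x = np.asarray(gaps, dtype=float).ravel()
    if np.any(x <= 0):
        raise ValueError("non-positive excitation gap: reference is not a "
                         "closed-shell ground state in this domain")
    n = len(x)
    d = 1.0 / (x[:, None] + x[None, :])
    diag = d.diagonal().copy()
    vecs = []
    for _ in range(n):
        p = int(np.argmax(diag))
        if diag[p] < cd_threshold:
            break
        col = d[:, p].copy()
        for v in vecs:
            col -= v * v[p]
        v = col / np.sqrt(col[p])
        vecs.append(v)
        diag = diag - v * v
    if not vecs:
        vecs = [d[:, 0] / np.sqrt(d[0, 0])]
    return OmegaVectors("CD", np.array(vecs), x, cd_threshold)


@dataclass
class LaplaceRule:
    points: np.ndarray
    weights: np.ndarray

    def vectors_for(self, gaps: np.ndarray) -> OmegaVectors:
        """Factor vectors (e_w)_x = sqrt(w_w) exp(-x t_w).

        The quadrature weight is split as w^{1/2} per factor so that the
        product of a bra and a ket vector reproduces w exp(-(x+y) t)."""
        x = np.asarray(gaps, dtype=float).ravel()
        v = np.sqrt(self.weights)[:, None] * np.exp(-np.outer(self.points, x))
        return OmegaVectors("Laplace", v, x)

    def eval_inverse(self, x: np.ndarray) -> np.ndarray:
        return np.einsum("w,wx->x", self.weights,
                         np.exp(-np.outer(self.points, np.asarray(x, float))))


def laplace_denominator(gap_min: float, gap_max: float, n_points: int) -> LaplaceRule:
    """Least-squares exponential quadrature for 1/x on [2 gap_min, 2 gap_max]."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not (0 < gap_min <= gap_max):
        raise ValueError("need 0 < gap_min <= gap_max")
    a, b = 2.0 * gap_min, 2.0 * gap_max
    if n_points == 1:
        # single exponential through the geometric midpoint; exact when a == b:
        # w e^{-x0 t} = 1/x0 with t = 1/x0 gives w = e/x0
        x0 = np.sqrt(a * b)
        return LaplaceRule(np.array([1.0 / x0]), np.array([np.exp(1.0) / x0]))
    xs = np.geomspace(a, b, max(60, 12 * n_points))
    x0 = np.sqrt(a * b)
    t0 = np.geomspace(0.05, 20.0, n_points) / x0
    w0 = np.gradient(t0) if n_points > 2 else np.full(n_points, 1.0 / x0)
    w0 = np.abs(w0) + 1e-3 / x0

    def resid(params):
        # clip to keep the optimizer's exploratory steps finite
        t = np.exp(np.clip(params[:n_points], -40.0, 40.0))
        w = np.exp(np.clip(params[n_points:], -40.0, 40.0))
        approx = np.einsum("w,wx->x", w, np.exp(-np.outer(t, xs)))
        return (approx - 1.0 / xs) * xs   # relative error

    sol = least_squares(resid, np.concatenate([np.log(t0), np.log(w0)]),
                        method="lm", xtol=1e-15, ftol=1e-15, max_nfev=20000)
    t = np.exp(np.clip(sol.x[:n_points], -40.0, 40.0))
    w = np.exp(np.clip(sol.x[n_points:], -40.0, 40.0))
    order = np.argsort(t)
    return LaplaceRule(t[order], w[order])


def apply_omega(j_block: np.ndarray, omega: OmegaVectors) -> np.ndarray:
    """Per-omega scaled fitting blocks J^w_{ai,P} = J_{ai,P} (e_w)_{ai}.

    j_block: (nv, no, P); omega composite index must equal nv*no in (a,i)
    row-major order. Returns (n_omega, nv, no, P).
    """
    nv, no, npfit = j_block.shape
    if omega.vectors.shape[1] != nv * no:
        raise ValueError("omega composite dimension does not match the block")
    e = omega.vectors.reshape(omega.n_omega, nv, no)
    return e[..., None] * j_block[None]
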