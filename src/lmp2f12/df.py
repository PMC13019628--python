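"""Density fitting: Coulomb-metric factorization, fitted coefficients J, and
robust-fitting coefficients K for non-Coulomb operators.

Fitted four-index reconstructions:
    (pq|rs)      ~ sum_P J_pq,P J_rs,P
    (pq|op|rs)   ~ sum_P (J_pq,P K_rs,P + K_pq,P J_rs,P)      (robust fitting)
The robust form makes the reconstruction error quadratic in the fitting-basis
incompleteness.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lapack, solve_triangular

from .basis import BasisSet
from .geminal import GeminalFactor, OperatorKind
from .integrals.twoelectron import three_center, two_center

PIVOT_DROP = 1e-10


@dataclass
class MetricFactor:
    """Cholesky factor of the (possibly pivot-conditioned) Coulomb metric."""
    L: np.ndarray            # (naux_kept, naux_kept) lower triangular
    kept: np.ndarray         # indices of retained auxiliary functions
    n_aux_full: int
    dropped: int = 0

    @property
    def naux(self) -> int:
        return len(self.kept)

    def reconstruct(self) -> np.ndarray:
        return self.L @ self.L.T

    def half_solve(self, x: np.ndarray) -> np.ndarray:
        """L^{-1} x for x with leading aux dimension (already restricted)."""
        return solve_triangular(self.L, x, lower=True)


def build_metric(aux: BasisSet | np.ndarray, terms=None) -> MetricFactor:
    """Pivoted-Cholesky factorization of the two-center Coulomb metric.

    Pivots below PIVOT_DROP x (largest diagonal) are discarded, which silently
    conditions near-linearly-dependent fitting sets.
    """
    if isinstance(aux, np.ndarray):
        v = np.array(aux, dtype=float)
    else:
        v = two_center(aux, terms or [(1.0, "coulomb", None)])
    n = v.shape[0]
    c, piv, rank, info = lapack.dpstrf(v, lower=1, tol=PIVOT_DROP * v.diagonal().max())
    if info < 0:
        raise ValueError("metric factorization failed")
    piv = piv - 1  # LAPACK is 1-based
    kept = piv[:rank]
    L = np.tril(c)[:rank, :rank]
    if np.any(L.diagonal() <= 0):
        raise ValueError("fitting metric is not positive definite")
    return MetricFactor(L=L, kept=kept, n_aux_full=n, dropped=n - rank)


@dataclass
class FittingBlock:
    """Three-index fitted coefficients for one operator over an orbital-pair set."""
    operator: OperatorKind
    J: np.ndarray                 # (n1, n2, naux_kept)
    K: np.ndarray | None = None   # robust partner, same shape

    def reconstruct(self, other: "FittingBlock | None" = None) -> np.ndarray:
        """Fitted four-index tensor (n1,n2,m1,m2)."""
        o = other or self
        if self.K is None:
            return np.einsum("pqP,rsP->pqrs", self.J, o.J)
        return (np.einsum("pqP,rsP->pqrs", self.J, o.K)
                + np.einsum("pqP,rsP->pqrs", self.K, o.J))


def fit_J(x3c: np.ndarray, metric: MetricFactor,
          operator: OperatorKind = OperatorKind.coulomb) -> FittingBlock:
    """Fitted coefficients J = (pq|Q) L^{-T} from three-center Coulomb integrals."""
    n1, n2, naux = x3c.shape
    if naux != metric.n_aux_full:
        raise ValueError("three-center tensor does not match the metric")
    flat = x3c.reshape(-1, naux)[:, metric.kept]
    j = solve_triangular(metric.L, flat.T, lower=True).T
    return FittingBlock(operator=operator, J=j.reshape(n1, n2, metric.naux))


def fit_K(x3c_op: np.ndarray, v2c_op: np.ndarray, jblock: FittingBlock,
          metric: MetricFactor, operator: OperatorKind) -> FittingBlock:
    """Robust-fitting partner coefficients K for a non-Coulomb operator."""
    if operator == OperatorKind.coulomb:
        raise ValueError("robust fitting applies to non-Coulomb operators only")
    n1, n2, naux = x3c_op.shape
    flat = x3c_op.reshape(-1, naux)[:, metric.kept]
    k1 = solve_triangular(metric.L, flat.T, lower=True).T
    w = v2c_op[np.ix_(metric.kept, metric.kept)]
    m = solve_triangular(metric.L, w, lower=True)
    m = solve_triangular(metric.L, m.T, lower=True).T  # L^{-1} W L^{-T}
    j = jblock.J.reshape(-1, metric.naux)
    k = k1 - 0.5 * j @ m.T
    return FittingBlock(operator=operator,
                        J=jblock.J,
                        K=k.reshape(n1, n2, metric.naux))


def fitted_blocks(bra_c: np.ndarray, ket_c: np.ndarray, x3c_ao: np.ndarray,
                  metric: MetricFactor) -> np.ndarray:
    """Transform AO three-center integrals to MO pairs and fit: J_{pq,P}.

    bra_c: (nao1, n1) MO coefficients for the first index;
    ket_c: (nao2, n2) for the second.
    """
    half = np.tensordot(bra_c.T, x3c_ao, axes=([1], [0]))
    full = np.tensordot(ket_c.T, half, axes=([1], [1])).transpose(1, 0, 2)
    return fit_J(full, metric).J
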