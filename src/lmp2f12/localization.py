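"""Boys localization of occupied orbitals and projected atomic orbitals (PAOs).

Core and valence occupied blocks are localized separately; the PAOs provide a
redundant, atom-tagged representation of the virtual space.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals.mcmurchie import dipole, overlap
from .reference import RestrictedReference

BOYS_CONV = 1e-8
BOYS_MAX_SWEEPS = 500
PAO_DROP = 1e-8


class LocalizationError(RuntimeError):
    pass


@dataclass
class LocalizedSet:
    kind: str                      # "core" | "valence"
    coefficients: np.ndarray       # AO x LMO
    boys_objective: float

    @property
    def n(self) -> int:
        return self.coefficients.shape[1]


@dataclass
class PAOSet:
    coefficients: np.ndarray       # AO x PAO (unit S-norm columns)
    parent_atom: np.ndarray        # atom index per PAO

    @property
    def n(self) -> int:
        return self.coefficients.shape[1]


def boys_objective(c: np.ndarray, dip: np.ndarray) -> float:
    cent = np.einsum("dpq,pi,qi->di", dip, c, c)
    return float(np.sum(cent * cent))


def boys_localize(block: np.ndarray, overlap_ao: np.ndarray,
                  dipole_ints: np.ndarray, kind: str = "valence") -> LocalizedSet:
    """Maximize sum_i |<i|r|i>|^2 by pairwise Jacobi rotations.

    Deterministic: row-major sweep order, analytic 2x2 rotations, sign fixing
    of the converged orbitals.
    """
    c = np.array(block, dtype=float)
    n = c.shape[1]
    if n <= 1:
        return LocalizedSet(kind, _fix_signs(c), boys_objective(c, dipole_ints))
    # dipole matrices in the current MO basis, updated in place
    d = np.einsum("dpq,pi,qj->dij", dipole_ints, c, c)
    obj = float(np.sum(d.diagonal(axis1=1, axis2=2) ** 2))
    for sweep in range(BOYS_MAX_SWEEPS):
        max_angle = 0.0
        for s in range(n - 1):
            for t in range(s + 1, n):
                dss = d[:, s, s]
                dtt = d[:, t, t]
                dst = d[:, s, t]
                a = float(np.sum(dst ** 2 - 0.25 * (dss - dtt) ** 2))
                b = float(np.sum(dst * (dss - dtt)))
                if a * a + b * b < 1e-30:
                    continue
                theta = 0.25 * np.arctan2(b, -a)
                if abs(theta) < 1e-12:
                    continue
                max_angle = max(max_angle, abs(theta))
                cs, sn = np.cos(theta), np.sin(theta)
                for mats in (c,):
                    ms, mt = mats[:, s].copy(), mats[:, t].copy()
                    mats[:, s] = cs * ms + sn * mt
                    mats[:, t] = -sn * ms + cs * mt
                for dd in d:
                    rs, rt = dd[s].copy(), dd[t].copy()
                    dd[s] = cs * rs + sn * rt
                    dd[t] = -sn * rs + cs * rt
                    cs_, ct_ = dd[:, s].copy(), dd[:, t].copy()
                    dd[:, s] = cs * cs_ + sn * ct_
                    dd[:, t] = -sn * cs_ + cs * ct_
        new_obj = float(np.sum(d.diagonal(axis1=1, axis2=2) ** 2))
        if new_obj < obj - 1e-10:
            raise LocalizationError("Boys objective decreased during a sweep")
        obj = new_obj
        if max_angle < BOYS_CONV:
            return LocalizedSet(kind, _fix_signs(c), obj)
    raise LocalizationError(
        f"Boys localization did not converge in {BOYS_MAX_SWEEPS} sweeps "
        f"(objective {obj:.10f})")


def _fix_signs(c: np.ndarray) -> np.ndarray:
    if c.shape[1] == 0:
        return c
    idx = np.argmax(np.abs(c), axis=0)
    signs = np.sign(c[idx, np.arange(c.shape[1])])
    signs[signs == 0] = 1.0
    return c * signs


def localize_core_and_valence(ref: RestrictedReference, dipole_ints=None):
    """Boys-localize core and valence occupied blocks separately."""
    if dipole_ints is None:
        dipole_ints = dipole(ref.basis)
    s = ref.overlap_ao
    core = boys_localize(ref.c_occ[:, :ref.n_core], s, dipole_ints, "core")
    val = boys_localize(ref.c_occ[:, ref.n_core:], s, dipole_ints, "valence")
    return core, val


def lmo_centroids(lset: LocalizedSet, dipole_ints: np.ndarray) -> np.ndarray:
    return np.einsum("dpq,pi,qi->id", dipole_ints, lset.coefficients,
                     lset.coefficients)


def build_paos(ref: RestrictedReference) -> PAOSet:
    """One PAO per AO: p_mu = (1 - sum_i |i><i| S) chi_mu, dropped if its
    S-norm falls below 1e-8, normalized otherwise."""
    s = ref.overlap_ao
    cocc = ref.c_occ
    proj = np.eye(ref.nao) - cocc @ (cocc.T @ s)
    atom_of = ref.basis.atom_of_function()
    norms2 = np.einsum("mi,mn,ni->i", proj, s, proj)
    keep = norms2 > PAO_DROP ** 2
    coeff = proj[:, keep] / np.sqrt(norms2[keep])
    return PAOSet(coefficients=_fix_signs(coeff), parent_atom=atom_of[keep])
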