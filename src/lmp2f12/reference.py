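"""Validated restricted HF reference and semicanonicalization utilities."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

ORTHO_REJECT = 1e-6
LINDEP_DROP = 1e-7


class ReferenceError(ValueError):
    pass


@dataclass
class RestrictedReference:
    mo_coefficients: np.ndarray
    orbital_energies: np.ndarray
    fock_ao: np.ndarray
    overlap_ao: np.ndarray
    n_core: int
    n_occ: int
    nuclear_repulsion: float
    hf_energy: float
    extras: dict = field(default_factory=dict)

    @property
    def nao(self) -> int:
        return self.mo_coefficients.shape[0]

    @property
    def nmo(self) -> int:
        return self.mo_coefficients.shape[1]

    @property
    def n_valence(self) -> int:
        return self.n_occ - self.n_core

    @property
    def c_occ(self) -> np.ndarray:
        return self.mo_coefficients[:, :self.n_occ]

    @property
    def c_virt(self) -> np.ndarray:
        return self.mo_coefficients[:, self.n_occ:]

    @property
    def molecule(self):
        return self.extras.get("molecule")

    @property
    def basis(self):
        return self.extras.get("basis")


def load_reference(payload: dict) -> RestrictedReference:
    """Validate a provider payload and return a reference object.

    Rejects payloads whose MO set is not S-orthonormal (beyond 1e-6) or whose
    dimensions are inconsistent.
    """
    required = ["mo_coefficients", "orbital_energies", "fock_ao", "overlap_ao",
                "n_core", "n_occ", "nuclear_repulsion", "hf_energy"]
    missing = [k for k in required if k not in payload]
    if missing:
        raise ReferenceError(f"payload missing fields: {missing}")
    c = np.asarray(payload["mo_coefficients"], dtype=float)
    s = np.asarray(payload["overlap_ao"], dtype=float)
    f = np.asarray(payload["fock_ao"], dtype=float)
    e = np.asarray(payload["orbital_energies"], dtype=float)
    nao, nmo = c.shape
    if s.shape != (nao, nao) or f.shape != (nao, nao) or len(e) != nmo:
        raise ReferenceError("payload dimensions are inconsistent")
    dev = np.abs(c.T @ s @ c - np.eye(nmo)).max()
    if dev > ORTHO_REJECT:
        raise ReferenceError(
            f"MO set not S-orthonormal: max |C^T S C - 1| = {dev:.2e}")
    n_core = int(payload["n_core"])
    n_occ = int(payload["n_occ"])
    if not (0 <= n_core <= n_occ <= nmo):
        raise ReferenceError("inconsistent orbital counts")
    extras = {k: v for k, v in payload.items() if k not in required}
    return RestrictedReference(
        mo_coefficients=c, orbital_energies=e, fock_ao=f, overlap_ao=s,
        n_core=n_core, n_occ=n_occ,
        nuclear_repulsion=float(payload["nuclear_repulsion"]),
        hf_energy=float(payload["hf_energy"]), extras=extras)


def semicanonicalize(orbital_block: np.ndarray, fock_ao: np.ndarray,
                     overlap_ao: np.ndarray, drop: float = LINDEP_DROP):
    """Orthonormalize a span and diagonalize the Fock matrix within it.

    Symmetric (Loewdin) orthogonalization in the S metric; near-dependent
    directions (overlap eigenvalues < drop) are discarded. Returns the rotated
    S-orthonormal block and its pseudo-energies, ordered ascending with ties
    broken by the original column index. Signs are fixed so the largest
    coefficient of each column is positive.
    """
    c = np.asarray(orbital_block, dtype=float)
    if c.size == 0 or c.shape[1] == 0:
        return c.reshape(c.shape[0], 0), np.zeros(0)
    sm = c.T @ overlap_ao @ c
    ev, u = sla.eigh(sm)
    keep = ev > drop * max(ev.max(), 1.0)
    x = u[:, keep] / np.sqrt(ev[keep])
    cortho = c @ x
    fm = cortho.T @ fock_ao @ cortho
    eps, v = sla.eigh(fm)
    # deterministic tie-break: stable argsort on (energy, original index proxy)
    order = np.argsort(eps, kind="stable")
    eps = eps[order]
    v = v[:, order]
    out = cortho @ v
    # sign convention
    idx = np.argmax(np.abs(out), axis=0)
    signs = np.sign(out[idx, np.arange(out.shape[1])])
    signs[signs == 0] = 1.0
    return out * signs, eps
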