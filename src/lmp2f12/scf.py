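"""Spin-restricted Hartree-Fock provider (density-fitted J/K, DIIS).

The correlation method consumes a converged RHF reference through the payload
contract of `lmp2f12.reference`; this module is the built-in provider used by
the driver and the test fixtures.
"""
from __future__ import annotations

import numpy as np
import scipy.linalg as sla

from .basis import BasisSet, autoaux, build_basis
from .df import build_metric, fit_J
from .integrals.mcmurchie import kinetic, nuclear_attraction, overlap
from .integrals.twoelectron import three_center
from .molecule import Molecule


class SCFError(RuntimeError):
    pass


def df_rhf(molecule: Molecule, basis: BasisSet, aux: BasisSet | None = None,
           conv: float = 1e-9, max_iter: int = 120, verbose: bool = False):
    """Converge a closed-shell DF-RHF and return the provider payload dict."""
    if molecule.n_electrons % 2:
        raise SCFError("odd electron count: only closed shells are supported")
    nocc = molecule.n_electrons // 2
    aux = aux or autoaux(basis)
    s = overlap(basis)
    h = kinetic(basis) + nuclear_attraction(basis)
    from .integrals.twoelectron import two_center
    v2c = two_center(aux, [(1.0, "coulomb", None)])
    metric = build_metric(v2c)
    x3c = three_center(basis, basis, aux, [(1.0, "coulomb", None)])
    b = fit_J(x3c, metric).J            # (nao, nao, naux)

    e_nuc = molecule.nuclear_repulsion()
    # symmetric orthogonalization with conditioning
    ev, u = sla.eigh(s)
    keep = ev > 1e-8 * ev.max()
    x = u[:, keep] / np.sqrt(ev[keep])

    def fock(dm, cocc):
        gamma = np.einsum("pqP,qp->P", b, dm)
        j = np.einsum("pqP,P->pq", b, gamma)
        bo = np.tensordot(cocc.T, b, axes=([1], [0]))   # (nocc, nao, naux)
        k = np.einsum("ipP,iqP->pq", bo, bo)
        return h + 2.0 * j - k

    # core-Hamiltonian guess
    e, cprime = sla.eigh(x.T @ h @ x)
    c = x @ cprime
    cocc = c[:, :nocc]
    dm = cocc @ cocc.T
    energy = 0.0
    diis_f, diis_r = [], []
    for it in range(max_iter):
        f = fock(dm, cocc)
        e_el = float(np.sum(dm * (h + f)))
        new_energy = e_el + e_nuc
        resid = x.T @ (f @ dm @ s - s @ dm @ f) @ x
        err = np.abs(resid).max()
        if verbose:
            print(f"  scf iter {it:3d}  E={new_energy:.12f}  |FDS-SDF|={err:.2e}")
        if err < conv and it > 0:
            mo_e, cp = sla.eigh(x.T @ f @ x)
            c = x @ cp
            return _payload(molecule, basis, aux, s, f, c, mo_e, nocc,
                            new_energy, e_nuc, metric, b, x3c, v2c)
        diis_f.append(f)
        diis_r.append(resid)
        if len(diis_f) > 8:
            diis_f.pop(0)
            diis_r.pop(0)
        if len(diis_f) > 1:
            m = len(diis_f)
            bm = -np.ones((m + 1, m + 1))
            bm[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    bm[i, j] = np.sum(diis_r[i] * diis_r[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                w = np.linalg.solve(bm, rhs)[:m]
                f = sum(wi * fi for wi, fi in zip(w, diis_f))
            except np.linalg.LinAlgError:
                pass
        mo_e, cp = sla.eigh(x.T @ f @ x)
        c = x @ cp
        cocc = c[:, :nocc]
        dm = cocc @ cocc.T
        energy = new_energy
    raise SCFError(f"SCF did not converge in {max_iter} iterations")


def _payload(molecule, basis, aux, s, f, c, mo_e, nocc, e_hf, e_nuc, metric, b3,
             x3c, v2c):
    return {
        "mo_coefficients": c,
        "orbital_energies": mo_e,
        "fock_ao": f,
        "overlap_ao": s,
        "n_core": molecule.n_core,
        "n_occ": nocc,
        "nuclear_repulsion": e_nuc,
        "hf_energy": e_hf,
        # carried conveniences (not part of the minimal contract)
        "molecule": molecule,
        "basis": basis,
        "aux_basis": aux,
        "metric": metric,
        "b3c": b3,
        "ao3c": x3c,
        "aux_metric_raw": v2c,
    }


def rhf_reference(molecule: Molecule, basis_name: str = "svp-d",
                  aux: BasisSet | None = None, **kw):
    """Convenience: build basis, run DF-RHF, return a validated reference."""
    from .reference import load_reference
    basis = build_basis(molecule, basis_name)
    return load_reference(df_rhf(molecule, basis, aux=aux, **kw))
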