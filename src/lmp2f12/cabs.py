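"""Complementary auxiliary basis (CABS) spaces and the CABS singles correction.

The RI space used by the explicitly correlated terms is the union of the MO
space (occupied + virtual) and a complementary block built from CABS source
functions with the MO space projected out. A second, projected-AO block fills
the gap between the MO span and the AO span. Spaces are constructed globally
(canonical path) or per extended domain (local path).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .basis import BasisSet, cabs_source
from .df import MetricFactor, fit_J
from .integrals.mcmurchie import kinetic, nuclear_attraction, overlap
from .integrals.twoelectron import three_center
from .reference import RestrictedReference

CABS_LOWDIN_DROP = 1e-7
AUG_LOWDIN_DROP = 1e-4


@dataclass
class JointSpace:
    """AO+CABS function space with overlap/Fock matrices and DF tensors."""
    basis: BasisSet              # joint basis (orbital shells first)
    nao: int                     # leading orbital-basis functions
    s: np.ndarray                # joint overlap
    fock: np.ndarray             # joint Fock (occupied HF density)
    b3c: np.ndarray              # fitted (xy|P) over joint pairs (global metric)
    kin: np.ndarray | None = None  # joint kinetic-energy matrix

    @property
    def ncabs(self) -> int:
        return self.basis.nbf - self.nao


def build_joint_space(ref: RestrictedReference,
                      cabs_basis: BasisSet | None = None) -> JointSpace:
    """Assemble the AO+CABS basis and the Fock matrix in it."""
    basis = ref.basis
    cabs = cabs_basis or cabs_source(basis)
    joint = basis + cabs
    s = overlap(joint)
    tkin = kinetic(joint)
    h = tkin + nuclear_attraction(joint, ref.molecule)
    aux = ref.extras["aux_basis"]
    metric = ref.extras["metric"]
    x3 = three_center(joint, joint, aux, [(1.0, "coulomb", None)])
    b = fit_J(x3, metric).J
    nao = basis.nbf
    cocc = ref.c_occ
    dm = cocc @ cocc.T
    gamma = np.einsum("pqP,pq->P", b[:nao, :nao], dm)
    jmat = np.einsum("xyP,P->xy", b, gamma)
    # exchange: K_xy = sum_{i,P} B_{x i P} B_{y i P}, B_{x i P} = sum_mu b[x,mu,P] C_mu,i
    bxi = np.einsum("xmP,mi->xiP", b[:, :nao], cocc, optimize=True)
    kmat = np.einsum("xiP,yiP->xy", bxi, bxi, optimize=True)
    f = h + 2.0 * jmat - kmat
    return JointSpace(basis=joint, nao=nao, s=s, fock=f, b3c=b, kin=tkin)


@dataclass
class ComplementarySpace:
    """Orthonormal complementary block and the full RI orbital set.

    All coefficient matrices are over the joint (AO+CABS) function space.
    ri = [occupied | virtual | complementary], S-orthonormal.
    """
    c_comp: np.ndarray
    c_ri: np.ndarray
    n_occ: int
    n_virt: int
    n_aug: int                   # how many columns came from projected AOs

    @property
    def n_comp(self) -> int:
        return self.c_comp.shape[1]

    @property
    def slices(self):
        o = slice(0, self.n_occ)
        v = slice(self.n_occ, self.n_occ + self.n_virt)
        c = slice(self.n_occ + self.n_virt, self.n_occ + self.n_virt + self.n_comp)
        return o, v, c


def build_complementary(joint: JointSpace, c_occ: np.ndarray,
                        c_virt: np.ndarray,
                        cabs_function_idx: np.ndarray | None = None,
                        aug_ao_idx: np.ndarray | None = None) -> ComplementarySpace:
    """Construct the complementary block of an RI space.

    c_occ / c_virt: S-orthonormal MO blocks over the *joint* function space
    (zero CABS rows for AO-expanded orbitals). cabs_function_idx selects the
    CABS functions admitted (CABS domain); aug_ao_idx the AO functions used
    for the gap-filling augmentation block (defaults: all).
    """
    s = joint.s
    n = s.shape[0]
    nao = joint.nao
    if cabs_function_idx is None:
        cabs_function_idx = np.arange(nao, n)
    if aug_ao_idx is None:
        aug_ao_idx = np.arange(nao)
    cmo = np.concatenate([c_occ, c_virt], axis=1)

    def project_out(cols_idx, block):
        cols = np.zeros((n, len(cols_idx)))
        cols[cols_idx, np.arange(len(cols_idx))] = 1.0
        return cols - block @ (block.T @ s[:, cols_idx])

    def lowdin(cols, drop):
        if cols.shape[1] == 0:
            return cols
        sm = cols.T @ s @ cols
        ev, u = sla.eigh(sm)
        keep = ev > drop
        return cols @ (u[:, keep] / np.sqrt(ev[keep]))

    comp = lowdin(project_out(cabs_function_idx, cmo), CABS_LOWDIN_DROP)
    # augmentation: projected AOs fill the gap between MO and AO spans
    aug = project_out(aug_ao_idx, cmo)
    aug = lowdin(aug, AUG_LOWDIN_DROP)
    # keep the union orthonormal: remove the part already spanned by comp
    if comp.shape[1] and aug.shape[1]:
        aug = aug - comp @ (comp.T @ s @ aug)
        aug = lowdin(aug, CABS_LOWDIN_DROP)
    naug = aug.shape[1]
    c_comp = np.concatenate([comp, aug], axis=1) if naug else comp
    c_ri = np.concatenate([cmo, c_comp], axis=1)
    return ComplementarySpace(c_comp=c_comp, c_ri=c_ri,
                              n_occ=c_occ.shape[1], n_virt=c_virt.shape[1],
                              n_aug=naug)


def cabs_singles(ref: RestrictedReference, joint: JointSpace,
                 comp: ComplementarySpace) -> float:
    """Second-order singles correction to the HF energy.

    Singles excitations go from occupied orbitals into the virtual +
    complementary space; with a canonical reference the occupied-virtual Fock
    block vanishes (Brillouin) and only CABS couplings contribute, but the
    virtual block still enters the denominator matrix.
    """
    o, v, c = comp.slices
    f_ri = comp.c_ri.T @ joint.fock @ comp.c_ri
    na = comp.n_virt + comp.n_comp
    faa = f_ri[comp.n_occ:, comp.n_occ:]
    e = 0.0
    eps_occ = np.diag(f_ri)[:comp.n_occ]
    for i in range(comp.n_occ):
        vi = f_ri[comp.n_occ:, i]
        m = faa - eps_occ[i] * np.eye(na)
        e -= float(vi @ np.linalg.solve(m, vi))
    return e
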