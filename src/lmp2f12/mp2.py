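"""Canonical DF-MP2 and the local MP2 correlation energy.

The local method sums per-orbital extended-domain contributions evaluated with
denominator-free (Cholesky/Laplace) amplitudes plus multipole or pair-domain
energies for the LMO pairs outside every extended domain.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .denominators import OmegaVectors, apply_omega, cd_denominator
from .df import MetricFactor, fit_J
from .domains import DomainBuilder, ExtendedDomain, PairClassification, PrimaryDomain
from .reference import RestrictedReference


@dataclass
class EnergyReport:
    mode: str
    e_hf: float
    e_corr: float | None = None
    opposite_spin: float | None = None
    same_spin: float | None = None
    per_orbital: dict = field(default_factory=dict)     # i -> dE_i (ED)
    pair_contributions: dict = field(default_factory=dict)  # (i,j) -> dE_ij
    distant_pair_energy: float | None = None
    e_f12: float | None = None
    f12_terms: dict = field(default_factory=dict)       # B/X/C/V sums
    cabs_singles: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def total_energy(self) -> float:
        tot = self.e_hf + (self.e_corr or 0.0)
        if self.e_f12:
            tot += self.e_f12
        if self.cabs_singles:
            tot += self.cabs_singles
        return tot

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "e_hf": self.e_hf,
            "e_corr": self.e_corr,
            "opposite_spin": self.opposite_spin,
            "same_spin": self.same_spin,
            "per_orbital": {str(k): v for k, v in self.per_orbital.items()},
            "pair_contributions": {f"{i},{j}": v for (i, j), v
                                   in self.pair_contributions.items()},
            "distant_pair_energy": self.distant_pair_energy,
            "e_f12": self.e_f12,
            "f12_terms": dict(self.f12_terms) or None,
            "cabs_singles": self.cabs_singles,
            "total_energy": self.total_energy,
        }


def canonical_mp2(ref: RestrictedReference, j_ov: np.ndarray) -> EnergyReport:
    """Canonical (frozen-core) DF-MP2 with explicit denominators.

    j_ov: fitted coefficients J_{ia,P} over (correlated occupied, virtual).
    """
    no = ref.n_valence
    eo = ref.orbital_energies[ref.n_core:ref.n_occ]
    ev = ref.orbital_energies[ref.n_occ:]
    if j_ov.shape[0] != no or j_ov.shape[1] != len(ev):
        raise ValueError("fitting block shape mismatch")
    g = np.einsum("iaP,jbP->iajb", j_ov, j_ov, optimize=True)
    denom = (eo[:, None, None, None] - ev[None, :, None, None]
             + eo[None, None, :, None] - ev[None, None, None, :])
    t = g / denom
    e_os = float(np.einsum("iajb,iajb->", g, t, optimize=True))
    e_ss = float(np.einsum("iajb,iajb->", g - g.transpose(0, 3, 2, 1), t,
                           optimize=True))
    per_orb = {}
    contr = (2.0 * g - g.transpose(0, 3, 2, 1)) * t
    for i in range(no):
        per_orb[i] = float(contr[i].sum())
    return EnergyReport(mode="canonical-MP2", e_hf=ref.hf_energy,
                        e_corr=e_os + e_ss, opposite_spin=e_os, same_spin=e_ss,
                        per_orbital=per_orb)


# ---------------------------------------------------------------------------
# Local path
# ---------------------------------------------------------------------------

def local_fitting_blocks(ref: RestrictedReference, ed: ExtendedDomain,
                         aux_basis, metric_cache=None):
    """(a~ i~|P) fitted coefficients in the ED with its local fitting domain.

    Uses the global AO three-center tensor restricted to the local auxiliary
    functions (those on PCD atoms), refitted with the local metric. Returns
    (j_vo (nv, no_ed, P_loc), local metric, aux function indices).
    """
    b3c = ref.extras.get("ao3c")
    if b3c is None:
        raise ValueError("reference lacks the AO three-center Coulomb tensor")
    aux_idx = aux_basis.functions_on_atoms(ed.pcd_atoms)
    v2c = ref.extras["aux_metric_raw"]
    from .df import build_metric
    key = tuple(aux_idx.tolist())
    if metric_cache is not None and key in metric_cache:
        metric = metric_cache[key]
    else:
        metric = build_metric(v2c[np.ix_(aux_idx, aux_idx)])
        if metric_cache is not None:
            metric_cache[key] = metric
    x = b3c[:, :, aux_idx]
    half = np.tensordot(ed.c_virt.T, x, axes=([1], [0]))
    full = np.tensordot(half, ed.c_occ_pseudo, axes=([1], [0]))
    full = full.transpose(0, 2, 1)              # (nv, no_ed, naux_loc)
    jb = fit_J(full, metric)
    return jb.J, metric, aux_idx


def ed_mp2_contribution(ed: ExtendedDomain, omega: OmegaVectors,
                        j_vo: np.ndarray) -> float:
    """MP2 correlation contribution of the central LMO of an ED (Eqs. of the
    denominator-free domain algorithm)."""
    nv, no, np_ = j_vo.shape
    if omega.vectors.shape[1] != nv * no:
        raise ValueError("omega vectors incompatible with the ED block")
    jw = apply_omega(j_vo, omega)              # (nw, nv, no, P)
    jw_cmo = np.einsum("wvoP,o->wvP", jw, ed.w_cmo)
    # t_{i j~}^{a~ b~} = - sum_w J^w_{a i} J^w_{b j~}
    t = -np.einsum("wvP,wboP->vbo", jw_cmo, jw, optimize=True)
    j_cmo = np.einsum("voP,o->vP", j_vo, ed.w_cmo)
    g_d = np.einsum("aP,boP->abo", j_cmo, j_vo, optimize=True)   # (a i | b j~)
    g_x = np.einsum("aoP,bP->abo", j_vo, j_cmo, optimize=True)   # (a j~ | b i)
    return float(np.einsum("abo,abo->", 2.0 * g_d - g_x, t, optimize=True))


def ed_amplitudes_explicit(ed: ExtendedDomain, j_vo: np.ndarray) -> np.ndarray:
    """Explicit-denominator amplitudes t_{i j~}^{a~ b~} (oracle for the
    factorized route; small domains only)."""
    nv, no, _ = j_vo.shape
    gaps = (ed.eps_virt[:, None] - ed.eps_occ[None, :]).ravel()
    g = np.einsum("aiP,bjP->aibj", j_vo, j_vo, optimize=True)
    d = -(gaps.reshape(nv, no)[:, :, None, None]
          + gaps.reshape(nv, no)[None, None, :, :])
    t_full = g / d
    return np.einsum("aibj,i->abj", t_full, ed.w_cmo)


def pair_domain_mp2(ref: RestrictedReference, builder: DomainBuilder,
                    i: int, j: int, pd_i: PrimaryDomain, pd_j: PrimaryDomain,
                    metric: MetricFactor,
                    b3c_val: np.ndarray | None = None) -> float:
    """Opposite-spin-only pair energy in the union pair domain P_ij.

    b3c_val: optional precomputed fitted coefficients J_{mu i,P} with the
    occupied index already in the valence-LMO basis (shape nval, nao, P);
    providing it keeps the per-pair cost independent of system size.
    """
    if i == j:
        raise ValueError("pair energy requires two distinct LMOs")
    atoms = sorted(set(pd_i.atoms) | set(pd_j.atoms))
    funcs = ref.basis.functions_on_atoms(atoms)
    pao_ids = np.nonzero(np.isin(builder.paos.parent_atom, atoms))[0]
    occ_all = np.concatenate([builder.core.coefficients,
                              builder.valence.coefficients], axis=1)
    from .domains import _truncate_project_canonicalize
    c_virt, eps_virt = _truncate_project_canonicalize(
        builder.paos.coefficients[:, pao_ids], funcs, occ_all,
        ref.overlap_ao, ref.fock_ao)
    if c_virt.shape[1] == 0:
        return 0.0
    ci = builder.valence.coefficients[:, i]
    cj = builder.valence.coefficients[:, j]
    if b3c_val is None:
        b3c_val = np.tensordot(builder.valence.coefficients.T,
                               ref.extras["b3c"], axes=([1], [0]))
    cvf = c_virt[funcs]
    jai = np.tensordot(cvf.T, b3c_val[i][funcs], axes=([1], [0]))
    jbj = np.tensordot(cvf.T, b3c_val[j][funcs], axes=([1], [0]))
    g = jai @ jbj.T
    fii = float(ci @ ref.fock_ao @ ci)
    fjj = float(cj @ ref.fock_ao @ cj)
    d = fii + fjj - eps_virt[:, None] - eps_virt[None, :]
    return float(2.0 * np.sum(g * g / d))


def assemble_lmp2(ref: RestrictedReference, ed_contributions: dict,
                  classification: PairClassification,
                  pair_energies: dict) -> EnergyReport:
    """Combine ED orbital contributions with the distant-pair (primed) sum.

    ed_contributions: i -> dE_i; pair_energies: (i,j) i<j -> value for pairs
    outside every ED (i.e. non-strong pairs).
    """
    strong = classification.strong
    for p in pair_energies:
        if p in strong:
            raise ValueError(f"pair {p} is inside an ED and in the primed sum")
    for p in strong:
        if p in pair_energies:
            raise ValueError(f"strong pair {p} double-counted")
    distant = float(sum(pair_energies.values()))
    e_corr = float(sum(ed_contributions.values())) + distant
    return EnergyReport(mode="LMP2", e_hf=ref.hf_energy, e_corr=e_corr,
                        per_orbital=dict(ed_contributions),
                        pair_contributions=dict(pair_energies),
                        distant_pair_energy=distant)
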