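"""High-level pipelines: canonical MP2(-F12) and local MP2(-F12) runs."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import autoaux, build_basis, basis_cardinal, cabs_source
from .denominators import CD_THRESHOLD, cd_denominator, laplace_denominator
from .df import fit_J
from .domains import DomainBuilder, DomainConfig
from .integrals.mcmurchie import dipole
from .localization import build_paos, localize_core_and_valence
from .mp2 import (EnergyReport, assemble_lmp2, canonical_mp2,
                  ed_mp2_contribution, local_fitting_blocks, pair_domain_mp2)
from .reference import RestrictedReference


@dataclass
class LocalContext:
    """Everything derived from a reference that the local methods reuse."""
    ref: RestrictedReference
    config: DomainConfig
    dip: np.ndarray
    builder: DomainBuilder
    pds: list
    classification: object
    eds: dict                      # valence LMO index -> ExtendedDomain

    @property
    def n_valence(self) -> int:
        return self.ref.n_valence


def prepare_local(ref: RestrictedReference,
                  config: DomainConfig | None = None) -> LocalContext:
    config = config or DomainConfig()
    dip = dipole(ref.basis)
    core, val = localize_core_and_valence(ref, dip)
    paos = build_paos(ref)
    builder = DomainBuilder(ref, core, val, paos, config, dip)
    pds = [builder.primary_domain(i) for i in range(val.n)]
    metric = ref.extras["metric"]
    b3c_val = np.tensordot(val.coefficients.T, ref.extras["b3c"],
                           axes=([1], [0]))

    def exact_pair(i, j, pd_i, pd_j):
        return pair_domain_mp2(ref, builder, i, j, pd_i, pd_j, metric,
                               b3c_val=b3c_val)

    cls = builder.classify_pairs(pds, pair_energy_fn=exact_pair)
    eds = {i: builder.extended_domain(i, cls, ref.extras["aux_basis"])
           for i in range(val.n)}
    return LocalContext(ref, config, dip, builder, pds, cls, eds)


def run_canonical_mp2(ref: RestrictedReference) -> EnergyReport:
    b3c = ref.extras["b3c"]
    c_o = ref.mo_coefficients[:, ref.n_core:ref.n_occ]
    c_v = ref.c_virt
    half = np.tensordot(c_o.T, b3c, axes=([1], [0]))
    j_ov = np.tensordot(half, c_v, axes=([1], [0])).transpose(0, 2, 1)
    return canonical_mp2(ref, j_ov)


def run_lmp2(ref: RestrictedReference, config: DomainConfig | None = None,
             ctx: LocalContext | None = None, denominator: str = "CD",
             cd_threshold: float = CD_THRESHOLD,
             n_laplace: int = 7) -> EnergyReport:
    ctx = ctx or prepare_local(ref, config)
    aux = ref.extras["aux_basis"]
    metric_cache: dict = {}
    ed_contrib = {}
    omegas = {}
    for i, ed in ctx.eds.items():
        j_vo, metric_loc, aux_idx = local_fitting_blocks(ref, ed, aux,
                                                         metric_cache)
        gaps = (ed.eps_virt[:, None] - ed.eps_occ[None, :]).ravel()
        if denominator == "CD":
            omega = cd_denominator(gaps, cd_threshold)
        else:
            rule = laplace_denominator(gaps.min(), gaps.max(), n_laplace)
            omega = rule.vectors_for(gaps)
        omegas[i] = omega
        ed_contrib[i] = ed_mp2_contribution(ed, omega, j_vo)
    pair_e = {p: ctx.classification.estimates[p]
              for p in ctx.classification.distant_pairs()}
    report = assemble_lmp2(ref, ed_contrib, ctx.classification, pair_e)
    report.extra["omegas"] = omegas
    report.extra["context"] = ctx
    return report


def _default_geminal(ref: RestrictedReference, gamma: float | None):
    from .geminal import make_geminal
    card = basis_cardinal(getattr(ref.basis, "name", "")) or "DZ"
    return make_geminal(card, gamma=gamma)


def prepare_f12(ref: RestrictedReference, gamma: float | None = None,
                cabs_basis=None):
    """Joint space, global complementary space and F12 integral bundle."""
    from .cabs import build_complementary, build_joint_space
    from .f12 import build_f12_integrals, global_ri
    import numpy as np
    geminal = _default_geminal(ref, gamma)
    joint = build_joint_space(ref, cabs_basis)
    nfull = joint.basis.nbf
    pad = np.zeros((nfull, ref.nmo))
    pad[:ref.nao] = ref.mo_coefficients
    comp = build_complementary(joint, pad[:, :ref.n_occ], pad[:, ref.n_occ:])
    ri = global_ri(joint, ref, comp)
    ints = build_f12_integrals(ref, joint, geminal)
    return {"geminal": geminal, "joint": joint, "comp": comp, "ri": ri,
            "ints": ints}


def run_canonical_mp2_f12(ref: RestrictedReference, gamma: float | None = None,
                          f12ctx: dict | None = None,
                          with_singles: bool = True) -> EnergyReport:
    import numpy as np
    from .cabs import cabs_singles
    from .f12 import (build_pair_intermediates, compute_C_canonical,
                      f12_pair_scalars)
    f12ctx = f12ctx or prepare_f12(ref, gamma)
    joint, ri, ints = f12ctx["joint"], f12ctx["ri"], f12ctx["ints"]
    c_val = ref.mo_coefficients[:, ref.n_core:ref.n_occ]
    eps_val = ref.orbital_energies[ref.n_core:ref.n_occ]
    eps_virt = ref.orbital_energies[ref.n_occ:]
    inter = build_pair_intermediates(ints, joint, ri, c_val, ints.metric)
    scal = f12_pair_scalars(inter, np.diag(eps_val))
    c_ij = compute_C_canonical(inter, ri, eps_val, eps_virt)
    s_ij = scal["B"] - scal["X"] + c_ij + scal["V"]
    n = len(eps_val)
    e_f12 = 0.0
    for i in range(n):
        for j in range(i, n):
            e_f12 += s_ij[i, j] / (1.0 + (i == j))
    rep = run_canonical_mp2(ref)
    rep.mode = "canonical-MP2-F12"
    rep.e_f12 = float(e_f12)
    rep.f12_terms = {
        "B": float(sum(scal["B"][i, j] / (1 + (i == j))
                       for i in range(n) for j in range(i, n))),
        "X": float(sum(scal["X"][i, j] / (1 + (i == j))
                       for i in range(n) for j in range(i, n))),
        "C": float(sum(c_ij[i, j] / (1 + (i == j))
                       for i in range(n) for j in range(i, n))),
        "V": float(sum(scal["V"][i, j] / (1 + (i == j))
                       for i in range(n) for j in range(i, n))),
    }
    if with_singles:
        rep.cabs_singles = cabs_singles(ref, joint, f12ctx["comp"])
    rep.extra["pair_f12"] = s_ij
    return rep


def run_lmp2_f12(ref: RestrictedReference, config: DomainConfig | None = None,
                 ctx: LocalContext | None = None, gamma: float | None = None,
                 f12ctx: dict | None = None, denominator: str = "CD",
                 cd_threshold: float = CD_THRESHOLD, n_laplace: int = 7,
                 with_singles: bool = True) -> EnergyReport:
    """Local explicitly correlated MP2: LMP2 plus per-extended-domain F12
    contributions and the (global) CABS singles correction."""
    import numpy as np
    from .cabs import cabs_singles
    from .df import build_metric
    from .f12 import (build_pair_intermediates, compute_C_local, ed_ri_space,
                      f12_pair_scalars, lmo_to_pseudo)
    from .geminal import OperatorKind

    ctx = ctx or prepare_local(ref, config)
    f12ctx = f12ctx or prepare_f12(ref, gamma)
    joint, ints = f12ctx["joint"], f12ctx["ints"]
    aux = ref.extras["aux_basis"]
    rep = run_lmp2(ref, ctx=ctx, denominator=denominator,
                   cd_threshold=cd_threshold, n_laplace=n_laplace)
    omegas = rep.extra["omegas"]
    f12_aux_atom = ints.aux.atom_of_function()
    metric_cache: dict = {}
    e_f12 = 0.0
    per_orb_f12 = {}
    for i, ed in ctx.eds.items():
        ri = ed_ri_space(joint, ref, ed)
        aux_idx = np.nonzero(np.isin(f12_aux_atom, list(ed.pcd_atoms)))[0]
        key = tuple(aux_idx.tolist())
        if key not in metric_cache:
            metric_cache[key] = build_metric(
                ints.v2[OperatorKind.coulomb][np.ix_(aux_idx, aux_idx)])
        metric_loc = metric_cache[key]
        inter = build_pair_intermediates(ints, joint, ri, ed.c_occ_trf,
                                         metric_loc, aux_idx=aux_idx)
        fock_pair = ed.c_occ_trf.T @ ref.fock_ao @ ed.c_occ_trf
        scal = f12_pair_scalars(inter, fock_pair)
        bxv = scal["B"] - scal["X"] + scal["V"]
        de = 0.5 * float(bxv[0, :].sum())      # CMO is pair label 0
        u = lmo_to_pseudo(ed, ref.overlap_ao)
        c_ij = compute_C_local(ed, ri, inter, u, omegas[i])
        de += 0.5 * float(c_ij.sum())
        per_orb_f12[i] = de
        e_f12 += de
    rep.mode = "LMP2-F12"
    rep.e_f12 = float(e_f12)
    rep.extra["per_orbital_f12"] = per_orb_f12
    if with_singles:
        rep.cabs_singles = cabs_singles(ref, joint, f12ctx["comp"])
    return rep
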