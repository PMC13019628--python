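import numpy as np
import pytest

from lmp2f12.domains import DomainConfig
from lmp2f12.driver import prepare_local, run_canonical_mp2, run_lmp2
from lmp2f12.molecule import Molecule, noble_pair
from lmp2f12.mp2 import assemble_lmp2, pair_domain_mp2
from lmp2f12.scf import rhf_reference

from oracles import mp2_dense_oracle, mp2_df_denominator_oracle


def test_canonical_mp2_matches_dense_oracle(h2_ref):
    """DF-MP2 with the aux spanning-quality of autoaux agrees with the exact
    four-index oracle to the fitting accuracy; with the *same* fitted
    integrals the explicit-loop oracle agrees to 1e-10."""
    rep = run_canonical_mp2(h2_ref)
    e_loop = mp2_df_denominator_oracle(h2_ref, _j_ov(h2_ref))
    assert rep.e_corr == pytest.approx(e_loop, abs=1e-10)
    e_dense = mp2_dense_oracle(h2_ref)
    assert rep.e_corr == pytest.approx(e_dense, abs=5e-5)


def _j_ov(ref):
    b3c = ref.extras["b3c"]
    c_o = ref.mo_coefficients[:, ref.n_core:ref.n_occ]
    half = np.tensordot(c_o.T, b3c, axes=([1], [0]))
    return np.tensordot(half, ref.c_virt, axes=([1], [0])).transpose(0, 2, 1)


def test_spin_partition_identity(h2o_ref):
    rep = run_canonical_mp2(h2o_ref)
    assert rep.opposite_spin + rep.same_spin == pytest.approx(rep.e_corr,
                                                              abs=1e-12)
    assert rep.e_corr == pytest.approx(sum(rep.per_orbital.values()), abs=1e-10)


def test_mp2_size_consistency_h2_pair():
    mono = Molecule(["H", "H"], [[0, 0, 0], [0, 0, 1.4]])
    dimer = Molecule(["H", "H", "H", "H"],
                     [[0, 0, 0], [0, 0, 1.4], [100, 0, 0], [100, 0, 1.4]])
    e1 = run_canonical_mp2(rhf_reference(mono, "svp-d", conv=1e-10)).e_corr
    e2 = run_canonical_mp2(rhf_reference(dimer, "svp-d", conv=1e-10)).e_corr
    assert e2 == pytest.approx(2 * e1, abs=1e-8)


def test_lmp2_full_domain_collapse(h2o_ref):
    """All thresholds maximal + eps_w = 0: the local energy reduces to the
    canonical MP2 energy."""
    rep = run_canonical_mp2(h2o_ref)
    ctx = prepare_local(h2o_ref, DomainConfig.full_domain())
    rl = run_lmp2(h2o_ref, ctx=ctx, cd_threshold=1e-7)
    assert rl.e_corr == pytest.approx(rep.e_corr, abs=1e-6)
    assert rl.distant_pair_energy == 0.0


def test_lmp2_denominator_shift_invariance(h2o_ref, h2o_ctx):
    """Shifting all virtual pseudo-energies and occupied energies by the same
    constant leaves the ED contribution unchanged."""
    import copy
    from lmp2f12.denominators import cd_denominator
    from lmp2f12.mp2 import ed_mp2_contribution, local_fitting_blocks
    ed = h2o_ctx.eds[0]
    aux = h2o_ref.extras["aux_basis"]
    j_vo, _, _ = local_fitting_blocks(h2o_ref, ed, aux)
    gaps = (ed.eps_virt[:, None] - ed.eps_occ[None, :]).ravel()
    e0 = ed_mp2_contribution(ed, cd_denominator(gaps, 1e-7), j_vo)
    shifted = copy.copy(ed)
    shifted.eps_virt = ed.eps_virt + 0.3
    shifted.eps_occ = ed.eps_occ + 0.3
    gaps2 = (shifted.eps_virt[:, None] - shifted.eps_occ[None, :]).ravel()
    e1 = ed_mp2_contribution(shifted, cd_denominator(gaps2, 1e-7), j_vo)
    assert e1 == pytest.approx(e0, abs=1e-10)


def test_pair_domain_guard(h2o_ref, h2o_ctx):
    with pytest.raises(ValueError):
        pair_domain_mp2(h2o_ref, h2o_ctx.builder, 1, 1, h2o_ctx.pds[1],
                        h2o_ctx.pds[1], h2o_ref.extras["metric"])


def test_he_dimer_pair_energy_vs_full_dimer():
    """Pair-domain opposite-spin energy at 10 bohr agrees with the full-dimer
    opposite-spin inter-monomer pair energy within 5%."""
    ref = rhf_reference(noble_pair("He", 10.0), "svp-d")
    ctx = prepare_local(ref)
    e_pd = pair_domain_mp2(ref, ctx.builder, 0, 1, ctx.pds[0], ctx.pds[1],
                           ref.extras["metric"])
    # full-dimer localized OS pair energy
    j_ov = _j_ov(ref)
    eo = ref.orbital_energies[ref.n_core:ref.n_occ]
    ev = ref.orbital_energies[ref.n_occ:]
    g = np.einsum("iaP,jbP->iajb", j_ov, j_ov, optimize=True)
    d = (eo[:, None, None, None] - ev[None, :, None, None]
         + eo[None, None, :, None] - ev[None, None, None, :])
    u = (ref.mo_coefficients[:, ref.n_core:ref.n_occ].T @ ref.overlap_ao
         @ ctx.builder.valence.coefficients)
    g_l = np.einsum("iajb,ik,jl->kalb", g, u, u, optimize=True)
    t_l = np.einsum("iajb,ik,jl->kalb", g / d, u, u, optimize=True)
    e_full = 2.0 * float(np.einsum("ab,ab->", g_l[0, :, 1, :], t_l[0, :, 1, :]))
    assert e_pd == pytest.approx(e_full, rel=0.05)
    # opposite-spin-only neglect makes the estimate an incomplete negative sum
    e_full_total = e_full + 2.0 * float(
        np.einsum("ab,ab->", g_l[0, :, 1, :] - g_l[1, :, 0, :].T,
                  t_l[0, :, 1, :]))
    assert e_pd < 0
    assert e_pd >= e_full_total - 1e-12


def test_assemble_rejects_double_counting(h2o_ref, h2o_ctx):
    cls = h2o_ctx.classification
    some_strong = next(iter(cls.strong))
    with pytest.raises(ValueError):
        assemble_lmp2(h2o_ref, {0: -0.1}, cls, {some_strong: -1e-6})


def test_lmp2_rotation_translation_invariance(h2o):
    cfg = None
    ref0 = rhf_reference(h2o, "sv", conv=1e-10)
    e0 = run_lmp2(ref0).e_corr
    th = 0.7
    rot = np.array([[np.cos(th), -np.sin(th), 0],
                    [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
    m2 = h2o.rotated(rot).translated([1.0, -2.0, 0.3])
    ref1 = rhf_reference(m2, "sv", conv=1e-10)
    e1 = run_lmp2(ref1).e_corr
    assert e1 == pytest.approx(e0, abs=1e-8)
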