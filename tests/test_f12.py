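import numpy as np
import pytest

from lmp2f12.basis import BasisSet, Shell
from lmp2f12.cabs import build_complementary, build_joint_space
from lmp2f12.df import build_metric
from lmp2f12.domains import DomainConfig
from lmp2f12.driver import (prepare_f12, prepare_local, run_canonical_mp2,
                            run_canonical_mp2_f12, run_lmp2_f12)
from lmp2f12.f12 import (build_f12_integrals, build_pair_intermediates,
                         compute_C_canonical, compute_R, f12_pair_scalars,
                         global_ri)
from lmp2f12.geminal import GeminalFactor, OperatorKind, make_geminal
from lmp2f12.integrals.twoelectron import four_center
from lmp2f12.molecule import Molecule
from lmp2f12.scf import rhf_reference


@pytest.fixture(scope="module")
def he_inter(he_ref, he_f12ctx):
    joint, ri, ints = (he_f12ctx["joint"], he_f12ctx["ri"], he_f12ctx["ints"])
    c_val = he_ref.mo_coefficients[:, :1]
    inter = build_pair_intermediates(ints, joint, ri, c_val, ints.metric)
    return inter, ri


def _dense_mo4(joint, ri, terms):
    t = four_center(joint.basis, terms, max_nbf=130)
    c = ri.c_ri
    return np.einsum("pqrs,pa,qb,rc,sd->abcd", t, c, c, c, c, optimize=True)


def test_vx_match_dense_finite_basis_oracle(he_ref, he_f12ctx, he_inter):
    """V and X for the He diagonal pair against a dense (DF-free) evaluation
    of the projected matrix elements in the same RI space."""
    inter, ri = he_inter
    joint, gem = he_f12ctx["joint"], he_f12ctx["geminal"]
    F = _dense_mo4(joint, ri, gem.kernel_terms(OperatorKind.f12))
    G = _dense_mo4(joint, ri, [(1.0, "coulomb", None)])
    F2 = _dense_mo4(joint, ri, gem.kernel_terms(OperatorKind.f12_squared))
    FR = _dense_mo4(joint, ri, gem.kernel_terms(OperatorKind.f12_over_r12))
    q, p = ri.masks()
    v_dense = FR[0, 0, 0, 0] - np.einsum("ab,ab,ab->", G[:, 0, :, 0], p,
                                         F[:, 0, :, 0])
    x_dense = F2[0, 0, 0, 0] - np.einsum("ab,ab,ab->", F[:, 0, :, 0], p,
                                         F[:, 0, :, 0])
    assert inter.V[0, 0, 0, 0] == pytest.approx(v_dense, abs=5e-6)
    assert inter.X[0, 0, 0, 0] == pytest.approx(x_dense, abs=1e-7)


def test_R_symmetry_and_loop_oracle(he_ref, he_inter):
    """R_{ij}^{ab} = R_{ji}^{ba}, and the einsum assembly matches an explicit
    index-loop evaluation of the two one-sided Fock transformations."""
    inter, ri = he_inter
    r = compute_R(inter, ri)
    assert abs(r - r.transpose(1, 0, 3, 2)).max() < 1e-10
    fvc = ri.fock[ri.virt, ri.comp]
    f4 = inter.F4
    nv = ri.n_virt
    comp = range(ri.comp.start, ri.comp.stop)
    loop = np.zeros_like(r)
    for a in range(nv):
        for b in range(nv):
            av, bv = ri.virt.start + a, ri.virt.start + b
            val = 0.0
            for ic, xc in enumerate(comp):
                val = val + fvc[a, ic] * f4[xc, :, bv, :] \
                          + fvc[b, ic] * f4[av, :, xc, :]
            loop[a, b] = val
    assert abs(r - loop).max() < 1e-12


def test_R_vanishes_without_complementary_coupling(he_inter):
    """With zero virtual-complementary Fock coupling the coupling tensor is
    zero: only CABS couplings drive the C term in ansatz 2B."""
    import copy
    inter, ri = he_inter
    ri2 = copy.copy(ri)
    f = ri.fock.copy()
    f[ri.virt, ri.comp] = 0.0
    f[ri.comp, ri.virt] = 0.0
    ri2.fock = f
    assert abs(compute_R(inter, ri2)).max() == 0.0


def test_C_coefficient_pattern_reduces_for_symmetric_tensors():
    rng = np.random.default_rng(0)
    g = rng.normal(size=(3, 3, 2, 2))
    g = g + g.transpose(0, 1, 3, 2)        # (ai|bj) = (aj|bi)
    r = rng.normal(size=(3, 3, 2, 2))
    r = r + r.transpose(0, 1, 3, 2)        # R_ij = R_ji
    bracket = 40 * g - 8 * g.transpose(0, 1, 3, 2) \
        + 7 * r + r.transpose(0, 1, 3, 2)
    np.testing.assert_allclose(bracket, 32 * g + 8 * r, atol=1e-12)


def test_C_canonical_matches_explicit_loop(he_ref, he_inter):
    inter, ri = he_inter
    eps_o = he_ref.orbital_energies[:1]
    eps_v = he_ref.orbital_energies[1:]
    c = compute_C_canonical(inter, ri, eps_o, eps_v)
    r = compute_R(inter, ri)
    g = inter.G4[ri.virt, :, ri.virt, :].transpose(0, 2, 1, 3)
    loop = 0.0
    for a in range(ri.n_virt):
        for b in range(ri.n_virt):
            d = eps_o[0] * 2 - eps_v[a] - eps_v[b]
            loop += (40 * g[a, b, 0, 0] - 8 * g[a, b, 0, 0]
                     + 7 * r[a, b, 0, 0] + r[a, b, 0, 0]) * r[a, b, 0, 0] / d
    assert c[0, 0] == pytest.approx(loop / 16.0, abs=1e-12)


def test_zero_geminal_gives_zero_intermediates(he_ref, he_f12ctx):
    joint, ri = he_f12ctx["joint"], he_f12ctx["ri"]
    gem0 = GeminalFactor(1.0, (0.0,) * 3, (0.3, 1.0, 3.0), 1.0,
                         fit_tolerance=2.0)
    ints0 = build_f12_integrals(he_ref, joint, gem0, aux=he_f12ctx["ints"].aux)
    inter = build_pair_intermediates(ints0, joint, ri,
                                     he_ref.mo_coefficients[:, :1],
                                     ints0.metric)
    assert abs(inter.V).max() < 1e-14
    assert abs(inter.X).max() < 1e-14
    assert abs(inter.B).max() < 1e-14
    c = compute_C_canonical(inter, ri, he_ref.orbital_energies[:1],
                            he_ref.orbital_energies[1:])
    assert abs(c).max() < 1e-14


def test_intermediate_pair_symmetries(h2o_ref, h2o_f12ctx):
    joint, ri, ints = (h2o_f12ctx["joint"], h2o_f12ctx["ri"],
                       h2o_f12ctx["ints"])
    c_val = h2o_ref.mo_coefficients[:, h2o_ref.n_core:h2o_ref.n_occ]
    inter = build_pair_intermediates(ints, joint, ri, c_val, ints.metric)
    # <kl|M|mn> = <lk|M|nm> (electron-exchange symmetry, real orbitals)
    for m4 in (inter.X, inter.B, inter.V):
        assert abs(m4 - m4.transpose(1, 0, 3, 2)).max() < 1e-9
    # X and B are symmetric pair-space matrices after symmetrization
    assert abs(inter.B - inter.B.transpose(2, 3, 0, 1)).max() < 1e-12
    assert abs(inter.X - inter.X.transpose(2, 3, 0, 1)).max() < 1e-9
    eps = h2o_ref.orbital_energies[h2o_ref.n_core:h2o_ref.n_occ]
    scal = f12_pair_scalars(inter, np.diag(eps))
    for key in ("V", "X", "B"):
        assert abs(scal[key] - scal[key].T).max() < 1e-9


def test_pair_sum_bookkeeping():
    """(1/2) sum over ordered pairs equals the 1/(1+delta_ij) triangle sum for
    any symmetric pair-scalar matrix."""
    rng = np.random.default_rng(5)
    s = rng.normal(size=(4, 4))
    s = s + s.T
    tri = sum(s[i, j] / (1 + (i == j)) for i in range(4) for j in range(i, 4))
    ordered = 0.5 * s.sum()
    assert tri == pytest.approx(ordered, abs=1e-12)


def test_he_f12_brackets_basis_limit(he_ref, he_f12ctx, he_large_mp2):
    """The F12 correction moves the small-basis MP2 energy toward (and close
    to) the large-basis value without overshooting past it wildly."""
    rep = run_canonical_mp2_f12(he_ref, f12ctx=he_f12ctx, with_singles=False)
    e_small = rep.e_corr
    e_large = he_large_mp2.e_corr
    e_f12tot = rep.e_corr + rep.e_f12
    assert rep.e_f12 < 0
    assert abs(e_f12tot - e_large) < abs(e_small - e_large)


def test_local_equals_canonical_on_full_domain_h2(h2_ref, h2_f12ctx):
    rep_c = run_canonical_mp2_f12(h2_ref, f12ctx=h2_f12ctx, with_singles=False)
    ctx = prepare_local(h2_ref, DomainConfig.full_domain())
    rep_l = run_lmp2_f12(h2_ref, ctx=ctx, f12ctx=h2_f12ctx,
                         cd_threshold=1e-7, with_singles=False)
    assert rep_l.e_f12 == pytest.approx(rep_c.e_f12, abs=1e-6)
    assert rep_l.e_corr == pytest.approx(rep_c.e_corr, abs=1e-6)
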