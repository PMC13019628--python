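import math

import numpy as np
import pytest

from lmp2f12.basis import BasisSet, Shell, build_basis
from lmp2f12.integrals.mcmurchie import dipole, kinetic, nuclear_attraction, overlap
from lmp2f12.integrals.twoelectron import four_center, three_center, two_center
from lmp2f12.molecule import Molecule

from oracles import eri_s_quadrature, threec_s_quadrature

KERNELS = [
    ("coulomb", [(1.0, "coulomb", None)], lambda r: 1.0 / r),
    ("gauss", [(0.7, "gauss", 0.9)], lambda r: 0.7 * math.exp(-0.9 * r * r)),
    ("gauss_r", [(0.5, "gauss_r", 1.3)],
     lambda r: 0.5 * math.exp(-1.3 * r * r) / r),
]


@pytest.fixture(scope="module")
def two_center_mol():
    mol = Molecule(["H", "H"], [[0, 0, 0], [0.5, -0.3, 1.1]])
    shells = [Shell(0, [0.8], [1.0], mol.coords[0], 0),
              Shell(0, [1.7], [1.0], mol.coords[1], 1)]
    return mol, BasisSet(mol, shells)


@pytest.mark.parametrize("name,terms,kern", KERNELS)
def test_four_center_s_vs_quadrature(two_center_mol, name, terms, kern):
    mol, b = two_center_mol
    eri = four_center(b, terms)
    ora = eri_s_quadrature(0.8, mol.coords[0], 1.7, mol.coords[1],
                           0.8, mol.coords[0], 1.7, mol.coords[1], kern)
    assert eri[0, 1, 0, 1] == pytest.approx(ora, abs=1e-13)
    ora2 = eri_s_quadrature(0.8, mol.coords[0], 0.8, mol.coords[0],
                            1.7, mol.coords[1], 1.7, mol.coords[1], kern)
    assert eri[0, 0, 1, 1] == pytest.approx(ora2, abs=1e-13)


@pytest.mark.parametrize("name,terms,kern", KERNELS)
def test_three_center_s_vs_quadrature(two_center_mol, name, terms, kern):
    mol, b = two_center_mol
    aux = BasisSet(mol, [Shell(0, [0.7], [1.0], mol.coords[1], 1)])
    bra = BasisSet(mol, [b.shells[0]])
    ket = BasisSet(mol, [b.shells[1]])
    t3 = three_center(bra, ket, aux, terms)
    ora = threec_s_quadrature(0.8, mol.coords[0], 1.7, mol.coords[1],
                              0.7, mol.coords[1], kern)
    assert t3[0, 0, 0] == pytest.approx(ora, abs=1e-13)


def _mixed_basis(shift):
    m = Molecule(["O", "H"], np.asarray([[0, 0, 0], [0, 0, 1.8]]) + shift)
    shells = [Shell(0, [1.2, 0.4], [0.7, 0.5], m.coords[0], 0),
              Shell(1, [0.9], [1.0], m.coords[0], 0),
              Shell(2, [1.1], [1.0], m.coords[1], 1),
              Shell(0, [0.5], [1.0], m.coords[1], 1)]
    return BasisSet(m, shells)


def test_translation_invariance_and_symmetry():
    terms = [(1.0, "coulomb", None), (0.4, "gauss", 0.8), (0.3, "gauss_r", 1.1)]
    e1 = four_center(_mixed_basis([0, 0, 0]), terms)
    e2 = four_center(_mixed_basis([1.3, -2.2, 0.7]), terms)
    assert abs(e1 - e2).max() < 1e-10
    for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1), (3, 2, 1, 0)]:
        assert abs(e1 - e1.transpose(perm)).max() < 1e-12


def test_p_function_from_center_derivative():
    """p integrals equal the center derivative of s integrals / (2a) (the
    finite difference moves the center in bra and ket, hence the factor 2)."""
    a_exp, terms = 0.9, [(1.0, "coulomb", None), (0.3, "gauss", 0.8)]

    def eri_s(z):
        mol = Molecule(["H", "H"], [[0, 0, z], [0.4, -0.2, 1.3]])
        b = BasisSet(mol, [Shell(0, [a_exp], [1.0], mol.coords[0], 0),
                           Shell(0, [1.5], [1.0], mol.coords[1], 1)])
        return four_center(b, terms)[0, 1, 0, 1]

    h = 2e-4
    fd = (eri_s(h) - eri_s(-h)) / (2 * h) / (2 * a_exp) / 2.0
    mol = Molecule(["H", "H"], [[0, 0, 0], [0.4, -0.2, 1.3]])
    b = BasisSet(mol, [Shell(1, [a_exp], [1.0], mol.coords[0], 0),
                       Shell(0, [a_exp], [1.0], mol.coords[0], 0),
                       Shell(0, [1.5], [1.0], mol.coords[1], 1)])
    eri = four_center(b, terms)
    ns = (2 * a_exp / math.pi) ** 0.75
    np_ = ns * math.sqrt(4 * a_exp)
    assert eri[2, 4, 3, 4] / (np_ / ns) == pytest.approx(fd, rel=1e-6)


def test_short_range_f12_decay():
    """A very tight Gaussian-geminal kernel between well-separated centers is
    numerically zero."""
    mol = Molecule(["H", "H"], [[0, 0, 0], [0, 0, 12.0]])
    b = BasisSet(mol, [Shell(0, [1.0], [1.0], mol.coords[0], 0),
                       Shell(0, [1.0], [1.0], mol.coords[1], 1)])
    eri = four_center(b, [(1.0, "gauss", 50.0)])
    assert abs(eri[0, 0, 1, 1]) < 1e-12


def test_one_electron_hydrogenic_eigenvalues():
    for sym, z in (("H", 1.0), ("He", 2.0)):
        m = Molecule([sym], [[0, 0, 0]])
        b = build_basis(m, "ref-large")
        import scipy.linalg as sla
        e0 = sla.eigh(kinetic(b) + nuclear_attraction(b), overlap(b))[0][0]
        assert e0 == pytest.approx(-z * z / 2, abs=3e-5)


def test_overlap_normalized_and_dipole_hermitian(h2o_ref):
    s = h2o_ref.overlap_ao
    assert np.abs(np.diag(s) - 1).max() < 1e-12
    d = dipole(h2o_ref.basis)
    assert abs(d - d.transpose(0, 2, 1)).max() < 1e-12


def test_four_center_size_guard():
    m = Molecule(["H"], [[0, 0, 0]])
    b = build_basis(m, "svp-d")
    with pytest.raises(ValueError):
        four_center(b, [(1.0, "coulomb", None)], max_nbf=2)
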