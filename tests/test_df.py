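import numpy as np
import pytest

from lmp2f12.basis import BasisSet, Shell
from lmp2f12.df import FittingBlock, build_metric, fit_J, fit_K
from lmp2f12.geminal import OperatorKind, make_geminal
from lmp2f12.integrals.twoelectron import four_center, three_center, two_center
from lmp2f12.molecule import Molecule


@pytest.fixture(scope="module")
def he_toy():
    """2-function orbital basis + aux spanning all products exactly."""
    mol = Molecule(["He"], [[0, 0, 0]])
    b = BasisSet(mol, [Shell(0, [1.2], [1.0], mol.coords[0], 0),
                       Shell(0, [0.4], [1.0], mol.coords[0], 0),
                       Shell(1, [0.8], [1.0], mol.coords[0], 0)])
    aux_shells = [Shell(0, [e], [1.0], mol.coords[0], 0) for e in (2.4, 1.6, 0.8)]
    aux_shells += [Shell(1, [e], [1.0], mol.coords[0], 0) for e in (2.0, 1.2)]
    aux_shells += [Shell(2, [1.6], [1.0], mol.coords[0], 0)]
    return b, BasisSet(mol, aux_shells)


def test_metric_factor_reconstruction(he_toy):
    _, aux = he_toy
    v = two_center(aux, [(1.0, "coulomb", None)])
    m = build_metric(v)
    rec = np.zeros_like(v)
    rec[np.ix_(m.kept, m.kept)] = m.reconstruct()
    assert abs(v[np.ix_(m.kept, m.kept)] - m.reconstruct()).max() < 1e-10
    assert m.dropped == 0


def test_metric_single_function_scalar():
    mol = Molecule(["He"], [[0, 0, 0]])
    aux = BasisSet(mol, [Shell(0, [1.0], [1.0], mol.coords[0], 0)])
    v = two_center(aux, [(1.0, "coulomb", None)])
    m = build_metric(v)
    assert m.L.shape == (1, 1)
    assert m.L[0, 0] == pytest.approx(np.sqrt(v[0, 0]))


def test_metric_duplicate_function_conditioned():
    mol = Molecule(["He"], [[0, 0, 0]])
    aux = BasisSet(mol, [Shell(0, [1.0], [1.0], mol.coords[0], 0),
                         Shell(0, [1.0], [1.0], mol.coords[0], 0)])
    m = build_metric(two_center(aux, [(1.0, "coulomb", None)]))
    assert m.naux == 1
    assert m.dropped == 1


def test_fit_J_exact_on_spanning_aux(he_toy):
    b, aux = he_toy
    metric = build_metric(two_center(aux, [(1.0, "coulomb", None)]))
    jb = fit_J(three_center(b, b, aux, [(1.0, "coulomb", None)]), metric)
    dense = four_center(b, [(1.0, "coulomb", None)])
    assert abs(jb.reconstruct() - dense).max() < 1e-10


def test_fit_J_zero_input(he_toy):
    _, aux = he_toy
    metric = build_metric(two_center(aux, [(1.0, "coulomb", None)]))
    jb = fit_J(np.zeros((2, 2, aux.nbf)), metric)
    assert abs(jb.J).max() == 0.0


def test_robust_fit_exact_on_spanning_aux(he_toy):
    b, aux = he_toy
    gem = make_geminal("DZ")
    terms = gem.kernel_terms(OperatorKind.f12)
    metric = build_metric(two_center(aux, [(1.0, "coulomb", None)]))
    jg = fit_J(three_center(b, b, aux, [(1.0, "coulomb", None)]), metric)
    kb = fit_K(three_center(b, b, aux, terms), two_center(aux, terms),
               jg, metric, OperatorKind.f12)
    dense = four_center(b, terms)
    assert abs(kb.reconstruct() - dense).max() < 1e-10


def test_robust_error_quadratic_in_incompleteness():
    """On nested shrinking aux sets the robust reconstruction error decays
    with about twice the log-slope of the one-sided fit."""
    mol = Molecule(["He"], [[0, 0, 0]])
    b = BasisSet(mol, [Shell(0, [1.2], [1.0], mol.coords[0], 0),
                       Shell(0, [0.4], [1.0], mol.coords[0], 0)])
    gem = make_geminal("DZ")
    terms = gem.kernel_terms(OperatorKind.f12)
    dense = four_center(b, terms)
    err_r, err_s = [], []
    for nscale in (0.55, 0.75, 0.9):
        # deliberately detuned aux exponents; closer to the product space as
        # nscale -> 1
        exps = np.array([2.4, 1.6, 0.8]) * nscale
        aux = BasisSet(mol, [Shell(0, [e], [1.0], mol.coords[0], 0) for e in exps])
        metric = build_metric(two_center(aux, [(1.0, "coulomb", None)]))
        x3f = three_center(b, b, aux, terms)
        jg = fit_J(three_center(b, b, aux, [(1.0, "coulomb", None)]), metric)
        kb = fit_K(x3f, two_center(aux, terms), jg, metric, OperatorKind.f12)
        err_r.append(abs(kb.reconstruct() - dense).max())
        # one-sided (non-robust) fit: operator J against itself
        jf = fit_J(x3f, metric)
        one_sided = np.einsum("pqP,rsP->pqrs", jf.J, jg.J)
        one_sided = 0.5 * (one_sided + one_sided.transpose(2, 3, 0, 1))
        err_s.append(abs(one_sided - dense).max())
    slope_r = np.polyfit(np.log(err_s), np.log(err_r), 1)[0]
    assert slope_r > 1.5  # quadratic vs linear error
    assert err_r[-1] < err_s[-1]


def test_fit_K_zero_two_center_reduces_to_pure_fit(he_toy):
    b, aux = he_toy
    gem = make_geminal("DZ")
    terms = gem.kernel_terms(OperatorKind.f12)
    metric = build_metric(two_center(aux, [(1.0, "coulomb", None)]))
    x3 = three_center(b, b, aux, terms)
    jg = fit_J(three_center(b, b, aux, [(1.0, "coulomb", None)]), metric)
    kb = fit_K(x3, np.zeros((aux.nbf, aux.nbf)), jg, metric, OperatorKind.f12)
    pure = fit_J(x3, metric)
    np.testing.assert_allclose(kb.K, pure.J, atol=1e-12)


def test_fit_K_rejects_coulomb(he_toy):
    b, aux = he_toy
    metric = build_metric(two_center(aux, [(1.0, "coulomb", None)]))
    jg = fit_J(three_center(b, b, aux, [(1.0, "coulomb", None)]), metric)
    with pytest.raises(ValueError):
        fit_K(np.zeros((2, 2, aux.nbf)), np.zeros((aux.nbf, aux.nbf)), jg,
              metric, OperatorKind.coulomb)
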