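import itertools

import numpy as np
import pytest

from lmp2f12.domains import DomainConfig, bp_atom_list
from lmp2f12.driver import prepare_local
from lmp2f12.molecule import Molecule, noble_pair, water_chain, water_monomer
from lmp2f12.scf import rhf_reference


def test_config_defaults_match_method():
    cfg = DomainConfig()
    assert (cfg.t_pdo, cfg.t_pdv, cfg.t_edo, cfg.t_o, cfg.t_trf) == \
        (0.999, 0.98, 0.9999, 0.985, 0.99999)
    assert cfg.eps_w == 1e-5
    assert cfg.cabs_domain_choice == "BPEDo"


@pytest.mark.parametrize("bad", [dict(t_trf=1.5), dict(t_pdo=0.0),
                                 dict(eps_w=-1e-6),
                                 dict(cabs_domain_choice="PD"),
                                 dict(t_edo=0.9, t_trf=0.8)])
def test_config_guards(bad):
    with pytest.raises(ValueError):
        DomainConfig(**bad)


def test_bp_single_atom_for_isolated_orbital():
    """A He 1s far from an H2 molecule yields a single-atom BP list."""
    m = Molecule(["He", "H", "H"], [[0, 0, 0], [0, 0, 20.0], [0, 0, 21.4]])
    ref = rhf_reference(m, "sv")
    ctx = prepare_local(ref)
    b = ctx.builder
    he_lmo = min(range(b.valence.n),
                 key=lambda i: np.linalg.norm(b.centroids[i]))
    lst = b.bp_pdo(he_lmo)
    assert lst.atoms == [0]
    assert lst.completeness >= 0.999


def test_bp_matches_exhaustive_minimal_list(h2o_ref, h2o_ctx):
    """Greedy OH-bond list at T=0.98 equals the brute-force minimal subset."""
    b = h2o_ctx.builder
    s = h2o_ref.overlap_ao
    atom_of = h2o_ref.basis.atom_of_function()
    # pick an OH-bond LMO (centroid off the oxygen, toward an H)
    i = max(range(b.valence.n), key=lambda k: abs(b.centroids[k][2]))
    c = b.valence.coefficients[:, i]
    greedy = bp_atom_list(c, s, atom_of, 0.98)

    def completeness(atoms):
        idx = np.concatenate([np.nonzero(atom_of == a)[0] for a in atoms])
        skk = s[np.ix_(idx, idx)]
        bk = (s @ c)[idx]
        return float(bk @ np.linalg.solve(skk, bk))

    best = None
    for size in range(1, 4):
        for subset in itertools.combinations(range(3), size):
            if completeness(list(subset)) >= 0.98:
                best = size
                break
        if best:
            break
    assert len(greedy.atoms) == best


def test_bp_threshold_one_takes_all_atoms(h2o_ref):
    """T = 1 can only be met (numerically) by the complete atom list."""
    atom_of = h2o_ref.basis.atom_of_function()
    lst = bp_atom_list(h2o_ref.c_occ[:, 1], h2o_ref.overlap_ao, atom_of, 1.0)
    assert sorted(lst.atoms) == [0, 1, 2]
    assert lst.completeness == pytest.approx(1.0, abs=1e-10)


def test_tighter_thresholds_enlarge_domains(h2o_ref):
    loose = prepare_local(h2o_ref, DomainConfig(t_pdo=0.98, t_pdv=0.95,
                                                t_edo=0.99, t_o=0.95,
                                                t_trf=0.995))
    tight = prepare_local(h2o_ref, DomainConfig())
    for i in range(len(loose.pds)):
        assert set(loose.pds[i].atoms) <= set(tight.pds[i].atoms)
        assert set(loose.eds[i].atoms) <= set(tight.eds[i].atoms)


def test_pd_water_is_whole_molecule(h2o_ctx):
    for pd in h2o_ctx.pds:
        assert sorted(pd.atoms) == [0, 1, 2]
        assert not pd.degenerate


def test_pd_he_dimer_stays_on_monomer():
    ref = rhf_reference(noble_pair("He", 20.0), "svp-d")
    ctx = prepare_local(ref)
    assert ctx.pds[0].atoms != ctx.pds[1].atoms
    for pd in ctx.pds:
        assert len(pd.atoms) == 1


def test_pair_estimate_guards(h2o_ctx):
    with pytest.raises(ValueError):
        h2o_ctx.builder.pair_energy_multipole(1, 1, h2o_ctx.pds[1], h2o_ctx.pds[1])


def test_he_pair_r6_power_law():
    rs = np.linspace(8.0, 16.0, 5)
    vals = []
    for r in rs:
        ref = rhf_reference(noble_pair("He", float(r)), "svp-d")
        ctx = prepare_local(ref)
        assert ctx.classification.method[(0, 1)] == "multipole"
        vals.append(abs(ctx.classification.estimates[(0, 1)]))
    slope = np.polyfit(np.log(rs), np.log(vals), 1)[0]
    assert slope == pytest.approx(-6.0, abs=0.3)


def test_distant_water_pair_below_default_threshold():
    m = water_chain(2, spacing=20.0 * 0.529177)  # 20 bohr O...O
    ref = rhf_reference(m, "sv")
    ctx = prepare_local(ref)
    cen = ctx.builder.centroids
    cross = [(i, j) for (i, j) in ctx.classification.estimates
             if (cen[i][0] < 10) != (cen[j][0] < 10)]
    assert cross
    for p in cross:
        assert abs(ctx.classification.estimates[p]) < 1e-5
        assert p not in ctx.classification.strong


def test_classification_flips_exactly_at_eps_w():
    ref = rhf_reference(noble_pair("He", 8.0), "svp-d")
    est = abs(prepare_local(ref).classification.estimates[(0, 1)])
    below = prepare_local(ref, DomainConfig(eps_w=est * 1.01)).classification
    above = prepare_local(ref, DomainConfig(eps_w=est * 0.99)).classification
    assert not below.is_strong(0, 1)
    assert above.is_strong(0, 1)


def test_classification_symmetric(h2o_ctx):
    cls = h2o_ctx.classification
    n = h2o_ctx.n_valence
    for i in range(n):
        for j in range(i + 1, n):
            assert cls.is_strong(i, j) == cls.is_strong(j, i)


def test_water_all_pairs_strong(h2o_ctx):
    n = h2o_ctx.n_valence
    assert len(h2o_ctx.classification.strong) == n * (n - 1) // 2


def test_ed_water_is_whole_molecule(h2o_ctx):
    for ed in h2o_ctx.eds.values():
        assert sorted(ed.atoms) == [0, 1, 2]
        assert ed.core_ids == [0]
        # default CABS domain is the BPEDo list of the CMO
        assert set(ed.cabs_atoms) == set(h2o_ctx.builder.bp_edo(ed.cmo).atoms)


def test_ed_spaces_orthonormal_and_fock_diagonal(h2o_ref, h2o_ctx):
    s, f = h2o_ref.overlap_ao, h2o_ref.fock_ao
    for ed in h2o_ctx.eds.values():
        co, cv = ed.c_occ_pseudo, ed.c_virt
        assert abs(co.T @ s @ co - np.eye(co.shape[1])).max() < 1e-8
        assert abs(cv.T @ s @ cv - np.eye(cv.shape[1])).max() < 1e-8
        assert abs(co.T @ s @ cv).max() < 1e-8
        fo = co.T @ f @ co
        fv = cv.T @ f @ cv
        assert abs(fo - np.diag(ed.eps_occ)).max() < 1e-8
        assert abs(fv - np.diag(ed.eps_virt)).max() < 1e-8


def test_far_water_dimer_monomer_domains_and_core_rule():
    m = water_chain(2, spacing=30.0 * 0.529177)
    ref = rhf_reference(m, "sv")
    ctx = prepare_local(ref)
    for ed in ctx.eds.values():
        # each ED stays on one monomer
        assert set(ed.atoms) <= {0, 1, 2} or set(ed.atoms) <= {3, 4, 5}
        # exactly the core of that monomer is included (coverage rule)
        assert len(ed.core_ids) == 1


def test_domain_report_serializable(h2o_ctx):
    import json
    from lmp2f12.domains import domain_report
    rep = domain_report(h2o_ctx.builder, h2o_ctx.pds, h2o_ctx.eds,
                        h2o_ctx.classification)
    text = json.dumps(rep)
    assert rep["n_valence"] == 4 and rep["n_core"] == 1
    assert len(rep["extended_domains"]) == 4
    assert json.loads(text) == rep
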