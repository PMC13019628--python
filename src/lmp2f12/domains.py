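"""Boughton-Pulay atom lists and the local-correlation domain hierarchy.

For every localized orbital the (modified) BP procedure selects the smallest
greedy atom list whose metric projection reproduces the orbital above a
completeness threshold. Unions of such lists define the primary domains (PD),
extended domains (ED), PAO-center domains (PCD), CABS domains and local
fitting domains; approximate multipole pair energies classify LMO pairs into
strong (kept in EDs) and distant (multipole-summed) pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .localization import LocalizedSet, PAOSet, lmo_centroids
from .reference import RestrictedReference, semicanonicalize


@dataclass
class DomainConfig:
    t_pdo: float = 0.999
    t_pdv: float = 0.98
    t_edo: float = 0.9999
    t_o: float = 0.985
    t_trf: float = 0.99999
    eps_w: float = 1e-5            # hartree, strong-pair threshold
    cabs_domain_choice: str = "BPEDo"   # ED | PCD | BPEDo | BPo

    def __post_init__(self):
        for name in ("t_pdo", "t_pdv", "t_edo", "t_o", "t_trf"):
            t = getattr(self, name)
            if not (0.0 < t <= 1.0):
                raise ValueError(f"threshold {name}={t} outside (0, 1]")
        if not (self.t_trf >= self.t_edo >= self.t_pdo):
            raise ValueError("expected t_trf >= t_edo >= t_pdo")
        if self.eps_w < 0:
            raise ValueError("eps_w must be non-negative")
        if self.cabs_domain_choice not in ("ED", "PCD", "BPEDo", "BPo"):
            raise ValueError(f"unknown CABS domain {self.cabs_domain_choice!r}")

    @classmethod
    def full_domain(cls) -> "DomainConfig":
        """Settings that force every domain to the whole molecule and every
        pair to be strong (the canonical-collapse limit)."""
        return cls(t_pdo=1.0, t_pdv=1.0, t_edo=1.0, t_o=1.0, t_trf=1.0,
                   eps_w=0.0, cabs_domain_choice="ED")


@dataclass
class BPAtomList:
    orbital: int
    atoms: list
    completeness: float
    reached: bool = True


def bp_atom_list(orbital_coeffs: np.ndarray, overlap: np.ndarray,
                 atom_of_ao: np.ndarray, threshold: float,
                 sqrt_overlap: np.ndarray | None = None,
                 orbital_id: int = -1) -> BPAtomList:
    """Greedy modified-BP atom list for one S-normalized orbital.

    Atoms are ranked by descending Loewdin population (ties by index) and
    appended until the squared norm of the metric projection of the orbital
    onto the listed atoms' AO block reaches the threshold. If the threshold is
    numerically unreachable, all atoms are returned with reached=False.
    """
    c = np.asarray(orbital_coeffs, dtype=float).ravel()
    natom = int(atom_of_ao.max()) + 1
    if sqrt_overlap is None:
        ev, u = sla.eigh(overlap)
        sqrt_overlap = (u * np.sqrt(np.maximum(ev, 0))) @ u.T
    lowdin = (sqrt_overlap @ c) ** 2
    pops = np.zeros(natom)
    np.add.at(pops, atom_of_ao, lowdin)
    order = np.lexsort((np.arange(natom), -pops))
    b = overlap @ c
    atoms: list[int] = []
    funcs: list[int] = []
    prev = -1.0
    comp = 0.0
    for a in order:
        atoms.append(int(a))
        funcs.extend(np.nonzero(atom_of_ao == a)[0].tolist())
        idx = np.array(funcs)
        skk = overlap[np.ix_(idx, idx)]
        bk = b[idx]
        try:
            x = sla.solve(skk, bk, assume_a="pos")
        except np.linalg.LinAlgError:
            x = np.linalg.lstsq(skk, bk, rcond=1e-12)[0]
        comp = float(bk @ x)
        if comp < prev - 1e-9:
            raise AssertionError("BP completeness decreased while adding atoms")
        prev = comp
        if comp >= threshold:
            return BPAtomList(orbital_id, atoms, comp, True)
    return BPAtomList(orbital_id, atoms, comp, False)


@dataclass
class PrimaryDomain:
    lmo: int
    atoms: list
    pao_ids: np.ndarray
    c_virt: np.ndarray            # AO x nv, S-orthonormal, Fock-canonical
    eps_virt: np.ndarray
    degenerate: bool = False


@dataclass
class PairClassification:
    estimates: dict               # (i, j) i<j -> hartree (<= 0)
    strong: set                   # frozen set of (i, j) i<j
    eps_w: float
    method: dict = field(default_factory=dict)  # (i,j) -> "multipole"|"pair-domain"

    def is_strong(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.strong

    def partners(self, i: int, n: int):
        return [j for j in range(n) if j != i and self.is_strong(i, j)]

    def distant_pairs(self):
        return [p for p in self.estimates if p not in self.strong]


@dataclass
class ExtendedDomain:
    cmo: int                          # valence LMO index
    occ_ids: list                     # valence LMOs of the ED (includes cmo)
    core_ids: list                    # core LMOs covered by the ED
    atoms: list
    ao_indices: np.ndarray            # functions on ED atoms
    pcd_atoms: list
    cabs_atoms: list
    c_occ_pseudo: np.ndarray          # AO x n_occ_ed (valence, pseudocanonical)
    eps_occ: np.ndarray
    w_cmo: np.ndarray                 # CMO in the pseudocanonical occupied basis
    c_virt: np.ndarray                # AO x nv (PAO-derived, pseudocanonical)
    eps_virt: np.ndarray
    c_occ_trf: np.ndarray             # BPtrf(cap ED)-truncated, renormalized LMOs
    c_core: np.ndarray                # included core LMOs (full coefficients)
    lmo_norm_deficit: float = 0.0


class DomainBuilder:
    """Derives the full domain hierarchy from a reference + localization."""

    def __init__(self, ref: RestrictedReference, core: LocalizedSet,
                 valence: LocalizedSet, paos: PAOSet, config: DomainConfig,
                 dipole_ints: np.ndarray):
        self.ref = ref
        self.core = core
        self.valence = valence
        self.paos = paos
        self.config = config
        self.dip = dipole_ints
        self.s = ref.overlap_ao
        self.f = ref.fock_ao
        self.atom_of_ao = ref.basis.atom_of_function()
        ev, u = sla.eigh(self.s)
        self._sqrt_s = (u * np.sqrt(np.maximum(ev, 0))) @ u.T
        self.centroids = lmo_centroids(valence, dipole_ints)
        self._lists: dict = {}

    # ---- BP lists -------------------------------------------------------
    def _bp(self, kind: str, which: str, idx: int, threshold: float) -> BPAtomList:
        key = (kind, which, idx, threshold)
        if key not in self._lists:
            c = {"valence": self.valence.coefficients,
                 "core": self.core.coefficients,
                 "pao": self.paos.coefficients}[which][:, idx]
            self._lists[key] = bp_atom_list(c, self.s, self.atom_of_ao, threshold,
                                            self._sqrt_s, idx)
        return self._lists[key]

    def bp_pdo(self, i): return self._bp("PDo", "valence", i, self.config.t_pdo)
    def bp_edo(self, i): return self._bp("EDo", "valence", i, self.config.t_edo)
    def bp_o(self, i): return self._bp("o", "valence", i, self.config.t_o)
    def bp_trf(self, i): return self._bp("trf", "valence", i, self.config.t_trf)
    def bp_core_edo(self, k): return self._bp("EDo", "core", k, self.config.t_edo)
    def bp_pdv(self, a): return self._bp("PDv", "pao", a, self.config.t_pdv)

    # ---- primary domains -------------------------------------------------
    def primary_domain(self, i: int) -> PrimaryDomain:
        cfg = self.config
        bppdo = self.bp_pdo(i)
        pd_atoms = set(bppdo.atoms)
        pao_ids = np.nonzero(np.isin(self.paos.parent_atom, list(pd_atoms)))[0]
        for a in pao_ids:
            pd_atoms.update(self.bp_pdv(int(a)).atoms)
        pd_atoms = sorted(pd_atoms)
        funcs = self.ref.basis.functions_on_atoms(pd_atoms)
        lmo = self.valence.coefficients[:, i:i + 1]
        cv = _truncate_project_canonicalize(self.paos.coefficients[:, pao_ids],
                                            funcs, lmo, self.s, self.f)
        c_virt, eps_virt = cv
        return PrimaryDomain(i, pd_atoms, pao_ids, c_virt, eps_virt,
                             degenerate=c_virt.shape[1] == 0)

    # ---- pair estimates ---------------------------------------------------
    def pair_energy_multipole(self, i: int, j: int, pd_i: PrimaryDomain,
                              pd_j: PrimaryDomain) -> float:
        """Opposite-spin dipole-dipole (R^-6) pair-energy estimate."""
        if i == j:
            raise ValueError("pair estimate requires two distinct LMOs")
        ci = self.valence.coefficients[:, i]
        cj = self.valence.coefficients[:, j]
        rij = self.centroids[j] - self.centroids[i]
        r = float(np.linalg.norm(rij))
        nhat = rij / r
        # transition dipoles <a|r|i> (origin-independent: <a|i> = 0)
        mu_i = np.einsum("dpq,pa,q->ad", self.dip, pd_i.c_virt, ci)
        mu_j = np.einsum("dpq,pb,q->bd", self.dip, pd_j.c_virt, cj)
        t = (mu_i @ mu_j.T - 3.0 * np.outer(mu_i @ nhat, mu_j @ nhat)) / r ** 3
        fii = float(ci @ self.f @ ci)
        fjj = float(cj @ self.f @ cj)
        denom = (fii + fjj) - pd_i.eps_virt[:, None] - pd_j.eps_virt[None, :]
        return float(2.0 * np.sum(t * t / denom))

    def classify_pairs(self, pds: list, pair_energy_fn=None) -> PairClassification:
        """Classify all valence pairs; `pair_energy_fn(i, j, pd_i, pd_j)` is the
        exact pair-domain evaluation used when the PDs share atoms."""
        n = self.valence.n
        estimates, method = {}, {}
        strong = set()
        for i in range(n):
            for j in range(i + 1, n):
                overlap_pd = set(pds[i].atoms) & set(pds[j].atoms)
                if overlap_pd and pair_energy_fn is not None:
                    val = pair_energy_fn(i, j, pds[i], pds[j])
                    method[(i, j)] = "pair-domain"
                else:
                    val = self.pair_energy_multipole(i, j, pds[i], pds[j])
                    method[(i, j)] = "multipole" if not overlap_pd else "multipole(overlap)"
                estimates[(i, j)] = val
                if abs(val) >= self.config.eps_w:
                    strong.add((i, j))
        return PairClassification(estimates, strong, self.config.eps_w, method)

    # ---- extended domains --------------------------------------------------
    def extended_domain(self, i: int, classification: PairClassification,
                        aux_basis=None) -> ExtendedDomain:
        cfg = self.config
        occ_ids = [i] + classification.partners(i, self.valence.n)
        ed_atoms = set()
        for j in occ_ids:
            ed_atoms.update(self.bp_edo(j).atoms)
        ed_atoms = sorted(ed_atoms)
        funcs = self.ref.basis.functions_on_atoms(ed_atoms)
        pcd = set()
        for j in occ_ids:
            pcd.update(self.bp_o(j).atoms)
        pcd = sorted(pcd & set(ed_atoms))  # the PCD is a subset of the ED
        # core orbitals whose complete BPEDo list is inside the ED
        core_ids = [k for k in range(self.core.n)
                    if set(self.bp_core_edo(k).atoms) <= set(ed_atoms)]
        # occupied: LMOs truncated to their own BPEDo lists, orthonormalized,
        # canonicalized
        occ_block = []
        deficit = 0.0
        for j in occ_ids:
            cj, dj = _truncate_renormalize(
                self.valence.coefficients[:, j],
                self.ref.basis.functions_on_atoms(self.bp_edo(j).atoms), self.s)
            occ_block.append(cj)
            deficit = max(deficit, dj)
        occ_block = np.array(occ_block).T
        c_occ_ps, eps_occ = semicanonicalize(occ_block, self.f, self.s)
        w_cmo = c_occ_ps.T @ self.s @ self.valence.coefficients[:, i]
        # core orbitals truncated to the ED and orthogonalized to the valence
        # block: together they form the exactly orthonormal ED occupied space
        if core_ids:
            ct = np.zeros((self.ref.nao, len(core_ids)))
            ct[funcs] = self.core.coefficients[np.ix_(funcs, core_ids)]
            ct = ct - c_occ_ps @ (c_occ_ps.T @ self.s @ ct)
            c_core_ed, _ = semicanonicalize(ct, self.f, self.s)
        else:
            c_core_ed = np.zeros((self.ref.nao, 0))
        # virtuals: PAOs of PCD atoms truncated to the ED, orthogonal to the
        # ED occupied space
        pao_ids = np.nonzero(np.isin(self.paos.parent_atom, list(pcd)))[0]
        occ_ed = np.concatenate([c_core_ed, c_occ_ps], axis=1)
        c_virt, eps_virt = _truncate_project_canonicalize(
            self.paos.coefficients[:, pao_ids], funcs, occ_ed, self.s, self.f)
        if c_virt.shape[1] == 0:
            raise RuntimeError(f"extended domain of LMO {i} has no virtual space")
        # BPtrf(cap ED) truncation for the F12 integral transformation
        trf_block = []
        for j in occ_ids:
            atoms_trf = sorted(set(self.bp_trf(j).atoms) & set(ed_atoms))
            cj, dj = _truncate_renormalize(
                self.valence.coefficients[:, j],
                self.ref.basis.functions_on_atoms(atoms_trf), self.s)
            trf_block.append(cj)
            deficit = max(deficit, dj)
        c_occ_trf = np.array(trf_block).T
        cabs_atoms = {"ED": ed_atoms, "PCD": pcd,
                      "BPEDo": sorted(self.bp_edo(i).atoms),
                      "BPo": sorted(self.bp_o(i).atoms)}[cfg.cabs_domain_choice]
        return ExtendedDomain(
            cmo=i, occ_ids=occ_ids, core_ids=core_ids, atoms=ed_atoms,
            ao_indices=funcs, pcd_atoms=pcd, cabs_atoms=cabs_atoms,
            c_occ_pseudo=c_occ_ps, eps_occ=eps_occ, w_cmo=w_cmo,
            c_virt=c_virt, eps_virt=eps_virt, c_occ_trf=c_occ_trf,
            c_core=c_core_ed, lmo_norm_deficit=deficit)


def _truncate_renormalize(c: np.ndarray, funcs: np.ndarray, s: np.ndarray):
    """Zero AO coefficients outside `funcs` and renormalize; returns
    (column, norm deficit 1 - |c_trunc|_S before renormalization)."""
    ct = np.zeros_like(c)
    ct[funcs] = c[funcs]
    n2 = float(ct @ s @ ct)
    if n2 <= 0:
        raise ValueError("orbital truncated to nothing")
    return ct / np.sqrt(n2), 1.0 - np.sqrt(n2)


def _truncate_project_canonicalize(c_pao: np.ndarray, funcs: np.ndarray,
                                   c_project_out: np.ndarray, s: np.ndarray,
                                   f: np.ndarray):
    """Truncate PAOs to an AO list, project out given orbitals, orthonormalize
    and Fock-canonicalize. Returns (c_virt, eps_virt)."""
    if c_pao.shape[1] == 0:
        return np.zeros((c_pao.shape[0], 0)), np.zeros(0)
    ct = np.zeros_like(c_pao)
    ct[funcs] = c_pao[funcs]
    proj = ct - c_project_out @ (c_project_out.T @ (s @ ct))
    norms = np.sqrt(np.maximum(np.einsum("mi,mn,ni->i", proj, s, proj), 0.0))
    keep = norms > 1e-8
    if not np.any(keep):
        return np.zeros((c_pao.shape[0], 0)), np.zeros(0)
    return semicanonicalize(proj[:, keep] / norms[keep], f, s)


def domain_report(builder: DomainBuilder, pds, eds, classification) -> dict:
    """JSON-able summary of the domain hierarchy (for logs and regression
    tests): atoms, orbital counts and completeness values per domain."""
    rep = {"n_valence": builder.valence.n, "n_core": builder.core.n,
           "primary_domains": [], "extended_domains": [],
           "n_strong_pairs": len(classification.strong),
           "n_distant_pairs": len(classification.distant_pairs())}
    for pd in pds:
        rep["primary_domains"].append({
            "lmo": pd.lmo, "atoms": list(map(int, pd.atoms)),
            "n_virt": int(pd.c_virt.shape[1]),
            "bp_completeness": builder.bp_pdo(pd.lmo).completeness})
    for i, ed in sorted(eds.items()):
        rep["extended_domains"].append({
            "cmo": ed.cmo, "atoms": list(map(int, ed.atoms)),
            "n_ao": int(len(ed.ao_indices)),
            "n_occ": len(ed.occ_ids), "n_core": len(ed.core_ids),
            "n_virt": int(ed.c_virt.shape[1]),
            "pcd_atoms": list(map(int, ed.pcd_atoms)),
            "cabs_atoms": list(map(int, ed.cabs_atoms)),
            "lmo_norm_deficit": float(ed.lmo_norm_deficit)})
    return rep
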