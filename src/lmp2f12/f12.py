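"""Explicitly correlated (F12) intermediates and energies, ansatz 2B with
fixed (cusp-condition) geminal amplitudes and the F+K commutator treatment of
the B intermediate.

Conventions
-----------
Four-index arrays are stored in Mulliken order: A[p,q,r,s] = (pq|op|rs).
Pair-space intermediates are assembled in an orthonormal RI orbital basis
[occupied | virtual | complementary]; the strong-orthogonality projector of
ansatz 2B, Q12 = (1-O1)(1-O2) - V1V2, is then an elementwise mask over RI
pair indices.

Fixed amplitudes: the first-order cusp conditions give geminal coefficients
3/8 (direct) and 1/8 (exchange) per occupied pair (singlet 1/2, triplet 1/4).
Contracting them with the closed-shell contravariant metric yields the pair
coefficient patterns (5/2, -1/2) for the linear (V) term and (7/16, 1/16) for
the quadratic (B, X) terms - the same patterns that appear in the printed
coupling intermediate C.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import BasisSet
from .cabs import ComplementarySpace, JointSpace
from .df import FittingBlock, MetricFactor, fit_J, fit_K
from .denominators import OmegaVectors, apply_omega
from .geminal import GeminalFactor, OperatorKind
from .integrals.twoelectron import three_center, two_center
from .reference import RestrictedReference

GEMINAL_OPS = (OperatorKind.f12, OperatorKind.f12_squared,
               OperatorKind.f12_over_r12, OperatorKind.grad_f12_squared)


@dataclass
class F12Integrals:
    """AO-level three/two-center tensors for all five operators.

    x3[op]: (njoint, nao, naux) for coulomb/f12/f12_squared;
            (nao, nao, naux) for f12_over_r12/grad_f12_squared.
    v2[op]: (naux, naux) two-center operator matrices.
    """
    geminal: GeminalFactor
    x3: dict
    v2: dict
    aux: BasisSet | None = None
    metric: MetricFactor | None = None


def build_f12_integrals(ref: RestrictedReference, joint: JointSpace,
                        geminal: GeminalFactor,
                        aux: BasisSet | None = None) -> F12Integrals:
    """Three/two-center integrals of the five operators over an auxiliary set
    that must span joint x orbital products (see `autoaux(..., other=...)`)."""
    from .basis import autoaux
    basis = ref.basis
    if aux is None:
        aux = autoaux(joint.basis, other=basis, l_cap=4)
    x3, v2 = {}, {}
    for op in (OperatorKind.coulomb, OperatorKind.f12, OperatorKind.f12_squared):
        terms = geminal.kernel_terms(op)
        x3[op] = three_center(joint.basis, basis, aux, terms)
    for op in (OperatorKind.f12_over_r12, OperatorKind.grad_f12_squared):
        x3[op] = three_center(basis, basis, aux, geminal.kernel_terms(op))
    for op in GEMINAL_OPS:
        v2[op] = two_center(aux, geminal.kernel_terms(op))
    v2[OperatorKind.coulomb] = two_center(aux, [(1.0, "coulomb", None)])
    from .df import build_metric
    return F12Integrals(geminal, x3, v2, aux=aux,
                        metric=build_metric(v2[OperatorKind.coulomb]))


@dataclass
class RISpace:
    """Orthonormal RI orbital set over a (possibly restricted) joint function set."""
    func_idx: np.ndarray        # indices into the joint function space
    c_ri: np.ndarray            # (nfunc_sel, M)
    n_occ: int                  # occupied orbitals (core + valence of the space)
    n_virt: int
    fock: np.ndarray            # (M, M) RI-basis Fock

    @property
    def m(self) -> int:
        return self.c_ri.shape[1]

    @property
    def occ(self):
        return slice(0, self.n_occ)

    @property
    def virt(self):
        return slice(self.n_occ, self.n_occ + self.n_virt)

    @property
    def comp(self):
        return slice(self.n_occ + self.n_virt, self.m)

    def masks(self):
        o = np.zeros(self.m)
        o[self.occ] = 1.0
        v = np.zeros(self.m)
        v[self.virt] = 1.0
        # P = 1 - Q with Q the ansatz-2B strong-orthogonality projector
        q = (1 - o[:, None]) * (1 - o[None, :]) - v[:, None] * v[None, :]
        return q, 1.0 - q


def global_ri(joint: JointSpace, ref: RestrictedReference,
              comp: ComplementarySpace) -> RISpace:
    nfull = joint.basis.nbf
    pad = np.zeros((nfull, ref.nmo))
    pad[:ref.nao] = ref.mo_coefficients
    c_ri = np.concatenate([pad, comp.c_comp], axis=1)
    fock = c_ri.T @ joint.fock @ c_ri
    return RISpace(func_idx=np.arange(nfull), c_ri=c_ri, n_occ=ref.n_occ,
                   n_virt=ref.nmo - ref.n_occ, fock=fock)


# ---------------------------------------------------------------------------
# Four-index intermediates V, X, B over occupied pair labels
# ---------------------------------------------------------------------------

@dataclass
class F12PairIntermediates:
    """Pair-label four-index intermediates and the tensors feeding C."""
    V: np.ndarray               # [k,l,m,n] = <kl| r^-1 Q f |mn>
    X: np.ndarray               # [k,l,m,n] = <kl| f Q f |mn>
    B: np.ndarray               # [k,l,m,n] = sym <kl| f Q (F1+F2) Q f |mn>
    F4: np.ndarray              # (x k|f12|y l) over RI x,y; pair labels k,l
    G4: np.ndarray              # (x k|y l) Coulomb
    j_f12: FittingBlock | None = None
    k_f12: np.ndarray | None = None


def _fit_pairs(x3_sel, c_bra, c_ket, metric, aux_idx):
    """Transform a three-center tensor to (bra, ket) pairs and fit J."""
    x = x3_sel[:, :, aux_idx] if aux_idx is not None else x3_sel
    half = np.tensordot(c_bra.T, x, axes=([1], [0]))
    full = np.tensordot(half, c_ket, axes=([1], [0])).transpose(0, 2, 1)
    return full


def build_pair_intermediates(ints: F12Integrals, joint: JointSpace,
                             ri: RISpace, c_pair: np.ndarray,
                             metric: MetricFactor,
                             aux_idx: np.ndarray | None = None,
                             fock_pair_ri: np.ndarray | None = None,
                             ri_kinetic: np.ndarray | None = None,
                             tkin_pair_ri: np.ndarray | None = None
                             ) -> F12PairIntermediates:
    """Assemble V, X, B for the occupied pair-label orbitals `c_pair`.

    c_pair: (nao, npair) AO coefficients of the correlated pair labels
    (canonical valence MOs, or truncated LMOs in a domain). `metric` must be
    the fitting metric matching `aux_idx` (the local fitting domain; None
    means the full auxiliary set). fock_pair_ri: (npair, M) Fock between pair
    labels and RI orbitals; computed from the joint Fock if omitted.
    """
    sel = ri.func_idx
    ao_rows = sel[sel < joint.nao]          # AO functions come first
    c_pair_ao = c_pair[ao_rows]
    npair = c_pair.shape[1]
    if ri_kinetic is None:
        ri_kinetic = ri.c_ri.T @ joint.kin[np.ix_(sel, sel)] @ ri.c_ri

    def x3sel(op):
        x = ints.x3[op]
        rows = sel if x.shape[0] == joint.basis.nbf else ao_rows
        x = x[np.ix_(rows, ao_rows)]
        return x[:, :, aux_idx] if aux_idx is not None else x

    def v2sel(op):
        v2 = ints.v2[op]
        return v2[np.ix_(aux_idx, aux_idx)] if aux_idx is not None else v2

    # --- robust-fitted blocks over (RI x pair-label) pairs.
    # The robust partner K of every operator is paired with the *Coulomb*
    # fitting coefficients J of the same orbital pairs.
    def transform(x):
        t = np.tensordot(ri.c_ri.T, x, axes=([1], [0]))
        return np.tensordot(t, c_pair_ao, axes=([1], [0])).transpose(0, 2, 1)

    jj = {OperatorKind.coulomb: fit_J(transform(x3sel(OperatorKind.coulomb)),
                                      metric)}
    for op in (OperatorKind.f12, OperatorKind.f12_squared):
        jj[op] = fit_K(transform(x3sel(op)), v2sel(op),
                       jj[OperatorKind.coulomb], metric, op)

    # --- pair-label-only operators (all four orbital indices are pair labels)
    def transform_occ(x):
        return np.tensordot(c_pair_ao.T, np.tensordot(
            c_pair_ao.T, x, axes=([1], [0])), axes=([1], [1])).transpose(1, 0, 2)

    x3g_occ = ints.x3[OperatorKind.coulomb][np.ix_(ao_rows, ao_rows)]
    x3g_occ = x3g_occ[:, :, aux_idx] if aux_idx is not None else x3g_occ
    jg_occ = fit_J(transform_occ(x3g_occ), metric)
    occ4 = {}
    for op in (OperatorKind.f12_over_r12, OperatorKind.grad_f12_squared,
               OperatorKind.f12_squared):
        x = ints.x3[op][np.ix_(ao_rows, ao_rows)]
        x = x[:, :, aux_idx] if aux_idx is not None else x
        occ4[op] = fit_K(transform_occ(x), v2sel(op), jg_occ, metric, op)

    jg = jj[OperatorKind.coulomb]
    jf = jj[OperatorKind.f12]
    jf2 = jj[OperatorKind.f12_squared]
    G4 = jg.reconstruct(jg)                       # (x k|y l)
    F4 = jf.reconstruct(jf)                       # (x k|f|y l)
    q, p = ri.masks()

    # ---- V = exact f/r - RI projection corrections -------------------------
    fr = occ4[OperatorKind.f12_over_r12].reconstruct()   # (k l|f/r|m n)
    # physicist <kl|g f|mn> = Mulliken (k m|f/r|l n)
    v = fr.transpose(0, 2, 1, 3).copy()
    v -= np.einsum("akbl,ab,ambn->klmn", G4, p, F4, optimize=True)
    # ---- X = exact f^2 - RI projection corrections -------------------------
    x4occ = occ4[OperatorKind.f12_squared].reconstruct()
    x = x4occ.transpose(0, 2, 1, 3).copy()
    x -= np.einsum("akbl,ab,ambn->klmn", F4, p, F4, optimize=True)

    # ---- B ----------------------------------------------------------------
    # Kinetic content via the commutator identity
    #   f T f = {T, f^2}/2 + (d1 f)^2,
    # which is exact for the multiplicative geminal and converges fast with
    # the RI size (kinetic insertions stay inside the Gaussian span). The
    # remaining Fock content (potential, Coulomb, exchange under the F+K
    # commutator approximation) is evaluated with both geminal indices
    # RI-projected, which keeps its cancellations consistent.
    fri = ri.fock
    tri = ri_kinetic
    if fock_pair_ri is None or tkin_pair_ri is None:
        c_pair_sel = np.zeros((len(sel), npair))
        c_pair_sel[:len(ao_rows)] = c_pair_ao
        if fock_pair_ri is None:
            fock_pair_ri = c_pair_sel.T @ joint.fock[np.ix_(sel, sel)] @ ri.c_ri
        if tkin_pair_ri is None:
            tkin_pair_ri = c_pair_sel.T @ joint.kin[np.ix_(sel, sel)] @ ri.c_ri
    FF4b = jf2.reconstruct(occ4[OperatorKind.f12_squared])  # (x k|f2|m n)
    t1 = np.einsum("kx,xmln->klmn", tkin_pair_ri, FF4b, optimize=True)
    t2 = np.einsum("lx,xnkm->klmn", tkin_pair_ri, FF4b, optimize=True)
    t3_ = np.einsum("xm,xkln->klmn", tkin_pair_ri.T, FF4b, optimize=True)
    t4 = np.einsum("xn,xlkm->klmn", tkin_pair_ri.T, FF4b, optimize=True)
    gf = occ4[OperatorKind.grad_f12_squared].reconstruct()
    b = 0.5 * (t1 + t2 + t3_ + t4) + gf.transpose(0, 2, 1, 3)

    def act(m, w4):
        return (np.einsum("xy,ykbl->xkbl", m, w4, optimize=True)
                + np.einsum("xkyl,yb->xkbl", w4, m, optimize=True))

    # kinetic P-space corrections: -<fPTf> - <fTPf> + <fPTPf>
    PW = p[:, None, :, None] * F4
    TW = act(tri, F4)
    TPW = act(tri, PW)
    b += (-np.einsum("akbl,ambn->klmn", PW, TW, optimize=True)
          - np.einsum("akbl,ambn->klmn", TW, PW, optimize=True)
          + np.einsum("akbl,ambn->klmn", PW, TPW, optimize=True))
    # non-kinetic Fock content, double-RI: <(Qf) (F-T) (Qf)>
    QW = q[:, None, :, None] * F4
    b += np.einsum("akbl,ambn->klmn", QW, act(fri - tri, QW), optimize=True)
    b = 0.5 * (b + b.transpose(2, 3, 0, 1))
    return F12PairIntermediates(V=v, X=x, B=b, F4=F4, G4=G4, j_f12=jf)


# ---------------------------------------------------------------------------
# Fixed-amplitude pair scalars
# ---------------------------------------------------------------------------

def _pattern(m4: np.ndarray, rows, cols) -> np.ndarray:
    """Contract a pair-space matrix with the fixed-amplitude patterns.

    rows/cols are (i, j) index grids; returns
    (15 M[ij,kl] + 5 M[ij,lk] - 3 M[ji,kl] - M[ji,lk]) / 64
    for row pair (i,j) and column pair (k,l)."""
    i, j = rows
    k, l = cols
    return (15.0 * m4[i, j, k, l] + 5.0 * m4[i, j, l, k]
            - 3.0 * m4[j, i, k, l] - 1.0 * m4[j, i, l, k]) / 64.0


def f12_pair_scalars(inter: F12PairIntermediates,
                     fock_pair: np.ndarray) -> dict:
    """Per-pair scalars V_ij, X_ij, B_ij for the fixed-amplitude energy.

    fock_pair: occupied Fock matrix in the pair-label basis (diagonal orbital
    energies for a canonical reference). The X scalar carries the occupied
    Fock coupling, which makes the B - X combination invariant to occupied
    rotations."""
    n = inter.V.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    v_d = inter.V[i, j, i, j]
    v_x = inter.V[i, j, j, i]
    v_ij = 2.5 * v_d - 0.5 * v_x
    b_ij = 2.0 * _pattern(inter.B, (i, j), (i, j))
    # X couplings: sum_k f_ik P_X(ij; kj) + f_jk P_X(ij; ik)
    x_ij = np.zeros((n, n))
    for k in range(n):
        kk = np.full_like(i, k)
        x_ij += 2.0 * (fock_pair[:, k][:, None] * _pattern(inter.X, (i, j), (kk, j))
                       + fock_pair[:, k][None, :] * _pattern(inter.X, (i, j), (i, kk)))
    return {"V": v_ij, "X": x_ij, "B": b_ij}


# ---------------------------------------------------------------------------
# Coupling intermediate C
# ---------------------------------------------------------------------------

def compute_R(inter: F12PairIntermediates, ri: RISpace) -> np.ndarray:
    """R[a,b,i,j] = sum_{a' in comp} f_aa' (a'i|f|bj) + f_bb' (ai|f|b'j)."""
    fvc = ri.fock[ri.virt, ri.comp]
    f_cv = inter.F4[ri.comp, :, ri.virt, :]     # (ncomp, np, nv, np)
    f_vc = inter.F4[ri.virt, :, ri.comp, :]
    r = np.einsum("ax,xibj->abij", fvc, f_cv, optimize=True)
    r += np.einsum("bx,aixj->abij", fvc, f_vc, optimize=True)
    return r


def compute_C_canonical(inter: F12PairIntermediates, ri: RISpace,
                        eps_occ: np.ndarray, eps_virt: np.ndarray) -> np.ndarray:
    """C_ij by the explicit-denominator coupling formula (canonical basis)."""
    r = compute_R(inter, ri)
    g = inter.G4[ri.virt, :, ri.virt, :].transpose(0, 2, 1, 3)  # (a,b,i,j)
    d = (eps_occ[None, None, :, None] + eps_occ[None, None, None, :]
         - eps_virt[:, None, None, None] - eps_virt[None, :, None, None])
    if np.any(np.abs(d) < 1e-12):
        raise ZeroDivisionError("vanishing denominator in the coupling term")
    amp = r / d
    gx = g.transpose(0, 1, 3, 2)    # (aj|bi) in (a,b,i,j) layout
    rx = r.transpose(0, 1, 3, 2)    # R_{ji}^{ab}
    bracket = 40.0 * g - 8.0 * gx + 7.0 * r + rx
    return np.einsum("abij,abij->ij", bracket, amp, optimize=True) / 16.0


# ---------------------------------------------------------------------------
# Per-extended-domain RI spaces and the local coupling algorithm
# ---------------------------------------------------------------------------

def ed_ri_space(joint: JointSpace, ref: RestrictedReference, ed) -> RISpace:
    """RI orbital space of an extended domain.

    Function set: ED AO functions plus the CABS functions on the CABS-domain
    atoms. Orbitals: [ED core | pseudocanonical occupied | ED virtuals]
    followed by the complementary block (projected CABS functions, augmented
    with projected ED AOs)."""
    import scipy.linalg as sla
    nao = joint.nao
    cabs_atom_of = joint.basis.atom_of_function()[nao:]
    cabs_pos = nao + np.nonzero(np.isin(cabs_atom_of, list(ed.cabs_atoms)))[0]
    sel = np.concatenate([ed.ao_indices, cabs_pos])
    s_sel = joint.s[np.ix_(sel, sel)]
    nsel = len(sel)
    nao_sel = len(ed.ao_indices)

    def lift(c_ao):
        out = np.zeros((nsel, c_ao.shape[1]))
        out[:nao_sel] = c_ao[ed.ao_indices]
        return out

    c_occ = np.concatenate([lift(ed.c_core), lift(ed.c_occ_pseudo)], axis=1)
    c_virt = lift(ed.c_virt)
    cmo = np.concatenate([c_occ, c_virt], axis=1)

    def project_out(cols_idx, block):
        cols = np.zeros((nsel, len(cols_idx)))
        cols[cols_idx, np.arange(len(cols_idx))] = 1.0
        return cols - block @ (block.T @ s_sel[:, cols_idx])

    def lowdin(cols, drop):
        if cols.shape[1] == 0:
            return cols
        sm = cols.T @ s_sel @ cols
        ev, u = sla.eigh(sm)
        keep = ev > drop
        return cols @ (u[:, keep] / np.sqrt(ev[keep]))

    from .cabs import AUG_LOWDIN_DROP, CABS_LOWDIN_DROP
    comp = lowdin(project_out(np.arange(nao_sel, nsel), cmo), CABS_LOWDIN_DROP)
    aug = lowdin(project_out(np.arange(nao_sel), cmo), AUG_LOWDIN_DROP)
    if comp.shape[1] and aug.shape[1]:
        aug = aug - comp @ (comp.T @ s_sel @ aug)
        aug = lowdin(aug, CABS_LOWDIN_DROP)
    c_ri = np.concatenate([cmo, comp, aug], axis=1)
    fock = c_ri.T @ joint.fock[np.ix_(sel, sel)] @ c_ri
    return RISpace(func_idx=sel, c_ri=c_ri, n_occ=c_occ.shape[1],
                   n_virt=c_virt.shape[1], fock=fock)


def lmo_to_pseudo(ed, overlap_ao: np.ndarray) -> np.ndarray:
    """Least-squares transformation from the (truncated) LMO pair labels to
    the pseudocanonical occupied basis of the ED."""
    ct = ed.c_occ_trf
    a = ct.T @ overlap_ao @ ct
    b = ct.T @ overlap_ao @ ed.c_occ_pseudo
    return np.linalg.solve(a, b)


def compute_C_local(ed, ri: RISpace, inter: F12PairIntermediates,
                    u_lmo_ps: np.ndarray, omega: OmegaVectors) -> np.ndarray:
    """Coupling intermediate of the central LMO by the denominator-free local
    algorithm: Fock-transformed fitting coefficients, omega-scaled products,
    and back-transformation of the pseudocanonical index to the CMO.

    Returns C_{i j~} over the pseudocanonical occupied index j~.
    """
    jb = inter.j_f12.J      # Coulomb J over (RI x LMO pairs), (M, np, P)
    kb = inter.j_f12.K      # robust f12 partner
    j_ps = np.einsum("xiP,ij->xjP", jb, u_lmo_ps, optimize=True)
    k_ps = np.einsum("xiP,ij->xjP", kb, u_lmo_ps, optimize=True)
    v, c = ri.virt, ri.comp
    fvc = ri.fock[v, c]
    jv, kv = j_ps[v], k_ps[v]                     # (nv, no, P)
    jbar = np.einsum("ax,xiP->aiP", fvc, j_ps[c], optimize=True)
    kbar = np.einsum("ax,xiP->aiP", fvc, k_ps[c], optimize=True)
    nv, no, npfit = jv.shape
    if omega.vectors.shape[1] != nv * no:
        raise ValueError("omega vector set incompatible with this ED "
                         "(the MP2 and coupling evaluations must share it)")
    w = ed.w_cmo

    def wsum(x):
        return np.einsum("aiP,i->aP", x, w, optimize=True)

    # omega-scaled blocks and their CMO back-transformations
    blocks = {"j": jv, "k": kv, "jbar": jbar, "kbar": kbar}
    bw = {key: apply_omega(val, omega) for key, val in blocks.items()}
    bwi = {key: np.einsum("waiP,i->waP", val, w, optimize=True)
           for key, val in bw.items()}
    r = -(np.einsum("waP,wbjP->abj", bwi["jbar"], bw["k"], optimize=True)
          + np.einsum("waP,wbjP->abj", bwi["kbar"], bw["j"], optimize=True)
          + np.einsum("waP,wbjP->abj", bwi["j"], bw["kbar"], optimize=True)
          + np.einsum("waP,wbjP->abj", bwi["k"], bw["jbar"], optimize=True))
    bi = {key: wsum(val) for key, val in blocks.items()}
    r_d = (np.einsum("aP,bjP->abj", bi["jbar"], kv, optimize=True)
           + np.einsum("aP,bjP->abj", bi["kbar"], jv, optimize=True)
           + np.einsum("aP,bjP->abj", bi["j"], kbar, optimize=True)
           + np.einsum("aP,bjP->abj", bi["k"], jbar, optimize=True))
    r_x = (np.einsum("ajP,bP->abj", jbar, bi["k"], optimize=True)
           + np.einsum("ajP,bP->abj", kbar, bi["j"], optimize=True)
           + np.einsum("ajP,bP->abj", jv, bi["kbar"], optimize=True)
           + np.einsum("ajP,bP->abj", kv, bi["jbar"], optimize=True))
    g_d = np.einsum("aP,bjP->abj", bi["j"], jv, optimize=True)
    g_x = np.einsum("ajP,bP->abj", jv, bi["j"], optimize=True)
    bracket = 40.0 * g_d - 8.0 * g_x + 7.0 * r_d + r_x
    return np.einsum("abj,abj->j", bracket, r, optimize=True) / 16.0
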