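"""Hermite-Gaussian machinery: expansion coefficients, the R-tensor recurrence,
and one-electron integrals (overlap, kinetic, dipole, nuclear attraction)."""
from __future__ import annotations

import math

import numpy as np

from ..basis import BasisSet, Shell, cart_components
from .boys import dn_point_charge


def _dfact(n: int) -> float:
    """(2n-1)!! with (-1)!! = 1."""
    out = 1.0
    for k in range(2 * n - 1, 0, -2):
        out *= k
    return out


def component_norms(shell: Shell) -> np.ndarray:
    """Per-component normalized contraction coefficients, shape (ncomp, nprim)."""
    comps = cart_components(shell.l)
    a = shell.exps
    c = shell.coefs
    # contraction coefficients refer to l-normalized primitives (as for (l,0,0))
    prim_norm = (2 * a / math.pi) ** 0.75 * (4 * a) ** (shell.l / 2.0)
    prim_norm = prim_norm / np.sqrt(_dfact(shell.l))
    out = np.empty((len(comps), len(a)))
    aij = a[:, None] + a[None, :]
    for ic, (lx, ly, lz) in enumerate(comps):
        cc = c * prim_norm
        # self-overlap of the contracted cartesian component
        s = (math.pi / aij) ** 1.5
        for l in (lx, ly, lz):
            s = s * _dfact(l) / (2 * aij) ** l
        out[ic] = cc / math.sqrt(float(cc @ s @ cc))
    return out


def hermite_e(la: int, lb: int, a: np.ndarray, b: np.ndarray, ab: float) -> np.ndarray:
    """Hermite expansion coefficients E[i, j, t, nprimpair] for one direction.

    ab = A - B (scalar component).
    """
    n = len(a)
    p = a + b
    mu = a * b / p
    e = np.zeros((la + 1, lb + 1, la + lb + 1, n))
    e[0, 0, 0] = np.exp(-mu * ab * ab)
    xpa = -(b / p) * ab
    xpb = (a / p) * ab
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                # build from (i-1, 0)
                for t in range(i + 1):
                    val = xpa * e[i - 1, 0, t]
                    if t > 0:
                        val = val + (1.0 / (2 * p)) * e[i - 1, 0, t - 1]
                    if t + 1 <= i - 1:
                        val = val + (t + 1) * e[i - 1, 0, t + 1]
                    e[i, 0, t] = val
            else:
                for t in range(i + j + 1):
                    val = xpb * e[i, j - 1, t]
                    if t > 0:
                        val = val + (1.0 / (2 * p)) * e[i, j - 1, t - 1]
                    if t + 1 <= i + j - 1:
                        val = val + (t + 1) * e[i, j - 1, t + 1]
                    e[i, j, t] = val
    return e


class HermitePair:
    """Hermite representation of a (contracted) shell-pair charge distribution.

    Attributes
    ----------
    p : (np,) combined exponents;  P : (np, 3) combined centers
    E : (ncomp_a*ncomp_b, nt, nu, nv, np) expansion coefficients including
        normalized contraction coefficients.
    """

    def __init__(self, sha: Shell, shb: Shell):
        a, b = sha.exps, shb.exps
        na, nb = len(a), len(b)
        aa = np.repeat(a, nb)
        bb = np.tile(b, na)
        self.p = aa + bb
        self.P = (aa[:, None] * sha.center + bb[:, None] * shb.center) / self.p[:, None]
        self.la, self.lb = sha.l, shb.l
        ca = component_norms(sha)
        cb = component_norms(shb)
        ex = [hermite_e(sha.l, shb.l, aa, bb, sha.center[d] - shb.center[d])
              for d in range(3)]
        compsa = cart_components(sha.l)
        compsb = cart_components(shb.l)
        L = sha.l + shb.l
        nc = len(compsa) * len(compsb)
        E = np.zeros((nc, L + 1, L + 1, L + 1, na * nb))
        cc = np.einsum("ak,bl->abkl", ca, cb).reshape(nc, na, nb).reshape(nc, na * nb)
        idx = 0
        for ia, (ax, ay, az) in enumerate(compsa):
            for ib, (bx, by, bz) in enumerate(compsb):
                exd = ex[0][ax, bx, :ax + bx + 1]  # (t, np)
                eyd = ex[1][ay, by, :ay + by + 1]
                ezd = ex[2][az, bz, :az + bz + 1]
                E[idx, :ax + bx + 1, :ay + by + 1, :az + bz + 1] = (
                    np.einsum("tn,un,vn->tuvn", exd, eyd, ezd) * cc[idx])
                idx += 1
        self.E = E
        self.L = L
        self.ncomp = nc
        self.nprim = na * nb


class HermiteSingle:
    """Hermite representation of a single (auxiliary) shell."""

    def __init__(self, sh: Shell):
        self.p = sh.exps.copy()
        self.P = np.tile(sh.center, (len(sh.exps), 1))
        cn = component_norms(sh)  # (ncomp, nprim)
        comps = cart_components(sh.l)
        L = sh.l
        E = np.zeros((len(comps), L + 1, L + 1, L + 1, len(sh.exps)))
        # x^l at its own center: (x-P) = Hermite/(2p)-combinations; for a single
        # Gaussian the cartesian factor equals the Hermite polynomial expansion
        # with E coefficients from a=exps, b=0 limit: use hermite_e with b=0.
        ex = hermite_e(L, 0, sh.exps, np.zeros_like(sh.exps), 0.0)
        for ic, (lx, ly, lz) in enumerate(comps):
            exd = ex[lx, 0]
            eyd = ex[ly, 0]
            ezd = ex[lz, 0]
            E[ic, :lx + 1, :ly + 1, :lz + 1] = np.einsum(
                "tn,un,vn->tuvn", exd[:lx + 1], eyd[:ly + 1], ezd[:lz + 1]) * cn[ic]
        self.E = E
        self.L = L
        self.ncomp = len(comps)
        self.nprim = len(sh.exps)


def r_tensor(tmax: int, umax: int, vmax: int, dn: np.ndarray, pq: np.ndarray) -> np.ndarray:
    """Hermite R tensor R[t,u,v,batch] by two-level downward recursion.

    dn : (N+1, batch) derivative table (d/dR^2)^n Phi
    pq : (batch, 3) displacement P - Q
    """
    nmax = dn.shape[0] - 1  # highest total Hermite order actually required
    batch = dn.shape[1:]
    x, y, z = pq[..., 0], pq[..., 1], pq[..., 2]
    prev = None
    for n in range(nmax, -1, -1):
        cur = np.zeros((tmax + 1, umax + 1, vmax + 1) + batch)
        cur[0, 0, 0] = (2.0 ** n) * dn[n]
        if prev is not None:
            for t in range(tmax + 1):
                for u in range(umax + 1):
                    for v in range(vmax + 1):
                        if t + u + v == 0 or t + u + v > nmax - n:
                            continue
                        if t > 0:
                            val = x * prev[t - 1, u, v]
                            if t > 1:
                                val = val + (t - 1) * prev[t - 2, u, v]
                        elif u > 0:
                            val = y * prev[t, u - 1, v]
                            if u > 1:
                                val = val + (u - 1) * prev[t, u - 2, v]
                        else:
                            val = z * prev[t, u, v - 1]
                            if v > 1:
                                val = val + (v - 1) * prev[t, u, v - 2]
                        cur[t, u, v] = val
        prev = cur
    return prev


# ---------------------------------------------------------------------------
# One-electron integrals
# ---------------------------------------------------------------------------

def _pair_sp(sha: Shell, shb: Shell):
    a, b = sha.exps, shb.exps
    na, nb = len(a), len(b)
    aa = np.repeat(a, nb)
    bb = np.tile(b, na)
    return aa, bb


def _overlap_block(sha: Shell, shb: Shell, moment: int = 0):
    """Overlap (moment=0) or dipole (moment=1 -> 3 matrices) block."""
    aa, bb = _pair_sp(sha, shb)
    p = aa + bb
    P = (aa[:, None] * sha.center + bb[:, None] * shb.center) / p[:, None]
    ex = [hermite_e(sha.l, shb.l, aa, bb, sha.center[d] - shb.center[d]) for d in range(3)]
    ca = component_norms(sha)
    cb = component_norms(shb)
    cc = np.einsum("ak,bl->abkl", ca, cb)
    cc = cc.reshape(ca.shape[0], cb.shape[0], -1)
    spi = np.sqrt(math.pi / p)
    compsa = cart_components(sha.l)
    compsb = cart_components(shb.l)
    if moment == 0:
        out = np.zeros((len(compsa), len(compsb)))
    else:
        out = np.zeros((3, len(compsa), len(compsb)))
    for ia, ka in enumerate(compsa):
        for ib, kb in enumerate(compsb):
            sdir = [ex[d][ka[d], kb[d], 0] * spi for d in range(3)]
            if moment == 0:
                out[ia, ib] = np.sum(cc[ia, ib] * sdir[0] * sdir[1] * sdir[2])
            else:
                for d in range(3):
                    e0 = ex[d][ka[d], kb[d], 0]
                    e1 = ex[d][ka[d], kb[d], 1] if ka[d] + kb[d] >= 1 else 0.0
                    # <x> picks up the t=0 Hermite times P_x plus the t=1 term
                    mdir = (P[:, d] * e0 + e1) * spi
                    oth = [sdir[dd] for dd in range(3) if dd != d]
                    out[d, ia, ib] = np.sum(cc[ia, ib] * mdir * oth[0] * oth[1])
    return out


def overlap(basis_a: BasisSet, basis_b: BasisSet | None = None) -> np.ndarray:
    bb = basis_b or basis_a
    sa = basis_a.shell_slices()
    sb = bb.shell_slices()
    out = np.zeros((basis_a.nbf, bb.nbf))
    for i, sha in enumerate(basis_a.shells):
        for j, shb in enumerate(bb.shells):
            if basis_b is None and j < i:
                continue
            blk = _overlap_block(sha, shb)
            out[sa[i], sb[j]] = blk
            if basis_b is None and j != i:
                out[sa[j], sb[i]] = blk.T
    return out


def dipole(basis: BasisSet) -> np.ndarray:
    """Dipole (position) integrals, shape (3, nbf, nbf)."""
    ss = basis.shell_slices()
    out = np.zeros((3, basis.nbf, basis.nbf))
    for i, sha in enumerate(basis.shells):
        for j, shb in enumerate(basis.shells):
            if j < i:
                continue
            blk = _overlap_block(sha, shb, moment=1)
            out[:, ss[i], ss[j]] = blk
            if j != i:
                out[:, ss[j], ss[i]] = blk.transpose(0, 2, 1)
    return out


def _kinetic_block(sha: Shell, shb: Shell):
    """Kinetic energy via the raising/lowering relation on shb's exponents."""
    aa, bb = _pair_sp(sha, shb)
    p = aa + bb
    ex = [hermite_e(sha.l, shb.l + 2, aa, bb, sha.center[d] - shb.center[d])
          for d in range(3)]
    ca = component_norms(sha)
    cb = component_norms(shb)
    cc = np.einsum("ak,bl->abkl", ca, cb).reshape(ca.shape[0], cb.shape[0], -1)
    spi = np.sqrt(math.pi / p)
    compsa = cart_components(sha.l)
    compsb = cart_components(shb.l)
    out = np.zeros((len(compsa), len(compsb)))
    for ia, ka in enumerate(compsa):
        for ib, kb in enumerate(compsb):
            s0 = [ex[d][ka[d], kb[d], 0] * spi for d in range(3)]
            tot = np.zeros_like(p)
            for d in range(3):
                j = kb[d]
                term = bb * (2 * j + 1) * ex[d][ka[d], j, 0]
                term = term - 2.0 * bb ** 2 * ex[d][ka[d], j + 2, 0]
                if j >= 2:
                    term = term - 0.5 * j * (j - 1) * ex[d][ka[d], j - 2, 0]
                term = term * spi
                oth = [s0[dd] for dd in range(3) if dd != d]
                tot = tot + term * oth[0] * oth[1]
            out[ia, ib] = np.sum(cc[ia, ib] * tot)
    return out


def kinetic(basis: BasisSet) -> np.ndarray:
    ss = basis.shell_slices()
    out = np.zeros((basis.nbf, basis.nbf))
    for i, sha in enumerate(basis.shells):
        for j, shb in enumerate(basis.shells):
            if j < i:
                continue
            blk = _kinetic_block(sha, shb)
            out[ss[i], ss[j]] = blk
            if j != i:
                out[ss[j], ss[i]] = blk.T
    return out


def nuclear_attraction(basis: BasisSet, molecule=None) -> np.ndarray:
    mol = molecule or basis.molecule
    charges = mol.charges
    centers = mol.coords
    ss = basis.shell_slices()
    out = np.zeros((basis.nbf, basis.nbf))
    for i, sha in enumerate(basis.shells):
        for j, shb in enumerate(basis.shells):
            if j < i:
                continue
            hp = HermitePair(sha, shb)
            L = hp.L
            # batch: prim-pairs x atoms
            pq = hp.P[:, None, :] - centers[None, :, :]
            r2 = np.sum(pq * pq, axis=-1)
            pcol = hp.p[:, None] * np.ones(len(charges))[None, :]
            dn = dn_point_charge(L, pcol, r2)
            R = r_tensor(L, L, L, dn, pq)  # (t,u,v,np,natom)
            Rz = np.tensordot(R, -charges, axes=([-1], [0]))  # sum over atoms
            blk = np.einsum("ctuvn,tuvn->c", hp.E, Rz).reshape(sha.ncart, shb.ncart)
            out[ss[i], ss[j]] = blk
            if j != i:
                out[ss[j], ss[i]] = blk.T
    return out
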