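"""Two-electron integrals over generalized kernels (Coulomb, Gaussian geminal,
Gaussian/r) for two-, three- and four-center cases.

Operators are supplied as lists of kernel terms (coef, family, omega); the
kernel derivative tables are additive, so a single Hermite R-tensor pass
serves an entire contracted operator (e.g. a 6-term geminal expansion).
"""
from __future__ import annotations

import math

import numpy as np

from ..basis import BasisSet
from .boys import dn_coulomb, dn_gauss, dn_gauss_r
from .mcmurchie import HermitePair, HermiteSingle, r_tensor

SCREEN_THRESHOLD = 1e-12


def _dn_total(terms, nmax, p, q, r2):
    dn = None
    for coef, family, omega in terms:
        if family == "coulomb":
            d = dn_coulomb(nmax, p, q, r2)
        elif family == "gauss":
            d = dn_gauss(nmax, p, q, r2, omega)
        elif family == "gauss_r":
            d = dn_gauss_r(nmax, p, q, r2, omega)
        else:
            raise ValueError(f"unknown kernel family {family!r}")
        dn = coef * d if dn is None else dn + coef * d
    return dn


def _nonzero_keys(E):
    """Keys (t,u,v) where any component/primitive of E is nonzero."""
    nz = np.nonzero(np.any(np.abs(E) > 0, axis=(0, 4)))
    return list(zip(*nz))


class _KetGroup:
    """All Hermite distributions of equal (Lmax) batched together."""

    def __init__(self, dists, offsets, ncomps):
        self.L = max(d.L for d in dists)
        self.q = np.concatenate([d.p for d in dists])
        self.Q = np.vstack([d.P for d in dists])
        self.offsets = offsets          # function offsets in the output
        self.ncomps = ncomps
        nk = len(self.q)
        ck = sum(ncomps)
        self.Ek = {}
        ip = 0
        ic = 0
        for d in dists:
            for key in _nonzero_keys(d.E):
                t, u, v = key
                mat = self.Ek.setdefault(key, np.zeros((ck, nk)))
                mat[ic:ic + d.ncomp, ip:ip + d.nprim] = d.E[:, t, u, v, :]
            ip += d.nprim
            ic += d.ncomp
        self.nk = nk
        self.ck = ck


def _contract(hp: HermitePair, group: _KetGroup, terms) -> np.ndarray:
    """Integral block (ncomp_bra, ck) of <bra-pair | op | ket-group>."""
    Lb, Lk = hp.L, group.L
    N = Lb + Lk
    pq = hp.P[:, None, :] - group.Q[None, :, :]
    r2 = np.sum(pq * pq, axis=-1)
    p = hp.p[:, None] * np.ones(group.nk)[None, :]
    q = np.ones(hp.nprim)[:, None] * group.q[None, :]
    dn = _dn_total(terms, N, p, q, r2)
    R = r_tensor(N, N, N, dn, pq)          # (N+1,N+1,N+1,nb,nk)
    acc = np.zeros((Lb + 1, Lb + 1, Lb + 1, hp.nprim, group.ck))
    for (t, u, v), Ek in group.Ek.items():
        sign = -1.0 if (t + u + v) % 2 else 1.0
        Rs = R[t:t + Lb + 1, u:u + Lb + 1, v:v + Lb + 1]
        acc += sign * np.tensordot(Rs, Ek, axes=([-1], [-1]))
    return np.einsum("ctuvn,tuvnk->ck", hp.E, acc, optimize=True)


def _pair_list(basis: BasisSet, screen: bool = True):
    """Shell-pair (i<=j) list with HermitePair objects and crude magnitude bound."""
    out = []
    for i, sha in enumerate(basis.shells):
        for j in range(i, basis.nshell):
            shb = basis.shells[j]
            if screen:
                d2 = float(np.sum((sha.center - shb.center) ** 2))
                mu = sha.exps.min() * shb.exps.min() / (sha.exps.min() + shb.exps.min())
                if math.exp(-mu * d2) < SCREEN_THRESHOLD:
                    continue
            out.append((i, j, HermitePair(sha, shb)))
    return out


def two_center(aux: BasisSet, terms) -> np.ndarray:
    """(P |op| Q) over an auxiliary basis."""
    singles = [HermiteSingle(sh) for sh in aux.shells]
    sl = aux.shell_slices()
    out = np.zeros((aux.nbf, aux.nbf))
    group = _KetGroup(singles, [s.start for s in sl], [d.ncomp for d in singles])
    for i, sh in enumerate(aux.shells):
        # bra as a one-sided Hermite pair: reuse HermiteSingle in bra position
        d = singles[i]
        hp_like = d
        blk = _contract_single_bra(d, group, terms)
        out[sl[i]] = blk
    return 0.5 * (out + out.T)


def _contract_single_bra(d: HermiteSingle, group: _KetGroup, terms) -> np.ndarray:
    Lb, Lk = d.L, group.L
    N = Lb + Lk
    pq = d.P[:, None, :] - group.Q[None, :, :]
    r2 = np.sum(pq * pq, axis=-1)
    p = d.p[:, None] * np.ones(group.nk)[None, :]
    q = np.ones(len(d.p))[:, None] * group.q[None, :]
    dn = _dn_total(terms, N, p, q, r2)
    R = r_tensor(N, N, N, dn, pq)
    acc = np.zeros((Lb + 1, Lb + 1, Lb + 1, len(d.p), group.ck))
    for (t, u, v), Ek in group.Ek.items():
        sign = -1.0 if (t + u + v) % 2 else 1.0
        Rs = R[t:t + Lb + 1, u:u + Lb + 1, v:v + Lb + 1]
        acc += sign * np.tensordot(Rs, Ek, axes=([-1], [-1]))
    return np.einsum("ctuvn,tuvnk->ck", d.E, acc, optimize=True)


def three_center(bra: BasisSet, ket: BasisSet, aux: BasisSet, terms,
                 screen: bool = True) -> np.ndarray:
    """(mu nu |op| P): mu in `bra`, nu in `ket`, P auxiliary.

    If bra is ket (same object), only the triangle is computed and mirrored.
    """
    same = bra is ket
    singles = [HermiteSingle(sh) for sh in aux.shells]
    sl_aux = aux.shell_slices()
    group = _KetGroup(singles, [s.start for s in sl_aux], [d.ncomp for d in singles])
    sl_b = bra.shell_slices()
    sl_k = ket.shell_slices()
    out = np.zeros((bra.nbf, ket.nbf, aux.nbf))
    for i, sha in enumerate(bra.shells):
        jstart = i if same else 0
        for j in range(jstart, ket.nshell):
            shb = ket.shells[j]
            if screen:
                d2 = float(np.sum((sha.center - shb.center) ** 2))
                mn = sha.exps.min() * shb.exps.min() / (sha.exps.min() + shb.exps.min())
                if math.exp(-mn * d2) < SCREEN_THRESHOLD:
                    continue
            hp = HermitePair(sha, shb)
            blk = _contract(hp, group, terms)  # (ncomp_pair, nbf_aux)
            blk = blk.reshape(sha.ncart, shb.ncart, aux.nbf)
            out[sl_b[i], sl_k[j]] = blk
            if same and j != i:
                out[sl_b[j], sl_k[i]] = blk.transpose(1, 0, 2)
    return out


def four_center(basis: BasisSet, terms, max_nbf: int = 130) -> np.ndarray:
    """Exact four-index tensor (pq|op|rs); test oracle for small bases only."""
    if basis.nbf > max_nbf:
        raise ValueError(f"four_center oracle limited to {max_nbf} functions "
                         f"(requested {basis.nbf})")
    pairs = _pair_list(basis, screen=False)
    sl = basis.shell_slices()
    n = basis.nbf
    out = np.zeros((n, n, n, n))
    for a in range(len(pairs)):
        i, j, hpa = pairs[a]
        for b in range(a, len(pairs)):
            k, l, hpb = pairs[b]
            group = _KetGroup([hpb], [0], [hpb.ncomp])
            blk = _contract(hpa, group, terms)
            blk = blk.reshape(basis.shells[i].ncart, basis.shells[j].ncart,
                              basis.shells[k].ncart, basis.shells[l].ncart)
            _scatter_4c(out, blk, sl[i], sl[j], sl[k], sl[l])
    return out


def _scatter_4c(out, blk, si, sj, sk, sl_):
    out[si, sj, sk, sl_] = blk
    out[sj, si, sk, sl_] = blk.transpose(1, 0, 2, 3)
    out[si, sj, sl_, sk] = blk.transpose(0, 1, 3, 2)
    out[sj, si, sl_, sk] = blk.transpose(1, 0, 3, 2)
    out[sk, sl_, si, sj] = blk.transpose(2, 3, 0, 1)
    out[sl_, sk, si, sj] = blk.transpose(3, 2, 0, 1)
    out[sk, sl_, sj, si] = blk.transpose(2, 3, 1, 0)
    out[sl_, sk, sj, si] = blk.transpose(3, 2, 1, 0)
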