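"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's Hermite/DF code paths: radial
quadrature for s-type two-electron integrals, explicit dense four-index
evaluations, and explicit-loop energy formulas.
"""
import math

import numpy as np
from scipy.integrate import quad


def eri_s_quadrature(a, A, b, B, c, C, d, D, kernel):
    """(ab|K|cd) for four normalized s-type primitives via radial quadrature."""
    A, B, C, D = map(np.asarray, (A, B, C, D))
    p, q = a + b, c + d
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    pre = math.exp(-a * b / p * float(np.sum((A - B) ** 2)))
    pre *= math.exp(-c * d / q * float(np.sum((C - D) ** 2)))
    rho = p * q / (p + q)
    R = float(np.linalg.norm(P - Q))
    norm = ((2 * a / math.pi) * (2 * b / math.pi)
            * (2 * c / math.pi) * (2 * d / math.pi)) ** 0.75
    if R < 1e-10:
        f = lambda r: 4 * math.pi * r * r * kernel(r) * math.exp(-rho * r * r)
    else:
        f = lambda r: (2 * math.pi * r * kernel(r) / (rho * R)
                       * math.exp(-rho * (r * r + R * R))
                       * math.sinh(2 * rho * r * R))
    val = quad(f, 0, 40, limit=400)[0]
    return norm * pre * (math.pi ** 2 / (p * q)) ** 1.5 \
        * (rho / math.pi) ** 1.5 * val


def threec_s_quadrature(a, A, b, B, c, C, kernel):
    """(ab|K|c) with a single normalized s-type auxiliary function."""
    A, B, C = map(np.asarray, (A, B, C))
    p = a + b
    P = (a * A + b * B) / p
    pre = math.exp(-a * b / p * float(np.sum((A - B) ** 2)))
    q = c
    Q = C
    rho = p * q / (p + q)
    R = float(np.linalg.norm(P - Q))
    norm = ((2 * a / math.pi) * (2 * b / math.pi)) ** 0.75 \
        * (2 * c / math.pi) ** 0.75
    if R < 1e-10:
        f = lambda r: 4 * math.pi * r * r * kernel(r) * math.exp(-rho * r * r)
    else:
        f = lambda r: (2 * math.pi * r * kernel(r) / (rho * R)
                       * math.exp(-rho * (r * r + R * R))
                       * math.sinh(2 * rho * r * R))
    val = quad(f, 0, 40, limit=400)[0]
    return norm * pre * (math.pi ** 2 / (p * q)) ** 1.5 \
        * (rho / math.pi) ** 1.5 * val


def mp2_dense_oracle(ref, eri_mo=None, frozen_core=True):
    """Explicit four-index, explicit-denominator MP2 from a dense MO ERI
    tensor (Mulliken order)."""
    from lmp2f12.integrals.twoelectron import four_center
    n0 = ref.n_core if frozen_core else 0
    c = ref.mo_coefficients
    if eri_mo is None:
        eri = four_center(ref.basis, [(1.0, "coulomb", None)])
        eri_mo = np.einsum("pqrs,pa,qb,rc,sd->abcd", eri, c, c, c, c,
                           optimize=True)
    no, nv = ref.n_occ, ref.nmo - ref.n_occ
    e = 0.0
    eps = ref.orbital_energies
    for i in range(n0, no):
        for j in range(n0, no):
            for a in range(no, ref.nmo):
                for b in range(no, ref.nmo):
                    g = eri_mo[a, i, b, j]
                    gx = eri_mo[a, j, b, i]
                    d = eps[i] + eps[j] - eps[a] - eps[b]
                    e += (2 * g - gx) * g / d
    return e


def mp2_df_denominator_oracle(ref, j_ov):
    """Explicit-denominator MP2 from *fitted* integrals (isolates the
    denominator treatment from the fitting error)."""
    eo = ref.orbital_energies[ref.n_core:ref.n_occ]
    ev = ref.orbital_energies[ref.n_occ:]
    g = np.einsum("iaP,jbP->iajb", j_ov, j_ov, optimize=True)
    d = (eo[:, None, None, None] - ev[None, :, None, None]
         + eo[None, None, :, None] - ev[None, None, None, :])
    return float(np.einsum("iajb,iajb->",
                           2 * g - np.einsum("iajb->ibja", g), g / d,
                           optimize=True))
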