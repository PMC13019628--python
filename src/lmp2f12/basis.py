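"""Gaussian basis sets generated at run time.

No external basis-set data files are shipped. Three kinds of named sets are
provided, all built programmatically:

* ``min``   - STO-3G-style minimal sets: contractions of 3 primitives fitted by
              least squares to Slater orbitals with Slater-rule exponents.
* ``svp-d`` / ``svp-t`` - small split-valence sets: the minimal contractions
              augmented with uncontracted valence and polarization shells
              (double- and triple-zeta-like; these carry the DZ/TZ cardinal tag
              that selects the default geminal exponent).
* ``ref-large`` - a large uncontracted even-tempered set used as a basis-set
              limit reference in convergence studies.

Auxiliary (density-fitting) and CABS source sets are generated from the
orbital basis by even-tempered rules (`autoaux`, `cabs_source`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.special import gamma as _gamma

from .elements import ATOMIC_NUMBER
from .molecule import Molecule

ANGMOM = {"s": 0, "p": 1, "d": 2, "f": 3, "g": 4}


def ncart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def cart_components(l: int):
    """Cartesian exponent triples in canonical (lexicographic-descending) order."""
    out = []
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            out.append((lx, ly, l - lx - ly))
    return out


@dataclass
class Shell:
    l: int
    exps: np.ndarray
    coefs: np.ndarray          # contraction coefficients (unnormalized primitives)
    center: np.ndarray         # bohr
    atom: int                  # atom index in the molecule

    def __post_init__(self):
        self.exps = np.asarray(self.exps, dtype=float)
        self.coefs = np.asarray(self.coefs, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    @property
    def ncart(self) -> int:
        return ncart(self.l)


@dataclass
class BasisSet:
    molecule: Molecule
    shells: list[Shell]
    name: str = ""

    @property
    def nbf(self) -> int:
        return sum(sh.ncart for sh in self.shells)

    @property
    def nshell(self) -> int:
        return len(self.shells)

    def shell_slices(self):
        out, off = [], 0
        for sh in self.shells:
            out.append(slice(off, off + sh.ncart))
            off += sh.ncart
        return out

    def atom_of_function(self) -> np.ndarray:
        return np.concatenate([[sh.atom] * sh.ncart for sh in self.shells]).astype(int)

    def functions_on_atoms(self, atoms) -> np.ndarray:
        aset = set(int(a) for a in atoms)
        return np.array([i for i, a in enumerate(self.atom_of_function()) if a in aset],
                        dtype=int)

    def restrict_to_atoms(self, atoms):
        """Sub-basis of shells centered on the given atoms.

        Returns (sub_basis, function_indices) where function_indices maps the
        sub-basis AO ordering into this basis's AO ordering.
        """
        aset = set(int(a) for a in atoms)
        shells, idx = [], []
        off = 0
        for sh in self.shells:
            if sh.atom in aset:
                shells.append(sh)
                idx.extend(range(off, off + sh.ncart))
            off += sh.ncart
        return (BasisSet(self.molecule, shells, name=f"{self.name}|atoms"),
                np.array(idx, dtype=int))

    def __add__(self, other: "BasisSet") -> "BasisSet":
        if other.molecule is not self.molecule and other.molecule.natom != self.molecule.natom:
            raise ValueError("cannot join bases on different molecules")
        return BasisSet(self.molecule, self.shells + other.shells,
                        name=f"{self.name}+{other.name}")


# ---------------------------------------------------------------------------
# Slater-orbital fits (STO-3G-like minimal sets, no tabulated data)
# ---------------------------------------------------------------------------

# Slater-rule orbital exponents for the supported elements
_SLATER_ZETA = {
    "H": {"1s": 1.24},
    "He": {"1s": 1.69},
    "Li": {"1s": 2.69, "2sp": 0.80},
    "Be": {"1s": 3.68, "2sp": 1.15},
    "B": {"1s": 4.68, "2sp": 1.45},
    "C": {"1s": 5.67, "2sp": 1.625},
    "N": {"1s": 6.67, "2sp": 1.95},
    "O": {"1s": 7.66, "2sp": 2.275},
    "F": {"1s": 8.65, "2sp": 2.60},
    "Ne": {"1s": 9.64, "2sp": 2.925},
}


def _slater_radial(n: int, zeta: float, r: np.ndarray) -> np.ndarray:
    norm = (2 * zeta) ** (n + 0.5) / math.sqrt(_gamma(2 * n + 1))
    return norm * r ** (n - 1) * np.exp(-zeta * r)


def _gauss_radial(l: int, alpha: np.ndarray, r: np.ndarray) -> np.ndarray:
    # normalized radial part of an l-type Gaussian, one row per exponent
    a = np.asarray(alpha)[:, None]
    norm = (2 * (2 * a) ** (l + 1.5) / _gamma(l + 1.5)) ** 0.5
    return norm * r[None, :] ** l * np.exp(-a * r[None, :] ** 2)


@lru_cache(maxsize=None)
def fit_sto_ng(n: int, l: int, zeta: float, ng: int = 3):
    """Least-squares fit of ng Gaussians to a Slater orbital R_{nl}(zeta).

    Exponents are optimized (log parametrization); contraction coefficients come
    from the linear normal equations at each step. Fitting is done for zeta=1
    and scaled: alpha(zeta) = zeta^2 * alpha(1).
    """
    r = np.linspace(1e-4, 12.0, 600)
    w = r ** 2
    target = _slater_radial(n, 1.0, r)

    def resid(logal):
        g = _gauss_radial(l, np.exp(logal), r)
        A = (g * w) @ g.T
        b = (g * w) @ target
        c = np.linalg.solve(A, b)
        return c, (c @ g - target)

    def obj(logal):
        _, d = resid(logal)
        return float(np.sum(w * d * d))

    x0 = np.log(np.geomspace(0.06, 10.0 * 3 ** (ng - 3), ng) * (1.0 if n == 1 else 0.25))
    best = minimize(obj, x0, method="Nelder-Mead",
                    options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
    c, _ = resid(best.x)
    alphas = np.exp(best.x) * zeta ** 2
    # coefficients refer to *normalized* primitives of the scaled exponents
    return alphas, np.array(c)


def _minimal_shells(symbol: str):
    """(n, l, zeta) shell list for a minimal set."""
    z = ATOMIC_NUMBER[symbol]
    zt = _SLATER_ZETA[symbol]
    shells = [(1, 0, zt["1s"])]
    if z > 2:
        shells.append((2, 0, zt["2sp"]))
        shells.append((2, 1, zt["2sp"]))
    return shells


# ---------------------------------------------------------------------------
# Even-tempered valence / polarization augmentation
# ---------------------------------------------------------------------------

# per element: extra uncontracted shells for the DZ-like family: (l, exponent)
_SVP_D_EXTRA = {
    "H": [(0, 0.55), (0, 0.17), (1, 0.80)],
    "He": [(0, 0.95), (0, 0.30), (1, 1.25)],
    "Li": [(0, 0.045), (1, 0.10), (2, 0.20)],
    "Be": [(0, 0.08), (1, 0.18), (2, 0.32)],
    "B": [(0, 0.75), (0, 0.12), (1, 0.72), (1, 0.11), (2, 0.45)],
    "C": [(0, 0.90), (0, 0.16), (1, 0.85), (1, 0.15), (2, 0.60)],
    "N": [(0, 1.00), (0, 0.21), (1, 0.93), (1, 0.19), (2, 0.85)],
    "O": [(0, 1.05), (0, 0.26), (1, 1.00), (1, 0.23), (2, 1.15)],
    "F": [(0, 1.15), (0, 0.32), (1, 1.10), (1, 0.28), (2, 1.45)],
    "Ne": [(0, 1.30), (0, 0.38), (1, 1.25), (1, 0.33), (2, 1.80)],
}

# lean split-valence family (no polarization): cheap enough for chain scans
_SV_EXTRA = {
    "H": [(0, 0.20)],
    "He": [(0, 0.35)],
    "Li": [(0, 0.045)],
    "Be": [(0, 0.08)],
    "B": [(0, 0.12), (1, 0.11)],
    "C": [(0, 0.16), (1, 0.15)],
    "N": [(0, 0.21), (1, 0.19)],
    "O": [(0, 0.26), (1, 0.23)],
    "F": [(0, 0.32), (1, 0.28)],
    "Ne": [(0, 0.38), (1, 0.33)],
}

# additional shells stacked on top of svp-d for the TZ-like family
_SVP_T_EXTRA = {
    "H": [(1, 0.25), (2, 1.0)],
    "He": [(1, 0.42), (2, 1.6)],
    "C": [(0, 0.50), (1, 0.47), (2, 0.20), (3, 0.85)],
    "N": [(0, 0.65), (1, 0.60), (2, 0.28), (3, 1.10)],
    "O": [(0, 0.80), (1, 0.73), (2, 0.36), (3, 1.40)],
    "F": [(0, 0.98), (1, 0.88), (2, 0.45), (3, 1.70)],
    "Ne": [(0, 1.17), (1, 1.04), (2, 0.55), (3, 2.05)],
}

# large uncontracted even-tempered reference sets (basis-limit studies)
def _ref_large_shells(symbol: str):
    z = ATOMIC_NUMBER[symbol]
    if z <= 2:
        zeta = _SLATER_ZETA[symbol]["1s"]
        return ([(0, e) for e in np.geomspace(0.045 * zeta ** 2, 900.0 * zeta ** 2 / 1.24 ** 2, 10)]
                + [(1, e) for e in np.geomspace(0.25, 12.0, 5)]
                + [(2, e) for e in np.geomspace(0.5, 5.0, 3)])
    zv = _SLATER_ZETA[symbol]["2sp"]
    return ([(0, e) for e in np.geomspace(0.055 * zv ** 2, 9.0e4, 12)]
            + [(1, e) for e in np.geomspace(0.05 * zv ** 2, 60.0 * zv ** 2, 8)]
            + [(2, e) for e in np.geomspace(0.22, 4.5, 4)]
            + [(3, e) for e in np.geomspace(0.5, 2.2, 2)])


_CARDINAL = {"min": None, "sv": None, "svp-d": "DZ", "svp-t": "TZ",
             "ref-large": None}


def basis_cardinal(name: str):
    """DZ/TZ/QZ cardinal tag of a named family (None if it has no cardinal)."""
    return _CARDINAL.get(name)


def build_basis(molecule: Molecule, name: str = "svp-d") -> BasisSet:
    shells: list[Shell] = []
    for ia, sym in enumerate(molecule.symbols):
        center = molecule.coords[ia]
        if name in ("min", "sv", "svp-d", "svp-t"):
            for n, l, zeta in _minimal_shells(sym):
                # a 6-term core fit keeps the heavy-atom 1s cusp region honest
                ng = 6 if (name != "min" and n == 1 and ATOMIC_NUMBER[sym] > 2) else 3
                al, c = fit_sto_ng(n, l, zeta, ng)
                shells.append(Shell(l, al, c, center, ia))
            if name == "sv":
                for l, e in _SV_EXTRA[sym]:
                    shells.append(Shell(l, [e], [1.0], center, ia))
            if name in ("svp-d", "svp-t"):
                for l, e in _SVP_D_EXTRA[sym]:
                    shells.append(Shell(l, [e], [1.0], center, ia))
            if name == "svp-t":
                for l, e in _SVP_T_EXTRA[sym]:
                    shells.append(Shell(l, [e], [1.0], center, ia))
        elif name == "ref-large":
            for l, e in _ref_large_shells(sym):
                shells.append(Shell(l, [e], [1.0], center, ia))
        else:
            raise ValueError(f"unknown basis family {name!r}")
    return BasisSet(molecule, shells, name=name)


def build_basis_from_shells(molecule: Molecule, spec: dict[str, list], name="custom") -> BasisSet:
    """spec: {element: [(l, [exps], [coefs]), ...]} with l as int or letter."""
    shells = []
    for ia, sym in enumerate(molecule.symbols):
        for item in spec[sym]:
            l, exps, coefs = item
            if isinstance(l, str):
                l = ANGMOM[l.lower()]
            shells.append(Shell(l, exps, coefs, molecule.coords[ia], ia))
    return BasisSet(molecule, shells, name=name)


# ---------------------------------------------------------------------------
# Auxiliary (RI) and CABS-source generators
# ---------------------------------------------------------------------------

def autoaux(basis: BasisSet, beta: float = 2.6, l_cap: int = 4,
            other: BasisSet | None = None) -> BasisSet:
    """Even-tempered fitting basis spanning a product-density exponent range.

    For each atom and each auxiliary angular momentum allowed by the product
    rules, primitives form a geometric series between the smallest and largest
    product exponents of that atom's shells. With `other` given, products of
    `basis` x `other` shells are covered (used for the explicitly correlated
    integrals, whose bra functions include the CABS set); otherwise products
    of `basis` with itself.
    """
    def shells_by_atom(b):
        d: dict[int, list[Shell]] = {}
        for sh in b.shells:
            d.setdefault(sh.atom, []).append(sh)
        return d

    bra_atoms = shells_by_atom(basis)
    ket_atoms = shells_by_atom(other) if other is not None else bra_atoms
    shells = []
    for ia in sorted(bra_atoms):
        bsh = bra_atoms[ia]
        ksh = ket_atoms.get(ia, bsh)
        e1_by_l: dict[int, list[float]] = {}
        for sh in bsh:
            e1_by_l.setdefault(sh.l, []).extend(sh.exps.tolist())
        e2_by_l: dict[int, list[float]] = {}
        for sh in ksh:
            e2_by_l.setdefault(sh.l, []).extend(sh.exps.tolist())
        lmax_pair = max(e1_by_l) + max(e2_by_l)
        center = bsh[0].center
        for laux in range(0, min(lmax_pair, l_cap) + 1):
            lo, hi = [], []
            for l1, e1 in e1_by_l.items():
                for l2, e2 in e2_by_l.items():
                    if abs(l1 - l2) <= laux <= l1 + l2:
                        lo.append(min(e1) + min(e2))
                        hi.append(max(e1) + max(e2))
            if not lo:
                continue
            emin, emax = min(lo) * 0.8, max(hi)
            # limit extremely tight functions for high l: they contribute nothing
            if laux >= 1:
                emax = min(emax, 4e3)
            n = max(1, int(math.ceil(math.log(emax / emin) / math.log(beta))) + 1)
            for e in np.geomspace(emin, emax, n):
                shells.append(Shell(laux, [e], [1.0], center, ia))
    return BasisSet(basis.molecule, shells, name=f"autoaux({basis.name})")


def cabs_source(basis: BasisSet, beta: float = 2.4, l_extra: int = 1, l_cap: int = 3) -> BasisSet:
    """Even-tempered CABS source set: denser than the orbital basis, one unit of
    angular momentum higher (the complementary construction later projects out
    the orbital space)."""
    by_atom: dict[int, list[Shell]] = {}
    for sh in basis.shells:
        by_atom.setdefault(sh.atom, []).append(sh)
    shells = []
    for ia, atom_shells in sorted(by_atom.items()):
        lmax = max(sh.l for sh in atom_shells)
        all_exps = np.concatenate([sh.exps for sh in atom_shells])
        center = atom_shells[0].center
        for l in range(0, min(lmax + l_extra, l_cap) + 1):
            emin = float(all_exps.min()) * 0.45
            emax = float(all_exps.max()) * (1.8 if l == 0 else 0.35)
            emax = max(emax, emin * beta ** 2)
            n = max(2, int(math.ceil(math.log(emax / emin) / math.log(beta))) + 1)
            n = min(n, {0: 5, 1: 4, 2: 3}.get(l, 2))
            for e in np.geomspace(emin, emax, n):
                shells.append(Shell(l, [e], [1.0], center, ia))
    return BasisSet(basis.molecule, shells, name=f"cabs({basis.name})")
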