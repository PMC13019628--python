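"""Molecular geometries: XYZ parsing/writing and deterministic test-system generators.

XYZ files carry angstrom coordinates; a `Molecule` stores bohr.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .elements import ATOMIC_NUMBER, n_core_orbitals
from .units import ANGSTROM_PER_BOHR, BOHR_PER_ANGSTROM


@dataclass
class Molecule:
    symbols: list[str]
    coords: np.ndarray  # (natom, 3), bohr
    charge: int = 0
    comment: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.symbols) != self.coords.shape[0]:
            raise ValueError("symbol/coordinate count mismatch")
        for s in self.symbols:
            if s not in ATOMIC_NUMBER:
                raise ValueError(f"unsupported element {s!r}")

    @property
    def natom(self) -> int:
        return len(self.symbols)

    @property
    def charges(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER[s] for s in self.symbols], dtype=float)

    @property
    def n_electrons(self) -> int:
        return int(self.charges.sum()) - self.charge

    @property
    def n_core(self) -> int:
        return sum(n_core_orbitals(ATOMIC_NUMBER[s]) for s in self.symbols)

    def nuclear_repulsion(self) -> float:
        z = self.charges
        e = 0.0
        for i in range(self.natom):
            for j in range(i + 1, self.natom):
                e += z[i] * z[j] / np.linalg.norm(self.coords[i] - self.coords[j])
        return e

    def translated(self, shift) -> "Molecule":
        return Molecule(list(self.symbols), self.coords + np.asarray(shift), self.charge)

    def rotated(self, rotmat) -> "Molecule":
        rot = np.asarray(rotmat)
        return Molecule(list(self.symbols), self.coords @ rot.T, self.charge)

    # ---- XYZ I/O (angstrom on disk) ----
    @classmethod
    def from_xyz(cls, text_or_path) -> "Molecule":
        try:
            text = open(text_or_path).read()
        except (OSError, ValueError):
            text = str(text_or_path)
        lines = text.strip().splitlines()
        natom = int(lines[0].split()[0])
        comment = lines[1] if len(lines) > 1 else ""
        symbols, coords = [], []
        for line in lines[2:2 + natom]:
            parts = line.split()
            symbols.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        return cls(symbols, np.array(coords) * BOHR_PER_ANGSTROM, comment=comment)

    def to_xyz(self) -> str:
        out = [str(self.natom), self.comment]
        for s, xyz in zip(self.symbols, self.coords * ANGSTROM_PER_BOHR):
            out.append(f"{s:2s} {xyz[0]:18.12f} {xyz[1]:18.12f} {xyz[2]:18.12f}")
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Deterministic fixture geometries
# ---------------------------------------------------------------------------

_R_OH = 0.9572          # angstrom
_A_HOH = math.radians(104.52)
_R_CC = 1.526
_R_CH = 1.094
_A_TET = math.radians(109.471)


def water_monomer() -> Molecule:
    """Single water in the xz plane, O at the origin, C2v axis along +x."""
    h = _R_OH * BOHR_PER_ANGSTROM
    a = _A_HOH / 2
    coords = np.array([
        [0.0, 0.0, 0.0],
        [h * math.cos(a), 0.0, h * math.sin(a)],
        [h * math.cos(a), 0.0, -h * math.sin(a)],
    ])
    return Molecule(["O", "H", "H"], coords, comment="water")


def water_chain(n: int, spacing: float = 2.85, seed: int = 0, jitter: float = 0.0) -> Molecule:
    """Hydrogen-bond-spaced chain of n waters along x.

    spacing is the O...O distance in angstrom; each donor O-H points at the
    next oxygen. An optional deterministic jitter (angstrom rms) breaks
    symmetry reproducibly for a given seed.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    rng = np.random.default_rng(seed)
    symbols: list[str] = []
    coords: list[list[float]] = []
    for k in range(n):
        ox = k * spacing
        # donor H toward the next O (along +x), second H splayed off-axis
        symbols += ["O", "H", "H"]
        coords.append([ox, 0.0, 0.0])
        coords.append([ox + _R_OH, 0.0, 0.0])
        a = _A_HOH
        # alternate the free H above/below the axis for a realistic zig-zag
        sgn = 1.0 if k % 2 == 0 else -1.0
        coords.append([ox + _R_OH * math.cos(a), 0.0, sgn * _R_OH * math.sin(a)])
    arr = np.array(coords)
    if jitter > 0:
        arr = arr + rng.normal(scale=jitter, size=arr.shape)
    return Molecule(symbols, arr * BOHR_PER_ANGSTROM, comment=f"water_chain n={n} seed={seed}")


def alkane(n: int) -> Molecule:
    """All-trans n-alkane C_nH_{2n+2}; n=1 gives methane."""
    if n < 1:
        raise ValueError("n >= 1 required")
    half = _A_TET / 2
    dx = _R_CC * math.sin(half)
    dz = _R_CC * math.cos(half)
    carbons = [np.array([k * dx, 0.0, (k % 2) * dz]) for k in range(n)]
    symbols: list[str] = []
    coords: list[np.ndarray] = []

    def ch_dirs(up: bool):
        # two C-H directions perpendicular to the backbone plane, tetrahedral
        s = 1.0 if up else -1.0
        a = math.cos(_A_TET / 2)
        b = math.sin(_A_TET / 2)
        return [np.array([0.0, b, s * a]), np.array([0.0, -b, s * a])]

    for k, c in enumerate(carbons):
        symbols.append("C")
        coords.append(c)
        up = k % 2 == 0
        if n == 1:
            # methane: exact tetrahedron
            t = _R_CH / math.sqrt(3.0)
            for sx, sy, sz in [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]:
                symbols.append("H")
                coords.append(c + t * np.array([sx, sy, sz]))
            break
        for d in ch_dirs(not up):
            symbols.append("H")
            coords.append(c + _R_CH * d)
        if k == 0:
            # terminal H anti to the C-C bond
            symbols.append("H")
            coords.append(c + _R_CH * _terminal_dir(carbons, 0))
        if k == n - 1 and n > 1:
            symbols.append("H")
            coords.append(c + _R_CH * _terminal_dir(carbons, n - 1))
    return Molecule(symbols, np.array(coords) * BOHR_PER_ANGSTROM, comment=f"alkane n={n}")


def _terminal_dir(carbons, k):
    """Direction for the extra terminal H: anti to the backbone neighbour, in-plane."""
    nb = carbons[1] if k == 0 else carbons[-2]
    d = carbons[k] - nb
    d = d / np.linalg.norm(d)
    # reflect slightly toward tetrahedral rather than pure anti; pure anti is fine
    return d


def noble_pair(element: str = "He", separation_bohr: float = 5.6) -> Molecule:
    if separation_bohr <= 0:
        raise ValueError("separation must be positive")
    return Molecule([element, element],
                    np.array([[0.0, 0.0, 0.0], [0.0, 0.0, separation_bohr]]),
                    comment=f"{element}2 R={separation_bohr} bohr")


def generate_fixture(kind: str, n: int = 1, separation: float = 5.6, seed: int = 0) -> str:
    """Produce XYZ text for one of the named synthetic systems."""
    if kind == "water_chain":
        return water_chain(n, seed=seed).to_xyz()
    if kind == "alkane":
        return alkane(n).to_xyz()
    if kind == "noble_pair":
        return noble_pair("He", separation).to_xyz()
    raise ValueError(f"unknown fixture kind {kind!r}")
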