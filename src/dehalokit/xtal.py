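"""Crystallographic content estimation.

Triclinic unit-cell volume, the Matthews coefficient V_M (asymmetric-unit
volume per Dalton of macromolecule) and the derived solvent fraction.
Typical protein crystals fall in the V_M range ~1.7-3.5 A^3/Da; the value
discriminates between candidate chain counts in the asymmetric unit before
molecular replacement is attempted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import gemmi

__all__ = [
    "UnitCell",
    "AsuContents",
    "MatthewsResult",
    "cell_volume",
    "matthews",
    "spacegroup_multiplicity",
]

#: inverse protein partial specific volume, A^3/Da (Matthews' convention)
PROTEIN_VOLUME_CONSTANT = 1.23


@dataclass(frozen=True)
class UnitCell:
    """Cell lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")


@dataclass(frozen=True)
class AsuContents:
    """What occupies the asymmetric unit."""

    n_copies: int
    copy_mass: float  # Da
    z_general: int  # space-group general-position multiplicity

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.copy_mass <= 0:
            raise ValueError("copy_mass must be positive")
        if self.z_general < 1:
            raise ValueError("z_general must be >= 1")


@dataclass(frozen=True)
class MatthewsResult:
    vm: float  # A^3 / Da
    solvent_fraction: float  # in [0, 1)


def cell_volume(cell: UnitCell) -> float:
    """General triclinic cell volume, A^3.

    V = abc * sqrt(1 - cos^2(a) - cos^2(b) - cos^2(g) + 2 cos(a)cos(b)cos(g))
    """
    ca = math.cos(math.radians(cell.alpha))
    cb = math.cos(math.radians(cell.beta))
    cg = math.cos(math.radians(cell.gamma))
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0.0:
        raise ValueError("impossible cell: metric discriminant is non-positive")
    return cell.a * cell.b * cell.c * math.sqrt(disc)


_SUBSCRIPT = str.maketrans("₀₁₂₃₄₅₆₇₈₉", "0123456789")


def spacegroup_multiplicity(symbol: str) -> int:
    """General-position multiplicity for a Hermann-Mauguin symbol.

    Accepts printed variants such as "P21", "P 21", "P12(1)1", "P12_1 1" or
    unicode subscripts; resolution uses gemmi's symmetry tables.
    """
    s = symbol.translate(_SUBSCRIPT)
    s = s.replace("(", "").replace(")", "").replace("_", "")
    sg = gemmi.find_spacegroup_by_name(s)
    if sg is None:
        # retry with separators stripped entirely ("P 1 21 1" <-> "P1211")
        sg = gemmi.find_spacegroup_by_name(re.sub(r"\s+", "", s))
    if sg is None:
        raise ValueError(f"unknown space-group symbol {symbol!r}")
    return len(list(sg.operations()))


def matthews(cell: UnitCell, contents: AsuContents,
             solvent_constant: float = PROTEIN_VOLUME_CONSTANT) -> MatthewsResult:
    """Matthews coefficient and solvent fraction for given ASU contents.

    V_M = (V_cell / Z) / (n_copies * copy_mass); the solvent fraction is
    1 - solvent_constant / V_M, floored at zero.
    """
    v_asu = cell_volume(cell) / contents.z_general
    vm = v_asu / (contents.n_copies * contents.copy_mass)
    solvent = max(0.0, 1.0 - solvent_constant / vm)
    return MatthewsResult(vm=vm, solvent_fraction=solvent)
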