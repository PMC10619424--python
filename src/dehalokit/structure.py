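"""Macromolecular coordinate handling.

Parses PDB/mmCIF coordinate files into a light-weight hierarchical model
(atoms grouped by chain and residue), provides atom selection, elementary
vector geometry (distances, angles), least-squares rigid-body superposition
and classification of the L5 surface loop that mediates back-to-back
homodimerization in haloalkane dehalogenases.

Coordinates are in Angstroms in the orthogonal frame of the input file and
residue numbering follows the file verbatim: catalytic-site declarations
cite author numbering (e.g. Asp95, Trp96, Asn28), so no renumbering is ever
applied.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .xtal import UnitCell

WATER_RES_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

__all__ = [
    "AtomRecord",
    "StructureModel",
    "AtomSelector",
    "Superposition",
    "LoopAnnotation",
    "LoopCluster",
    "ParseError",
    "parse_structure",
    "read_structure",
    "write_pdb",
    "select_atoms",
    "distance",
    "angle",
    "kabsch_superpose",
    "classify_l5_loop",
]


class ParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom from an ATOM/HETATM record."""

    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    alt_loc: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    het: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.key} has invalid coordinates")
        if not self.element:
            raise ValueError(f"atom {self.key} has empty element symbol")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.key} occupancy outside [0, 1]")

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.res_seq, self.name, self.alt_loc)

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_RES_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class StructureModel:
    """An ordered atom list with a derived chain/residue index."""

    atoms: list[AtomRecord]
    model_id: int = 1
    cell: Optional[UnitCell] = None

    def __post_init__(self) -> None:
        seen: dict[tuple, int] = {}
        for a in self.atoms:
            if a.key in seen:
                raise ParseError(
                    f"duplicate atom key {a.key!r} (serials "
                    f"{seen[a.key]} and {a.serial})"
                )
            seen[a.key] = a.serial

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def chains(self) -> dict[str, list[tuple[int, str]]]:
        """chain_id -> ordered unique (res_seq, res_name) list."""
        index: dict[str, list[tuple[int, str]]] = {}
        for a in self.atoms:
            residues = index.setdefault(a.chain_id, [])
            tag = (a.res_seq, a.res_name)
            if not residues or residues[-1] != tag:
                if tag not in residues:
                    residues.append(tag)
        return index

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with `R x + t` applied to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [replace(a, coords=R @ a.coords + t) for a in self.atoms]
        return StructureModel(atoms=atoms, model_id=self.model_id, cell=self.cell)


@dataclass
class AtomSelector:
    """Conjunctive atom filter; an empty selector selects every atom."""

    chain_ids: Optional[frozenset[str]] = None
    res_seq_range: Optional[tuple[int, int]] = None  # inclusive
    res_names: Optional[frozenset[str]] = None
    atom_names: Optional[frozenset[str]] = None
    elements: Optional[frozenset[str]] = None
    exclude_water: bool = False
    exclude_hydrogens: bool = False

    def matches(self, a: AtomRecord) -> bool:
        if self.chain_ids is not None and a.chain_id not in self.chain_ids:
            return False
        if self.res_seq_range is not None:
            lo, hi = self.res_seq_range
            if not lo <= a.res_seq <= hi:
                return False
        if self.res_names is not None and a.res_name not in self.res_names:
            return False
        if self.atom_names is not None and a.name not in self.atom_names:
            return False
        if self.elements is not None and a.element not in self.elements:
            return False
        if self.exclude_water and a.is_water:
            return False
        if self.exclude_hydrogens and a.is_hydrogen:
            return False
        return True

    @classmethod
    def from_spec(cls, spec: str) -> "AtomSelector":
        """Build from a compact ``chain:A,res:63-70,atom:CA,name:PHE`` string.

        Recognised clauses: chain, res (single number or lo-hi range),
        resname, atom, element, nowater, noh.
        """
        kwargs: dict = {}
        spec = spec.strip()
        if not spec:
            return cls()
        for clause in spec.split(","):
            if clause == "nowater":
                kwargs["exclude_water"] = True
                continue
            if clause == "noh":
                kwargs["exclude_hydrogens"] = True
                continue
            key, _, val = clause.partition(":")
            if key == "chain":
                kwargs["chain_ids"] = frozenset(val.split("+"))
            elif key == "res":
                lo, dash, hi = val.partition("-")
                kwargs["res_seq_range"] = (int(lo), int(hi) if dash else int(lo))
            elif key == "resname":
                kwargs["res_names"] = frozenset(val.split("+"))
            elif key == "atom":
                kwargs["atom_names"] = frozenset(val.split("+"))
            elif key == "element":
                kwargs["elements"] = frozenset(val.split("+"))
            else:
                raise ValueError(f"unknown selector clause {clause!r}")
        return cls(**kwargs)


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid-body fit of a mobile onto a reference point set."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector
    rmsd: float
    n_atoms: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


class LoopCluster(str, Enum):
    SHORT = "SHORT"
    LONG = "LONG"
    DMMARA_TYPE = "DMMARA_TYPE"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class LoopAnnotation:
    """A named surface-loop span (e.g. the L5 loop) in one chain."""

    loop_id: str
    chain_id: str
    res_range: tuple[int, int]
    length: int

    @classmethod
    def from_structure(cls, model: StructureModel, loop_id: str, chain_id: str,
                       res_range: tuple[int, int]) -> "LoopAnnotation":
        residues = [r for r, _ in model.chains.get(chain_id, [])
                    if res_range[0] <= r <= res_range[1]]
        return cls(loop_id=loop_id, chain_id=chain_id, res_range=res_range,
                   length=len(residues))


# ---------------------------------------------------------------------------
# parsing / writing

def _cell_from_gemmi(cell: gemmi.UnitCell) -> Optional[UnitCell]:
    if cell.a <= 1.0:  # gemmi's placeholder dummy cell
        return None
    return UnitCell(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


def parse_structure(text: str, model_id: Optional[int] = None,
                    keep_altlocs: Sequence[str] = ("", "A")) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Multi-MODEL files yield the requested model (default: the first).
    Waters are retained (flagged by residue name). By default only blank or
    'A' alternate locations are kept so downstream geometry is deterministic.
    """
    st = gemmi.read_pdb_string(text)
    return _convert(st, text, model_id, keep_altlocs)


def read_structure(path: str, model_id: Optional[int] = None,
                   keep_altlocs: Sequence[str] = ("", "A")) -> StructureModel:
    """Read a structure from a PDB or mmCIF file (format by extension)."""
    st = gemmi.read_structure(str(path))
    with open(path, "r", errors="replace") as fh:
        head = fh.read(20000)
    return _convert(st, head, model_id, keep_altlocs)


def _convert(st: gemmi.Structure, text: str, model_id: Optional[int],
             keep_altlocs: Sequence[str]) -> StructureModel:
    if len(st) == 0:
        raise ParseError(_first_line_message(text))
    if model_id is None:
        gmodel = st[0]
    else:
        gmodel = None
        for m in st:
            if int(getattr(m, "num", getattr(m, "name", 0))) == model_id:
                gmodel = m
                break
        if gmodel is None:
            raise ParseError(f"model {model_id} not present")
    atoms: list[AtomRecord] = []
    for chain in gmodel:
        for res in chain:
            for atom in res:
                alt = atom.altloc if atom.altloc != "\0" else ""
                if alt not in keep_altlocs:
                    continue
                atoms.append(AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name.upper(),
                    res_name=res.name,
                    chain_id=chain.name,
                    res_seq=res.seqid.num,
                    alt_loc=alt,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    b_factor=atom.b_iso,
                    het=res.het_flag == "H",
                ))
    if not atoms:
        raise ParseError(_first_line_message(text))
    mid = int(getattr(gmodel, "num", getattr(gmodel, "name", 1)) or 1)
    return StructureModel(atoms=atoms, model_id=mid, cell=_cell_from_gemmi(st.cell))


def parse_models(text: str, keep_altlocs: Sequence[str] = ("", "A")) -> list[StructureModel]:
    """Parse every MODEL in a (possibly multi-model) PDB text."""
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise ParseError(_first_line_message(text))
    out = []
    for m in st:
        mid = int(getattr(m, "num", getattr(m, "name", 1)) or 1)
        out.append(_convert_single(st, m, mid, keep_altlocs, text))
    return out


def _convert_single(st, gmodel, mid, keep_altlocs, text) -> StructureModel:
    sub = gemmi.Structure()
    sub.cell = st.cell
    sub.add_model(gmodel)
    return _convert(sub, text, None, keep_altlocs)


def _first_line_message(text: str) -> str:
    for i, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            return (f"no parseable ATOM/HETATM records; first content at "
                    f"line {i}: {line[:40]!r}")
    return "no parseable ATOM/HETATM records; input is empty"


def _pdb_atom_name_field(name: str, element: str) -> str:
    # column convention: element right-aligned in cols 13-14 for 1-2 char names
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2 or (len(name) == 4):
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_pdb(models: "StructureModel | Iterable[StructureModel]") -> str:
    """Serialize one model (or an iterable -> MODEL/ENDMDL blocks) to PDB text."""
    if isinstance(models, StructureModel):
        models = [models]
    models = list(models)
    buf = io.StringIO()
    cell = models[0].cell
    if cell is not None:
        buf.write(f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
                  f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} P 1           1\n")
    multi = len(models) > 1
    for m in models:
        if multi:
            buf.write(f"MODEL     {m.model_id:4d}\n")
        for a in m.atoms:
            rec = "HETATM" if (a.het or a.is_water) else "ATOM  "
            buf.write(
                f"{rec}{a.serial:5d} {_pdb_atom_name_field(a.name, a.element)}"
                f"{a.alt_loc or ' '}{a.res_name:>3s} {a.chain_id:1s}"
                f"{a.res_seq:4d}    "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{a.b_factor:6.2f}          "
                f"{a.element:>2s}\n")
        if multi:
            buf.write("ENDMDL\n")
    buf.write("END\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# selection and geometry

def select_atoms(model: StructureModel, sel: AtomSelector) -> list[AtomRecord]:
    """Atoms satisfying every selector clause, in input order (idempotent)."""
    return [a for a in model.atoms if sel.matches(a)]


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two points, Angstrom."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(a - b))


def angle(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Angle a-vertex-c in degrees, in [0, 180]."""
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(c, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-length arm: a point coincides with the vertex")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares optimal rigid superposition (SVD; reflections suppressed).

    Returns the proper rotation R and translation t minimising
    ``|| R mobile + t - reference ||`` over paired points, plus the residual
    RMSD. Mirror solutions are corrected so det(R) = +1 always.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching N x 3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 paired points are required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    if np.linalg.matrix_rank(H) < 2:
        warnings.warn("degenerate (near-collinear) point set; superposition "
                      "is not uniquely determined", stacklevel=2)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)


# ---------------------------------------------------------------------------
# L5 loop classification

#: canonical loop-length clusters observed across dimeric family members
L5_SHORT_LENGTH = 18
L5_LONG_RANGE = (20, 22)


def classify_l5_loop(annotation: LoopAnnotation, phe_exposed: bool = False) -> LoopCluster:
    """Assign an L5 loop to a length cluster.

    Family-wide comparisons split L5 loops into a short cluster (18 residues)
    and a long cluster (20-22 residues). A loop carrying a solvent-exposed
    phenylalanine is the hallmark of the back-to-back dimerizing variant and
    takes precedence over either length cluster.
    """
    if annotation.length < 1:
        raise ValueError("loop must contain at least one residue")
    if phe_exposed:
        return LoopCluster.DMMARA_TYPE
    if annotation.length == L5_SHORT_LENGTH:
        return LoopCluster.SHORT
    if L5_LONG_RANGE[0] <= annotation.length <= L5_LONG_RANGE[1]:
        return LoopCluster.LONG
    return LoopCluster.UNCLASSIFIED
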