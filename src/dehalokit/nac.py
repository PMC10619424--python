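"""Near-attack-conformation (NAC) analysis of enzyme-substrate poses.

A haloalkane dehalogenase cleaves the carbon-halogen bond by S_N2
backside attack of a catalytic aspartate carboxylate oxygen on the
halogen-bound carbon. A docking pose is productive (a NAC) when

* the nucleophile O ... C distance d_OC is at most 3.41 A,
* the O-C-X attack angle (X = leaving halogen) is at least 157 deg, and
* the halide is stabilised by at least weak hydrogen bonding to the
  halide-stabilising residues (indole NH of the catalytic tryptophan and
  side-chain NH of the asparagine), d_XH <= 3.0 A.

Boundary equalities satisfy the criteria. Poses that miss one or more
criteria by a small margin are graded quasi-NAC; everything else is
non-productive. When a structure carries no hydrogens the stabiliser
distances are measured to the donor heavy atom (N) and the threshold is
relaxed by +1.0 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .structure import AtomRecord, StructureModel, angle as _angle, distance as _dist

__all__ = [
    "AtomRef",
    "CatalyticSiteSpec",
    "NACThresholds",
    "ReactionGeometry",
    "NACCategory",
    "NACVerdict",
    "SiteResolutionError",
    "measure_reaction_geometry",
    "classify_nac",
    "screen_pose_ensemble",
]

#: halogen elements in auto-detection priority order
HALOGEN_PRIORITY = ("BR", "CL", "I", "F")

#: heavy-atom relaxation applied to d_XH when no hydrogens are present
HEAVY_ATOM_RELAXATION = 1.0


class SiteResolutionError(ValueError):
    """An atom reference in the catalytic-site declaration did not resolve."""


@dataclass(frozen=True)
class AtomRef:
    """Reference to exactly one atom by chain / residue number / atom name."""

    chain_id: Optional[str]
    res_seq: Optional[int]
    atom_name: str
    res_name: Optional[str] = None

    def resolve(self, model: StructureModel, label: str = "atom") -> AtomRecord:
        hits = [a for a in model.atoms
                if (self.chain_id is None or a.chain_id == self.chain_id)
                and (self.res_seq is None or a.res_seq == self.res_seq)
                and (self.res_name is None or a.res_name == self.res_name)
                and a.name == self.atom_name]
        if len(hits) != 1:
            raise SiteResolutionError(
                f"{label} reference {self} resolved to {len(hits)} atoms "
                f"(expected exactly 1)")
        return hits[0]

    @classmethod
    def parse(cls, spec: str) -> "AtomRef":
        """Parse ``"A:95:OD1"`` or ``"A:95:ASP:OD1"``."""
        parts = spec.split(":")
        if len(parts) == 3:
            chain, seq, name = parts
            return cls(chain or None, int(seq), name)
        if len(parts) == 4:
            chain, seq, resname, name = parts
            return cls(chain or None, int(seq), name, resname or None)
        raise ValueError(f"cannot parse atom reference {spec!r}")


@dataclass
class CatalyticSiteSpec:
    """Declaration of the catalytic machinery and the reacting ligand atoms.

    ``nucleophile_oxygens`` lists the carboxylate O atoms of the catalytic
    aspartate (both OD1 and OD2: the closer one attacks).
    ``stabilizer_donors`` lists the halide-stabilising H-bond donor atoms
    (the explicit polar hydrogens when present, else the donor N atoms).
    ``ligand_halogen`` may be omitted: the halogen is then auto-detected in
    the pose by element (Br, Cl, I, F priority).
    """

    nucleophile_oxygens: list[AtomRef]
    stabilizer_donors: list[AtomRef]
    ligand_carbon: AtomRef
    ligand_halogen: Optional[AtomRef] = None
    donors_are_heavy: bool = False  # True: d_XH measured to N, threshold relaxed

    def __post_init__(self) -> None:
        if not self.nucleophile_oxygens:
            raise ValueError("at least one nucleophile O atom is required")
        if not self.stabilizer_donors:
            raise ValueError("at least one stabilizer donor is required")

    @classmethod
    def from_dict(cls, cfg: dict) -> "CatalyticSiteSpec":
        return cls(
            nucleophile_oxygens=[AtomRef.parse(s) for s in cfg["nucleophile_oxygens"]],
            stabilizer_donors=[AtomRef.parse(s) for s in cfg["stabilizer_donors"]],
            ligand_carbon=AtomRef.parse(cfg["ligand_carbon"]),
            ligand_halogen=(AtomRef.parse(cfg["ligand_halogen"])
                            if cfg.get("ligand_halogen") else None),
            donors_are_heavy=bool(cfg.get("donors_are_heavy", False)),
        )


@dataclass
class NACThresholds:
    """Strict NAC criteria plus looser quasi-NAC bounds."""

    d_oc_max: float = 3.41
    angle_min: float = 157.0
    d_xh_max: float = 3.0
    quasi_d_oc_max: float = 3.8
    quasi_angle_min: float = 140.0
    quasi_d_xh_max: float = 3.5
    require_all_donors: bool = True  # both stabiliser donors must satisfy d_XH

    def __post_init__(self) -> None:
        if not (self.quasi_d_oc_max >= self.d_oc_max
                and self.quasi_angle_min <= self.angle_min
                and self.quasi_d_xh_max >= self.d_xh_max):
            raise ValueError("quasi bounds must be looser than strict bounds")

    def relaxed(self, by: float = HEAVY_ATOM_RELAXATION) -> "NACThresholds":
        """Thresholds with d_XH cutoffs relaxed (heavy-atom donor mode)."""
        return NACThresholds(
            d_oc_max=self.d_oc_max, angle_min=self.angle_min,
            d_xh_max=self.d_xh_max + by,
            quasi_d_oc_max=self.quasi_d_oc_max,
            quasi_angle_min=self.quasi_angle_min,
            quasi_d_xh_max=self.quasi_d_xh_max + by,
            require_all_donors=self.require_all_donors,
        )


@dataclass
class ReactionGeometry:
    """The attack geometry of one pose."""

    d_oc: float  # min over nucleophile O atoms, A
    angle_ocx: float  # O-C-X angle for the O achieving d_oc, deg
    d_xh: list[float]  # halogen to each stabiliser donor, A
    pose_id: int = 0

    def __post_init__(self) -> None:
        if self.d_oc <= 0 or any(d <= 0 for d in self.d_xh):
            raise ValueError("distances must be positive")
        if not 0.0 <= self.angle_ocx <= 180.0:
            raise ValueError("angle must lie in [0, 180] degrees")


class NACCategory(str, Enum):
    NAC = "NAC"
    QUASI_NAC = "QUASI_NAC"
    NON_PRODUCTIVE = "NON_PRODUCTIVE"


@dataclass
class NACVerdict:
    category: NACCategory
    failed_criteria: list[tuple[str, float, float, float]]  # (name, observed, threshold, margin)
    geometry: Optional[ReactionGeometry]
    note: str = ""


def measure_reaction_geometry(receptor: StructureModel, pose: StructureModel,
                              site: CatalyticSiteSpec,
                              pose_id: int = 0) -> ReactionGeometry:
    """Measure d_OC, the O-C-X attack angle and the halide-donor distances.

    d_OC is minimised over the declared nucleophile O atoms; the angle uses
    the O that achieves the minimum, with the ligand carbon as vertex.
    """
    o_atoms = [ref.resolve(receptor, "nucleophile O") for ref in site.nucleophile_oxygens]
    donors = [ref.resolve(receptor, "stabilizer donor") for ref in site.stabilizer_donors]
    c_atom = site.ligand_carbon.resolve(pose, "ligand carbon")
    if site.ligand_halogen is not None:
        x_atom = site.ligand_halogen.resolve(pose, "ligand halogen")
    else:
        x_atom = _auto_halogen(pose)

    d_by_o = [( _dist(o.coords, c_atom.coords), o) for o in o_atoms]
    d_oc, best_o = min(d_by_o, key=lambda t: t[0])
    ang = _angle(best_o.coords, c_atom.coords, x_atom.coords)
    d_xh = [_dist(x_atom.coords, d.coords) for d in donors]
    return ReactionGeometry(d_oc=d_oc, angle_ocx=ang, d_xh=d_xh, pose_id=pose_id)


def _auto_halogen(pose: StructureModel) -> AtomRecord:
    for element in HALOGEN_PRIORITY:
        hits = [a for a in pose.atoms if a.element == element]
        if hits:
            return hits[0]
    raise SiteResolutionError("ligand contains no halogen (Br/Cl/I/F)")


def classify_nac(geom: ReactionGeometry,
                 thr: Optional[NACThresholds] = None) -> NACVerdict:
    """Grade one measured geometry as NAC, quasi-NAC or non-productive.

    Strict NAC requires every criterion satisfied (boundary equality counts
    as satisfied). Quasi-NAC requires at least one strict failure with all
    quantities still inside the quasi bounds. ``failed_criteria`` lists each
    violated strict criterion with its margin.
    """
    thr = thr or NACThresholds()
    failed: list[tuple[str, float, float, float]] = []
    within_quasi = True

    if geom.d_oc > thr.d_oc_max:
        failed.append(("d_oc", geom.d_oc, thr.d_oc_max,
                       round(geom.d_oc - thr.d_oc_max, 6)))
    if geom.d_oc > thr.quasi_d_oc_max:
        within_quasi = False

    if geom.angle_ocx < thr.angle_min:
        failed.append(("angle_ocx", geom.angle_ocx, thr.angle_min,
                       round(thr.angle_min - geom.angle_ocx, 6)))
    if geom.angle_ocx < thr.quasi_angle_min:
        within_quasi = False

    if thr.require_all_donors:
        strict_ok = all(d <= thr.d_xh_max for d in geom.d_xh)
        quasi_ok = all(d <= thr.quasi_d_xh_max for d in geom.d_xh)
        worst = max(geom.d_xh)
    else:
        strict_ok = min(geom.d_xh) <= thr.d_xh_max
        quasi_ok = min(geom.d_xh) <= thr.quasi_d_xh_max
        worst = min(geom.d_xh)
    if not strict_ok:
        failed.append(("d_xh", worst, thr.d_xh_max,
                       round(worst - thr.d_xh_max, 6)))
    if not quasi_ok:
        within_quasi = False

    if not failed:
        category = NACCategory.NAC
    elif within_quasi:
        category = NACCategory.QUASI_NAC
    else:
        category = NACCategory.NON_PRODUCTIVE
    return NACVerdict(category=category, failed_criteria=failed, geometry=geom)


def screen_pose_ensemble(receptor: StructureModel,
                         poses: Sequence[StructureModel],
                         site: CatalyticSiteSpec,
                         thr: Optional[NACThresholds] = None,
                         ) -> tuple[pd.DataFrame, dict]:
    """Classify every pose of an ensemble; per-pose errors do not abort.

    Returns a table with one row per pose (pose_id, d_oc, angle_ocx, per-donor
    d_xh, category, note) plus a summary dict with counts per category and
    the best pose (lowest d_OC among strict NACs).
    """
    if len(poses) == 0:
        raise ValueError("pose ensemble is empty")
    thr = thr or NACThresholds()
    if site.donors_are_heavy:
        thr = thr.relaxed()
    rows = []
    verdicts: list[NACVerdict] = []
    for i, pose in enumerate(poses, start=1):
        pose_id = pose.model_id if pose.model_id else i
        try:
            geom = measure_reaction_geometry(receptor, pose, site, pose_id=pose_id)
            v = classify_nac(geom, thr)
        except (SiteResolutionError, ValueError) as exc:
            v = NACVerdict(category=NACCategory.NON_PRODUCTIVE,
                           failed_criteria=[], geometry=None,
                           note=f"measurement error: {exc}")
        verdicts.append(v)
        row = {"pose_id": pose_id,
               "d_oc": v.geometry.d_oc if v.geometry else np.nan,
               "angle_ocx": v.geometry.angle_ocx if v.geometry else np.nan,
               "category": v.category.value,
               "note": v.note}
        if v.geometry:
            for k, d in enumerate(v.geometry.d_xh, start=1):
                row[f"d_xh{k}"] = d
        rows.append(row)
    table = pd.DataFrame(rows)
    counts = table["category"].value_counts().to_dict()
    summary = {"n_poses": len(poses),
               "counts": {c.value: int(counts.get(c.value, 0)) for c in NACCategory}}
    nac_rows = table[table["category"] == NACCategory.NAC.value]
    if len(nac_rows):
        summary["best_pose_id"] = int(nac_rows.loc[nac_rows["d_oc"].idxmin(), "pose_id"])
    else:
        summary["best_pose_id"] = None
    return table, summary
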