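"""Seed-deterministic synthetic fixtures with known ground truth.

Every generator emulates one input class of the analysis pipeline: docking
pose ensembles with prescribed attack geometry, back-to-back toy dimers
with planted interface contacts, single-barrier adiabatic-mapping energy
profiles, two-transition nanoDSF melting curves and noisy Debye scattering
experiments. Receptors and dimers are minimal atom constellations rather
than folded proteins: the downstream classifiers and geometry operators
are coordinate-local, so folded-protein realism would not change what the
tests can demonstrate. All noise is Gaussian. Each generator returns its
objects together with a machine-readable truth record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nac import NACThresholds
from .interface import SasaParams, sasa
from .saxs import FormFactorMode, SaxsCurve, debye_curve
from .structure import AtomRecord, StructureModel
from .thermo import EnergyProfile, MeltingCurve

__all__ = [
    "GeneratorConfig",
    "gen_pose_set",
    "gen_toy_dimer",
    "gen_energy_profile",
    "gen_melting_curve",
    "gen_saxs_experiment",
    "gen_bead_sphere",
    "gen_oligomer_models",
]


@dataclass
class GeneratorConfig:
    """Bundled generator settings; identical config -> identical outputs."""

    seed: int = 0
    pose: dict = field(default_factory=dict)
    dimer: dict = field(default_factory=dict)
    profile: dict = field(default_factory=dict)
    melt: dict = field(default_factory=dict)
    saxs: dict = field(default_factory=dict)


def _atom(serial, name, element, res_name, chain, res_seq, xyz, het=False) -> AtomRecord:
    return AtomRecord(serial=serial, name=name, element=element,
                      res_name=res_name, chain_id=chain, res_seq=res_seq,
                      alt_loc="", coords=np.asarray(xyz, float), het=het)


# ---------------------------------------------------------------------------
# docking pose ensembles

def _make_receptor() -> StructureModel:
    """Minimal catalytic constellation: Asp carboxylate, Trp and Asn donors.

    The attack axis is +z from OD1 at the origin; the ideal halogen site
    sits at (0, 0, 5.15) with both donor hydrogens exactly 2.6 A away.
    """
    b0 = np.array([0.0, 0.0, 5.15])  # ideal halide position
    off = math.sqrt(2.6 ** 2 - 2.2 ** 2)
    atoms = [
        _atom(1, "CG", "C", "ASP", "A", 95, (-1.1, 0.0, -0.8)),
        _atom(2, "OD1", "O", "ASP", "A", 95, (0.0, 0.0, 0.0)),
        _atom(3, "OD2", "O", "ASP", "A", 95, (-2.2, 0.0, 0.0)),
        _atom(4, "NE1", "N", "TRP", "A", 96, (3.2, 0.0, 5.15 + off)),
        _atom(5, "HE1", "H", "TRP", "A", 96, (2.2, 0.0, 5.15 + off)),
        _atom(6, "ND2", "N", "ASN", "A", 28, (-3.2, 0.0, 5.15 + off)),
        _atom(7, "HD21", "H", "ASN", "A", 28, (-2.2, 0.0, 5.15 + off)),
    ]
    assert abs(np.linalg.norm(atoms[4].coords - b0) - 2.6) < 1e-9
    return StructureModel(atoms=atoms)


def _pose_from_sites(c: np.ndarray, br: np.ndarray, pose_id: int) -> StructureModel:
    """Ligand pose: attacked carbon, halogen and two dummy methyl carbons."""
    axis = br - c
    axis = axis / np.linalg.norm(axis)
    perp = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    atoms = [
        _atom(1, "C2", "C", "LIG", "L", 1, c, het=True),
        _atom(2, "BR", "BR", "LIG", "L", 1, br, het=True),
        _atom(3, "C1", "C", "LIG", "L", 1, c + 1.5 * perp, het=True),
        _atom(4, "C3", "C", "LIG", "L", 1, c - 1.5 * perp, het=True),
    ]
    return StructureModel(atoms=atoms, model_id=pose_id)


def _nac_flags(d_oc, ang, d_xh, thr: NACThresholds) -> str:
    """Generator-side category rule (inline comparisons, no classifier call)."""
    strict = (d_oc <= thr.d_oc_max and ang >= thr.angle_min
              and all(d <= thr.d_xh_max for d in d_xh))
    quasi = (d_oc <= thr.quasi_d_oc_max and ang >= thr.quasi_angle_min
             and all(d <= thr.quasi_d_xh_max for d in d_xh))
    if strict:
        return "NAC"
    return "QUASI_NAC" if quasi else "NON_PRODUCTIVE"


def gen_pose_set(n_poses: int = 20, n_nac: int = 5, seed: int = 0,
                 thresholds: Optional[NACThresholds] = None,
                 ) -> tuple[StructureModel, list[StructureModel], list[dict]]:
    """Docking-pose ensemble with exactly ``n_nac`` strict NACs planted.

    Returns (receptor, poses, truth): the truth list records each pose's
    intended category and the geometry the generator measured itself.
    """
    if not 0 <= n_nac <= n_poses:
        raise ValueError("need 0 <= n_nac <= n_poses")
    thr = thresholds or NACThresholds()
    rng = np.random.default_rng(seed)
    receptor = _make_receptor()
    od1 = receptor.atoms[1].coords
    od2 = receptor.atoms[2].coords
    he1 = receptor.atoms[4].coords
    hd21 = receptor.atoms[6].coords

    categories = ["NAC"] * n_nac + ["NON_PRODUCTIVE"] * (n_poses - n_nac)
    order = rng.permutation(n_poses)
    poses, truth = [], []
    for pose_id, slot in enumerate(order, start=1):
        want = categories[slot]
        for _ in range(500):
            if want == "NAC":
                d_oc = rng.uniform(3.00, 3.35)
                c = np.array([rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1), d_oc])
                c[2] = math.sqrt(max(d_oc ** 2 - c[0] ** 2 - c[1] ** 2, 0.1))
                tilt = math.radians(rng.uniform(0.0, 8.0))
                az = rng.uniform(0, 2 * math.pi)
                direction = (c - od1) / np.linalg.norm(c - od1)
                direction = _tilted(direction, tilt, az)
                br = c + 1.95 * direction
            else:
                mode = rng.integers(0, 2)
                if mode == 0:  # too far for attack
                    d_oc = rng.uniform(4.2, 6.0)
                    c = _random_direction(rng) * d_oc
                    c[2] = abs(c[2]) + 1.0
                    c *= d_oc / np.linalg.norm(c)
                    br = c + 1.95 * _random_direction(rng)
                else:  # attack angle hopeless
                    d_oc = rng.uniform(3.0, 3.4)
                    c = np.array([0.0, 0.0, d_oc])
                    direction = _tilted(np.array([0.0, 0.0, 1.0]),
                                        math.radians(rng.uniform(75.0, 110.0)),
                                        rng.uniform(0, 2 * math.pi))
                    br = c + 1.95 * direction
            d1 = min(np.linalg.norm(od1 - c), np.linalg.norm(od2 - c))
            o_best = od1 if np.linalg.norm(od1 - c) <= np.linalg.norm(od2 - c) else od2
            ang = _angle_deg(o_best, c, br)
            d_xh = [float(np.linalg.norm(br - he1)), float(np.linalg.norm(br - hd21))]
            got = _nac_flags(float(d1), ang, d_xh, thr)
            if got == want:
                poses.append(_pose_from_sites(c, br, pose_id))
                truth.append({"pose_id": pose_id, "category": want,
                              "d_oc": float(d1), "angle_ocx": float(ang),
                              "d_xh": d_xh})
                break
        else:
            raise RuntimeError(f"could not realise a {want} pose (infeasible geometry)")
    return receptor, poses, truth


def _random_direction(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _tilted(axis: np.ndarray, tilt: float, azimuth: float) -> np.ndarray:
    """Unit vector at angle ``tilt`` from ``axis`` (rotated by ``azimuth``)."""
    perp1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(perp1) < 1e-8:
        perp1 = np.cross(axis, [0.0, 1.0, 0.0])
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis, perp1)
    return (math.cos(tilt) * axis
            + math.sin(tilt) * (math.cos(azimuth) * perp1 + math.sin(azimuth) * perp2))


def _angle_deg(a, vertex, c) -> float:
    u, v = a - vertex, c - vertex
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))


# ---------------------------------------------------------------------------
# toy back-to-back dimer

_CONTACT_ATOM = {
    "HBOND": ("SER", "OG", "O"),
    "HYDROPHOBIC": ("LEU", "CD1", "C"),
    "WATER_BRIDGE": ("THR", "OG1", "O"),
}


def gen_toy_dimer(monomer_size: int = 40,
                  interface_spec: Optional[Sequence[dict]] = None,
                  separation: float = 0.0,
                  seed: int = 0) -> tuple[StructureModel, dict]:
    """Two-fold symmetric toy dimer with planted interface contacts.

    Chain A is a compact random coil (Gly CA trace) centred off-axis; chain
    B is its 180-degree rotation about the z axis. Each requested contact
    is realised by a symmetric atom pair straddling the axis at exactly the
    requested distance; water bridges additionally place a bridging water
    on the interface plane at the requested leg lengths. ``separation``
    pushes the chains apart along x (use ~100 for a no-contact control).

    Returns (model, truth) where truth holds the planted contact list and
    the buried interface area measured with a dense-sampling SASA oracle.
    """
    interface_spec = list(interface_spec or [])
    if interface_spec and separation:
        raise ValueError("planted contacts and a separation offset are "
                         "mutually exclusive")
    rng = np.random.default_rng(seed)

    # compact coil: confined random walk, 3.8 A steps inside a 6.5 A sphere
    center = np.array([12.0, 0.0, 0.0])
    pos = center.copy()
    a_atoms: list[AtomRecord] = []
    serial = 1
    for i in range(monomer_size):
        a_atoms.append(_atom(serial, "CA", "C", "GLY", "A", i + 1, pos))
        serial += 1
        for _ in range(100):
            step = 3.8 * _random_direction(rng)
            cand = pos + step
            if np.linalg.norm(cand - center) <= 6.5:
                pos = cand
                break
        else:
            pos = center + rng.uniform(-1, 1, 3)

    waters: list[AtomRecord] = []
    truth_contacts = []
    res_seq = 200
    z_slot = -6.0 * (max(len(interface_spec), 1) - 1) / 2.0
    for k, spec in enumerate(interface_spec):
        kind = spec["kind"]
        res_name, atom_name, element = _CONTACT_ATOM[kind]
        theta = 2.0 * math.pi * k / max(len(interface_spec), 1)
        e_r = np.array([math.cos(theta), math.sin(theta), 0.0])
        z = z_slot + 6.0 * k
        if kind == "WATER_BRIDGE":
            d1, d2 = spec["distance"]
            x1 = 2.0  # keeps the direct polar pair at 4.0 A, beyond H-bond range
            w = (d2 ** 2 - d1 ** 2) / (4.0 * x1)
            h = math.sqrt(d1 ** 2 - (w - x1) ** 2)
            a_pos = x1 * e_r + np.array([0, 0, z])
            w_pos = w * e_r + np.array([0, 0, z + h])
            a_atoms.append(_atom(serial, atom_name, element, res_name, "A",
                                 res_seq, a_pos))
            serial += 1
            waters.append(_atom(serial, "O", "O", "HOH", "W", 500 + k, w_pos,
                                het=True))
            serial += 1
            truth_contacts.append({"kind": kind, "distance": [d1, d2],
                                   "res_seq": res_seq})
        else:
            d = float(spec["distance"])
            if kind == "HBOND" and d > 3.5:
                raise ValueError("requested H-bond distance exceeds the rule cutoff")
            a_pos = (d / 2.0) * e_r + np.array([0, 0, z])
            a_atoms.append(_atom(serial, atom_name, element, res_name, "A",
                                 res_seq, a_pos))
            serial += 1
            truth_contacts.append({"kind": kind, "distance": d,
                                   "res_seq": res_seq})
        res_seq += 1

    # contact-inert interface pad: carbon patch either side of the axis so a
    # substantial surface is buried on association; Gly-like carbons cannot
    # register as typed contacts, keeping the planted inventory exact.
    z_top = (z_slot + 6.0 * (len(interface_spec) - 1)) if interface_spec else 0.0
    pad_z0 = z_top + 10.0
    for iy in range(3):
        for iz in range(3):
            p = np.array([1.8, 4.0 * (iy - 1), pad_z0 + 4.0 * (iz - 1)])
            a_atoms.append(_atom(serial, "CA", "C", "GLY", "A", res_seq, p))
            serial += 1
            res_seq += 1

    if separation:
        shift = np.array([separation / 2.0, 0.0, 0.0])
        a_atoms = [AtomRecord(serial=a.serial, name=a.name, element=a.element,
                              res_name=a.res_name, chain_id=a.chain_id,
                              res_seq=a.res_seq, alt_loc="",
                              coords=a.coords + shift, het=a.het)
                   for a in a_atoms]

    # chain B: 2-fold rotation about z, (x, y, z) -> (-x, -y, z)
    flip = np.diag([-1.0, -1.0, 1.0])
    b_atoms = [AtomRecord(serial=a.serial + 1000, name=a.name, element=a.element,
                          res_name=a.res_name, chain_id="B", res_seq=a.res_seq,
                          alt_loc="", coords=flip @ a.coords, het=a.het)
               for a in a_atoms]
    model = StructureModel(atoms=a_atoms + b_atoms + waters)

    dense = SasaParams(n_points=10000)
    sa = sasa(a_atoms, dense).total
    sb = sasa(b_atoms, dense).total
    sab = sasa(a_atoms + b_atoms, dense).total
    truth = {"contacts": truth_contacts,
             "buried_area": max(0.0, (sa + sb - sab) / 2.0),
             "separation": separation}
    return model, truth


# ---------------------------------------------------------------------------
# energy profiles

def gen_energy_profile(barrier: float = 9.9, reactant_coord: float = 3.3,
                       ts_coord: float = 2.2, product_drop: float = 5.0,
                       noise_sigma: float = 0.05, seed: int = 0,
                       end_coord: float = 1.6, step: float = 0.025,
                       well_coord: float = 3.0, well_depth: float = 2.0,
                       ) -> tuple[EnergyProfile, dict]:
    """Single-barrier profile sampled at fixed coordinate decrements.

    The smooth shape is a localized reactant well (Gaussian dip of
    ``well_depth`` at ``well_coord``), a Gaussian barrier at ``ts_coord``
    whose amplitude is chosen so the well-to-peak difference equals the
    requested ``barrier``, and a sigmoid drop into the product basin.
    Gaussian noise of width ``noise_sigma`` is added on top. The truth
    record carries the barrier measured on the noiseless samples (so
    sigma = 0 recovers it to grid resolution).
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    well_depth = min(well_depth, barrier / 2.0)
    rng = np.random.default_rng(seed)
    coord = np.arange(reactant_coord, end_coord - 1e-9, -step)
    smooth = ((barrier - well_depth) * np.exp(-((coord - ts_coord) / 0.18) ** 2)
              - well_depth * np.exp(-((coord - well_coord) / 0.2) ** 2)
              - product_drop / (1.0 + np.exp((coord - (ts_coord - 0.45)) / 0.08)))
    # truth from the noiseless samples, by the barrier definition itself
    ts = int(np.argmax(smooth[1:-1])) + 1
    ground = int(np.argmin(smooth[:ts]))
    truth = {"barrier": float(smooth[ts] - smooth[ground]),
             "nominal_barrier": barrier,
             "ts_coord": ts_coord, "noise_sigma": noise_sigma}
    energy = smooth + rng.normal(0.0, noise_sigma, size=coord.shape) \
        if noise_sigma > 0 else smooth
    return EnergyProfile(coordinate=coord, energy=energy), truth


# ---------------------------------------------------------------------------
# melting curves

def gen_melting_curve(tm_list: Sequence[float] = (40.7, 57.3),
                      amplitudes: Optional[Sequence[float]] = None,
                      width: float = 1.2, noise_sigma: float = 0.002,
                      baseline: float = 0.8, seed: int = 0,
                      t_min: float = 20.0, t_max: float = 80.0,
                      step: float = 0.25) -> tuple[MeltingCurve, dict]:
    """Sum-of-sigmoids nanoDSF curve with prescribed transition midpoints."""
    tm_list = sorted(tm_list)
    if amplitudes is None:
        # typical nanoDSF F350/F330 excursion across an unfolding transition
        amplitudes = [0.25] * len(tm_list)
    if len(amplitudes) != len(tm_list):
        raise ValueError("one amplitude per transition midpoint")
    rng = np.random.default_rng(seed)
    t = np.arange(t_min, t_max + 1e-9, step)
    ratio = np.full_like(t, baseline)
    for tm, amp in zip(tm_list, amplitudes):
        if not t_min < tm < t_max:
            raise ValueError("every Tm must lie inside the temperature grid")
        ratio = ratio + amp / (1.0 + np.exp(-(t - tm) / width))
    if noise_sigma > 0:
        ratio = ratio + rng.normal(0.0, noise_sigma, size=t.shape)
    truth = {"tm_list": list(tm_list), "amplitudes": list(amplitudes),
             "width": width, "noise_sigma": noise_sigma}
    return MeltingCurve(temperature=t, ratio=np.maximum(ratio, 1e-6)), truth


# ---------------------------------------------------------------------------
# scattering experiments

def gen_bead_sphere(n_beads: int = 500, radius: float = 25.0,
                    seed: int = 0, jitter: float = 0.0,
                    chain_id: str = "A") -> StructureModel:
    """Solid sphere of residue beads (Rg = R sqrt(3/5) in the uniform limit).

    Beads sit on a cubic lattice clipped to the sphere (spacing chosen to
    give about ``n_beads`` sites) so the sample radius of gyration matches
    the continuum value closely; ``jitter`` adds Gaussian positional noise.
    """
    rng = np.random.default_rng(seed)
    spacing = (4.0 / 3.0 * math.pi * radius ** 3 / n_beads) ** (1.0 / 3.0)
    grid = np.arange(-radius, radius + spacing / 2, spacing)
    xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    if jitter > 0:
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    atoms = [_atom(i + 1, "CA", "C", "GLY", chain_id, i + 1, p)
             for i, p in enumerate(pts)]
    return StructureModel(atoms=atoms)


def gen_oligomer_models(n_beads: int = 150, radius: float = 16.0,
                        seed: int = 0) -> dict[str, StructureModel]:
    """A toy monomer globule and the corresponding side-by-side dimer."""
    mono = gen_bead_sphere(n_beads, radius, seed=seed)
    shift = np.array([2 * radius + 2.0, 0.0, 0.0])
    dimer_atoms = list(mono.atoms)
    for a in mono.atoms:
        dimer_atoms.append(AtomRecord(
            serial=a.serial + 10000, name=a.name, element=a.element,
            res_name=a.res_name, chain_id="B", res_seq=a.res_seq,
            alt_loc="", coords=a.coords + shift))
    return {"monomer": mono, "dimer": StructureModel(atoms=dimer_atoms)}


def gen_saxs_experiment(model: StructureModel,
                        ff: FormFactorMode = FormFactorMode.RESIDUE_BEAD,
                        noise_frac: float = 0.02, noise_floor: float = 0.0,
                        seed: int = 0,
                        q_grid: Optional[np.ndarray] = None,
                        ) -> tuple[SaxsCurve, dict]:
    """Noisy synthetic scattering experiment computed from a bead model.

    sigma = noise_frac * I + noise_floor per point; the intensity is
    perturbed by Gaussian noise of exactly that width, so fitting the
    source model back gives reduced chi^2 near 1.
    """
    rng = np.random.default_rng(seed)
    ideal = debye_curve(model, q_grid=q_grid, ff=ff)
    sigma = noise_frac * ideal.intensity + noise_floor
    positive_sigma = np.where(sigma > 0, sigma, 1e-9 * ideal.intensity.max())
    noisy = ideal.intensity + (rng.normal(0.0, 1.0, size=sigma.shape) * sigma
                               if noise_frac > 0 or noise_floor > 0 else 0.0)
    truth = {"noise_frac": noise_frac, "noise_floor": noise_floor}
    return SaxsCurve(q=ideal.q, intensity=noisy, sigma=positive_sigma), truth
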