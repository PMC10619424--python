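"""Small-angle X-ray scattering forward model and oligomer discrimination.

Computes scattering curves from coordinate models with the Debye formula

    I(q) = sum_i sum_j f_i f_j sin(q r_ij) / (q r_ij),

performs Guinier analysis (ln I linear in q^2 at low q, giving the radius
of gyration), fits calculated curves to experimental data with an optimal
multiplicative scale and a reduced chi^2, and ranks candidate oligomeric
models by fit quality. No hydration-shell or excluded-volume contrast
terms are applied, so absolute chi^2 against real detector data is not
comparable to solution-scattering packages that model them; the intended
use is relative discrimination between oligomeric states.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .structure import StructureModel

__all__ = [
    "SaxsCurve",
    "FormFactorMode",
    "SaxsFit",
    "debye_curve",
    "guinier_rg",
    "chi2_fit",
    "select_oligomer",
]

#: electron counts per element (q -> 0 form-factor scale)
ELEMENT_ELECTRONS: dict[str, float] = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15,
    "F": 9, "CL": 17, "BR": 35, "I": 53, "SE": 34, "FE": 26, "ZN": 30,
}

#: electron counts per standard amino-acid residue (neutral, with hydrogens)
RESIDUE_ELECTRONS: dict[str, float] = {
    "GLY": 30, "ALA": 38, "SER": 46, "CYS": 54, "THR": 54, "VAL": 54,
    "PRO": 52, "LEU": 62, "ILE": 62, "ASN": 60, "ASP": 59, "GLN": 68,
    "GLU": 67, "MET": 70, "HIS": 72, "LYS": 71, "PHE": 78, "ARG": 85,
    "TYR": 86, "TRP": 98,
}
GENERIC_RESIDUE_ELECTRONS = 62.0  # fallback for non-standard residues


class FormFactorMode(str, Enum):
    POINT = "POINT"  # every atom scatters with f = 1
    ELEMENT = "ELEMENT"  # per-element electron count at the q=0 scale
    RESIDUE_BEAD = "RESIDUE_BEAD"  # one bead per residue at CA, f = residue electrons


@dataclass
class SaxsCurve:
    """A scattering curve on a strictly increasing non-negative q grid."""

    q: np.ndarray  # 1/A
    intensity: np.ndarray  # arbitrary units
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.q.shape != self.intensity.shape or self.q.ndim != 1:
            raise ValueError("q and intensity must be 1-D of equal length")
        if self.q[0] < 0 or not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be non-negative and strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if self.sigma.shape != self.q.shape or np.any(self.sigma <= 0):
                raise ValueError("sigma must match q and be positive")

    @classmethod
    def from_text(cls, path: str) -> "SaxsCurve":
        data = np.loadtxt(path, comments="#")
        sigma = data[:, 2] if data.shape[1] >= 3 else None
        return cls(q=data[:, 0], intensity=data[:, 1], sigma=sigma)

    def to_text(self, path: str) -> None:
        cols = [self.q, self.intensity]
        header = "q_invA  intensity"
        if self.sigma is not None:
            cols.append(self.sigma)
            header += "  sigma"
        np.savetxt(path, np.column_stack(cols), fmt="%.8g", header=header)


DEFAULT_Q_GRID = np.linspace(0.01, 0.5, 250)


def _scatterers(model: StructureModel, mode: FormFactorMode) -> tuple[np.ndarray, np.ndarray]:
    """(coordinates, form factors) for the chosen coarse-graining."""
    if mode is FormFactorMode.RESIDUE_BEAD:
        xyz, f = [], []
        for a in model.atoms:
            if a.name == "CA" and not a.is_water:
                xyz.append(a.coords)
                f.append(RESIDUE_ELECTRONS.get(a.res_name, GENERIC_RESIDUE_ELECTRONS))
        if not xyz:  # models without CA atoms (bead files): every atom a bead
            for a in model.atoms:
                if not a.is_water:
                    xyz.append(a.coords)
                    f.append(RESIDUE_ELECTRONS.get(a.res_name, GENERIC_RESIDUE_ELECTRONS))
    else:
        xyz, f = [], []
        for a in model.atoms:
            if a.is_water or a.is_hydrogen:
                continue
            xyz.append(a.coords)
            f.append(1.0 if mode is FormFactorMode.POINT
                     else ELEMENT_ELECTRONS.get(a.element, 6.0))
    if not xyz:
        raise ValueError("model contains no scatterers")
    return np.asarray(xyz, float), np.asarray(f, float)


def debye_curve(model: StructureModel, q_grid: Optional[np.ndarray] = None,
                ff: FormFactorMode = FormFactorMode.RESIDUE_BEAD) -> SaxsCurve:
    """Forward-compute I(q) with the Debye formula.

    The self terms and the q -> 0 limit use sin(x)/x -> 1, so
    I(0) = (sum_i f_i)^2 exactly. O(N^2) in the number of scatterers: the
    default residue-bead coarse-graining keeps protein-size models fast.
    """
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, float)
    xyz, f = _scatterers(model, ff)
    n = len(f)
    self_term = float(np.sum(f * f))
    if n == 1:
        return SaxsCurve(q=q, intensity=np.full_like(q, self_term))
    d = pdist(xyz)  # matches np.triu_indices(n, k=1) ordering
    iu = np.triu_indices(n, k=1)
    fpair = f[iu[0]] * f[iu[1]]
    x = np.outer(q, d)  # (nq, npairs)
    sinc = np.sinc(x / np.pi)  # numpy sinc is sin(pi z)/(pi z)
    intensity = self_term + 2.0 * sinc @ fpair
    return SaxsCurve(q=q, intensity=intensity)


@dataclass(frozen=True)
class GuinierResult:
    rg: float  # A
    i0: float
    n_points: int
    qmax_used: float


def guinier_rg(curve: SaxsCurve, qmax_rg: float = 1.3,
               max_iter: int = 30) -> GuinierResult:
    """Radius of gyration from the Guinier approximation.

    Fits ln I = ln I0 - (Rg^2 / 3) q^2 by least squares, iteratively
    restricting the window to q Rg <= ``qmax_rg`` until the point set is
    stable. Raises if the low-q intensity does not decay.
    """
    q, I = curve.q, curve.intensity
    pos = I > 0
    q, I = q[pos], I[pos]
    if len(q) < 5:
        raise ValueError("need >= 5 positive-intensity points")
    mask = np.ones(len(q), bool)
    rg = None
    for _ in range(max_iter):
        if mask.sum() < 5:
            mask = np.zeros(len(q), bool)
            mask[:5] = True
        slope, intercept = np.polyfit(q[mask] ** 2, np.log(I[mask]), 1)
        if slope >= 0:
            raise ValueError("no Guinier decay: low-q slope is non-negative")
        new_rg = float(np.sqrt(-3.0 * slope))
        new_mask = q * new_rg <= qmax_rg
        if rg is not None and np.array_equal(new_mask, mask):
            rg = new_rg
            break
        mask, rg = new_mask, new_rg
    return GuinierResult(rg=rg, i0=float(np.exp(intercept)),
                         n_points=int(mask.sum()), qmax_used=float(q[mask].max()))


@dataclass(frozen=True)
class SaxsFit:
    scale: float
    chi2: float  # reduced, N-1 denominator
    n_points: int


def chi2_fit(exp: SaxsCurve, calc: SaxsCurve) -> SaxsFit:
    """Scale a calculated curve onto an experimental one and score it.

    The optimal scale is the weighted least-squares solution
    c = sum(I_exp I_calc / s^2) / sum(I_calc^2 / s^2); the reduced chi^2
    uses an N-1 denominator. The calculated curve is linearly resampled
    onto the experimental q grid when the grids differ.
    """
    if exp.sigma is None:
        raise ValueError("experimental curve must carry uncertainties")
    if len(exp.q) < 2:
        raise ValueError("need at least 2 points")
    if len(calc.q) == len(exp.q) and np.allclose(calc.q, exp.q):
        icalc = calc.intensity
    else:
        icalc = np.interp(exp.q, calc.q, calc.intensity)
    w = 1.0 / exp.sigma ** 2
    denom = float(np.sum(icalc ** 2 * w))
    if denom == 0:
        raise ValueError("calculated curve is identically zero")
    c = float(np.sum(exp.intensity * icalc * w) / denom)
    resid = (exp.intensity - c * icalc) / exp.sigma
    chi2 = float(np.sum(resid ** 2) / (len(exp.q) - 1))
    return SaxsFit(scale=c, chi2=chi2, n_points=len(exp.q))


def select_oligomer(exp: SaxsCurve, candidates: dict[str, StructureModel],
                    ff: FormFactorMode = FormFactorMode.RESIDUE_BEAD,
                    ) -> tuple[list[tuple[str, SaxsFit]], list[str]]:
    """Rank candidate oligomeric models by chi^2 against an experiment.

    Returns (ranking, notes): the ranking is ascending in chi^2 (ties broken
    by name, so ordering is stable); candidates whose curve cannot be
    computed are excluded with an explanatory note rather than aborting.
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate models")
    fits: list[tuple[str, SaxsFit]] = []
    notes: list[str] = []
    for name in sorted(candidates):
        try:
            calc = debye_curve(candidates[name], q_grid=exp.q, ff=ff)
            fits.append((name, chi2_fit(exp, calc)))
        except (ValueError, KeyError) as exc:
            notes.append(f"candidate {name!r} excluded: {exc}")
    fits.sort(key=lambda t: (t[1].chi2, t[0]))
    return fits, notes
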