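"""Thermokinetic post-processing.

Turns 1-D adiabatic-mapping energy profiles into activation barriers,
converts free-energy differences into rate ratios and dissociation
constants via the Boltzmann factor exp(dG / RT), compares enantiomer
stabilities, and extracts melting transitions from label-free differential
scanning fluorimetry (nanoDSF) curves, where transition midpoints appear as
peaks in the first derivative of the tryptophan F350/F330 ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "EnergyProfile",
    "BarrierResult",
    "ThermoConstants",
    "MeltingCurve",
    "MeltingResult",
    "extract_barrier",
    "rate_ratio",
    "kd_from_dg_diss",
    "enantiomer_stability_ratio",
    "melt_transitions",
]

#: gas constant, kcal / (mol K)
GAS_CONSTANT_KCAL = 1.987204e-3


@dataclass(frozen=True)
class ThermoConstants:
    gas_constant: float = GAS_CONSTANT_KCAL
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


@dataclass
class EnergyProfile:
    """Reaction coordinate (A, conventionally the O...C distance, decreasing
    in 0.025 A steps) versus total potential energy (kcal/mol).

    Index order defines the reaction direction: the reactant side comes
    first regardless of whether the coordinate decreases or increases.
    """

    coordinate: np.ndarray
    energy: np.ndarray

    def __post_init__(self) -> None:
        self.coordinate = np.asarray(self.coordinate, float)
        self.energy = np.asarray(self.energy, float)
        if self.coordinate.shape != self.energy.shape or self.coordinate.ndim != 1:
            raise ValueError("coordinate and energy must be 1-D of equal length")
        if len(self.coordinate) < 5:
            raise ValueError("profile needs at least 5 points")
        diffs = np.diff(self.coordinate)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("coordinate must be strictly monotone")

    @classmethod
    def from_text(cls, path: str) -> "EnergyProfile":
        data = np.loadtxt(path, comments="#")
        return cls(coordinate=data[:, 0], energy=data[:, 1])

    def to_text(self, path: str) -> None:
        np.savetxt(path, np.column_stack([self.coordinate, self.energy]),
                   fmt="%.6f", header="coordinate_A  energy_kcal_mol")


@dataclass(frozen=True)
class BarrierResult:
    delta_g_act: float  # kcal/mol
    ground_index: int
    ts_index: int
    ground_energy: float
    ts_energy: float


def extract_barrier(profile: EnergyProfile, refine_window: int = 2) -> BarrierResult:
    """Activation barrier from a single-barrier adiabatic-mapping profile.

    The transition state is the highest interior local maximum; the ground
    state is the minimum-energy point on the reactant side of it (earlier
    along the reaction direction), so a lower product basin is never picked
    as the ground state. delta_g_act = E_TS - E_ground >= 0.

    ``refine_window`` > 0 refits each stationary point's energy by a local
    quadratic over +/- that many grid points (vertex clamped to one grid
    step), which suppresses the selection bias of picking the noisiest
    sample as the extremum; 0 uses the raw point energies.
    """
    e = profile.energy
    n = len(e)
    interior_maxima = [i for i in range(1, n - 1)
                       if e[i] >= e[i - 1] and e[i] >= e[i + 1]
                       and (e[i] > e[i - 1] or e[i] > e[i + 1])]
    if not interior_maxima:
        raise ValueError("no transition state located: profile is monotone")
    ts = max(interior_maxima, key=lambda i: e[i])
    ground = int(np.argmin(e[:ts]))

    def refined_energy(idx: int) -> float:
        if refine_window < 1:
            return float(e[idx])
        lo, hi = max(0, idx - refine_window), min(n, idx + refine_window + 1)
        if hi - lo < 3:
            return float(e[idx])
        coeffs = np.polyfit(np.arange(lo, hi, dtype=float) - idx, e[lo:hi], 2)
        if coeffs[0] == 0:
            return float(e[idx])
        vertex = float(np.clip(-coeffs[1] / (2 * coeffs[0]), -1.0, 1.0))
        return float(np.polyval(coeffs, vertex))

    e_ts, e_ground = refined_energy(ts), refined_energy(ground)
    return BarrierResult(
        delta_g_act=float(max(e_ts - e_ground, 0.0)),
        ground_index=ground, ts_index=int(ts),
        ground_energy=e_ground, ts_energy=e_ts,
    )


def rate_ratio(delta_delta_g: float, const: Optional[ThermoConstants] = None) -> float:
    """Fold-change in rate for an activation-barrier difference.

    k_fast / k_slow = exp(ddG / RT) under transition-state theory with a
    shared prefactor; > 1 iff ddG > 0.
    """
    const = const or ThermoConstants()
    return math.exp(delta_delta_g / const.rt)


def kd_from_dg_diss(delta_g_diss: float, const: Optional[ThermoConstants] = None) -> float:
    """Dissociation constant from a dissociation free energy.

    K_d = exp(-dG_diss / RT) in standard-state units; a negative dG_diss
    (thermodynamically unstable complex) gives K_d > 1.
    """
    const = const or ThermoConstants()
    return math.exp(-delta_g_diss / const.rt)


def enantiomer_stability_ratio(dg_r: float, dg_s: float,
                               const: Optional[ThermoConstants] = None) -> float:
    """Boltzmann population ratio R/S from binding free energies.

    ratio = exp(-(dG_R - dG_S) / RT); > 1 iff the R pose is more stable
    (more negative dG_R).
    """
    const = const or ThermoConstants()
    return math.exp(-(dg_r - dg_s) / const.rt)


# ---------------------------------------------------------------------------
# melting curves

@dataclass
class MeltingCurve:
    """nanoDSF tryptophan fluorescence ratio (F350/F330) vs temperature."""

    temperature: np.ndarray  # degrees C, strictly increasing
    ratio: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, float)
        self.ratio = np.asarray(self.ratio, float)
        if self.temperature.shape != self.ratio.shape or self.temperature.ndim != 1:
            raise ValueError("temperature and ratio must be 1-D of equal length")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if np.any(self.ratio <= 0):
            raise ValueError("fluorescence ratio must be positive")

    @classmethod
    def from_text(cls, path: str) -> "MeltingCurve":
        data = np.loadtxt(path, comments="#")
        return cls(temperature=data[:, 0], ratio=data[:, 1])

    def to_text(self, path: str) -> None:
        np.savetxt(path, np.column_stack([self.temperature, self.ratio]),
                   fmt="%.6f", header="temperature_C  F350_F330")


@dataclass
class MeltingResult:
    tm_list: list[float]  # transition midpoints, degrees C, ascending
    derivative: np.ndarray  # d(ratio)/dT on the input grid


def melt_transitions(curve: MeltingCurve, smoothing_window: int = 5,
                     prominence_frac: float = 0.2,
                     derivative_floor: float = 1e-5) -> MeltingResult:
    """Transition midpoints as first-derivative peaks of the ratio curve.

    The ratio is moving-average smoothed, differentiated by central
    differences, and peaks exceeding ``prominence_frac`` of the global
    derivative maximum are reported; each peak position is refined as the
    centroid of the derivative above its half maximum, which averages the
    grid- and noise-jitter of the raw peak sample away. A flat curve
    (derivative below ``derivative_floor`` everywhere) yields an empty
    list, not an error.
    """
    t, r = curve.temperature, curve.ratio
    if len(t) < 20 or (t[-1] - t[0]) < 20.0:
        raise ValueError("need >= 20 points spanning >= 20 degrees C")
    w = max(1, int(smoothing_window))
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        rp = np.pad(r, pad, mode="edge")
        smooth = np.convolve(rp, kernel, mode="valid")[:len(r)]
    else:
        smooth = r
    deriv = np.gradient(smooth, t)
    dmax = float(np.max(deriv))
    if dmax < derivative_floor:
        return MeltingResult(tm_list=[], derivative=deriv)
    peaks, _ = find_peaks(deriv, prominence=prominence_frac * dmax)
    tms = []
    for p in peaks:
        half = 0.5 * deriv[p]
        lo = p
        while lo > 0 and deriv[lo - 1] > half:
            lo -= 1
        hi = p
        while hi < len(deriv) - 1 and deriv[hi + 1] > half:
            hi += 1
        w = deriv[lo:hi + 1] - half
        total = float(np.sum(w))
        tms.append(float(np.sum(t[lo:hi + 1] * w) / total) if total > 0
                   else float(t[p]))
    return MeltingResult(tm_list=sorted(tms), derivative=deriv)
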