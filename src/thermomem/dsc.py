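"""DSC thermogram processing: baselines, onset/maximum, enthalpy and entropy.

A differential scanning calorimetry thermogram is excess molar heat
capacity versus temperature. The processing chain mirrors standard
calorimetric practice for lipid phase transitions: subtract the solvent
reference scan, remove a manual two-point baseline, locate the event by
its onset (tangent at the steepest ascending point extrapolated to zero)
and its curve maximum (parabolically refined), integrate the excess heat
capacity over the event to get the calorimetric enthalpy dH_cal
(kJ mol^-1), and convert to an entropy change via

    dS = dH_cal / T      (T in kelvin, result in J K^-1 mol^-1)

using the temperature of the event maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

CELSIUS_TO_KELVIN = 273.15


@dataclass
class Thermogram:
    """Excess molar heat capacity (kJ mol^-1 K^-1) on a strictly increasing
    temperature grid (deg C)."""

    temperatures: np.ndarray
    excess_heat_capacity: np.ndarray
    scan_direction: str = "heating"
    label: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.excess_heat_capacity = np.asarray(self.excess_heat_capacity, dtype=float)
        if self.temperatures.shape != self.excess_heat_capacity.shape:
            raise ValueError("temperature and heat-capacity arrays must have equal length")
        if self.temperatures.ndim != 1 or self.temperatures.size < 2:
            raise ValueError("thermogram needs at least two points")
        if not (np.all(np.isfinite(self.temperatures))
                and np.all(np.isfinite(self.excess_heat_capacity))):
            raise ValueError("thermogram contains non-finite values")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperature grid must be strictly increasing")
        if self.scan_direction not in ("heating", "cooling"):
            raise ValueError("scan_direction must be 'heating' or 'cooling'")

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "temperature_C": self.temperatures,
            "cp_excess_kJ_per_mol_K": self.excess_heat_capacity,
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "Thermogram":
        df = pd.read_csv(path)
        for col in ("temperature_C", "cp_excess_kJ_per_mol_K"):
            if col not in df.columns:
                raise ValueError(f"thermogram CSV missing required column '{col}'")
        return cls(df["temperature_C"].to_numpy(),
                   df["cp_excess_kJ_per_mol_K"].to_numpy(), **kwargs)


class PeakResult(NamedTuple):
    T_max: float
    flags: tuple


class OnsetResult(NamedTuple):
    T_onset: float
    T_steepest: float
    slope: float


@dataclass
class ThermoEvent:
    """Derived thermodynamics of one thermotropic event."""

    T_onset: float
    T_max: float
    delta_H_cal: float  # kJ mol^-1
    delta_S: float      # J K^-1 mol^-1
    integration_bounds: tuple
    T_used_K: float
    flags: tuple = ()

    def to_dict(self) -> dict:
        return {
            "T_onset_C": self.T_onset,
            "T_max_C": self.T_max,
            "delta_H_cal_kJ_per_mol": self.delta_H_cal,
            "delta_S_J_per_K_mol": self.delta_S,
            "integration_bounds_C": list(self.integration_bounds),
            "T_used_K": self.T_used_K,
            "flags": list(self.flags),
        }


def subtract_reference(sample: Thermogram, reference: Thermogram) -> Thermogram:
    """Subtract the solvent reference scan, interpolated onto the sample grid.

    The result is restricted to the temperature overlap of the two scans.
    """
    lo = max(sample.temperatures[0], reference.temperatures[0])
    hi = min(sample.temperatures[-1], reference.temperatures[-1])
    mask = (sample.temperatures >= lo) & (sample.temperatures <= hi)
    if mask.sum() < 2:
        raise ValueError("sample and reference scans overlap in fewer than 2 points")
    T = sample.temperatures[mask]
    ref = np.interp(T, reference.temperatures, reference.excess_heat_capacity)
    return Thermogram(T, sample.excess_heat_capacity[mask] - ref,
                      scan_direction=sample.scan_direction, label=sample.label)


def two_point_baseline(t: Thermogram, T_left: float, T_right: float) -> Thermogram:
    """Subtract the straight line through the curve values at the two anchors.

    The output is exactly zero at both anchor temperatures; a purely linear
    input is annihilated identically.
    """
    if T_left >= T_right:
        raise ValueError("T_left must be smaller than T_right")
    if T_left < t.temperatures[0] or T_right > t.temperatures[-1]:
        raise ValueError("baseline anchors must lie inside the temperature grid")
    yL = np.interp(T_left, t.temperatures, t.excess_heat_capacity)
    yR = np.interp(T_right, t.temperatures, t.excess_heat_capacity)
    line = yL + (yR - yL) * (t.temperatures - T_left) / (T_right - T_left)
    return Thermogram(t.temperatures, t.excess_heat_capacity - line,
                      scan_direction=t.scan_direction, label=t.label)


def _window_mask(t: Thermogram, window) -> np.ndarray:
    if window is None:
        return np.ones_like(t.temperatures, dtype=bool)
    lo, hi = window
    return (t.temperatures >= lo) & (t.temperatures <= hi)


def peak_maximum(t: Thermogram, window=None) -> PeakResult:
    """Temperature of the curve maximum, refined parabolically.

    A parabola through the top three points interpolates the maximum below
    grid resolution; at a window edge the endpoint is returned with a
    ``"no interior maximum"`` flag, and an exact plateau returns its leftmost
    point flagged ``"plateau"``.
    """
    mask = _window_mask(t, window)
    if mask.sum() < 3:
        raise ValueError("peak window must contain at least 3 points")
    T = t.temperatures[mask]
    y = t.excess_heat_capacity[mask]
    flags: list = []
    ymax = y.max()
    idx = np.flatnonzero(y == ymax)
    i = int(idx[0])
    if idx.size > 1:
        flags.append("plateau")
    if i == 0 or i == y.size - 1:
        flags.append("no interior maximum")
        return PeakResult(float(T[i]), tuple(flags))
    x0, x1, x2 = T[i - 1], T[i], T[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x1 - x0) * (y1 - y2) - (x1 - x2) * (y1 - y0)
    if denom == 0 or flags:
        return PeakResult(float(x1), tuple(flags))
    vertex = x1 - 0.5 * ((x1 - x0) ** 2 * (y1 - y2) - (x1 - x2) ** 2 * (y1 - y0)) / denom
    return PeakResult(float(vertex), tuple(flags))


def onset_temperature(t: Thermogram, window=None) -> OnsetResult:
    """Onset by the tangent construction on a baseline-subtracted curve.

    The tangent at the steepest ascending point of the rising flank is
    extrapolated to the zero baseline; its intercept is the onset. For a
    Gaussian peak (center mu, width sigma) this gives mu - 2*sigma exactly.
    """
    mask = _window_mask(t, window)
    if mask.sum() < 3:
        raise ValueError("onset window must contain at least 3 points")
    T = t.temperatures[mask]
    y = t.excess_heat_capacity[mask]
    dy = np.gradient(y, T)
    i = int(np.argmax(dy))
    if dy[i] <= 0:
        raise ValueError("no positive slope in window: cannot construct an onset tangent")
    onset = T[i] - y[i] / dy[i]
    return OnsetResult(float(onset), float(T[i]), float(dy[i]))


def integrate_enthalpy(t: Thermogram, bounds) -> float:
    """Trapezoidal integral of the excess heat capacity over ``bounds``.

    Temperature differences in degC equal those in kelvin, so the result is
    directly kJ mol^-1. The native grid is used (no re-gridding); bound
    temperatures falling between grid points contribute interpolated nodes.
    """
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("integration bounds are reversed or empty")
    if lo < t.temperatures[0] or hi > t.temperatures[-1]:
        raise ValueError("integration bounds must lie inside the temperature grid")
    inner = (t.temperatures > lo) & (t.temperatures < hi)
    x = np.concatenate(([lo], t.temperatures[inner], [hi]))
    y = np.concatenate((
        [np.interp(lo, t.temperatures, t.excess_heat_capacity)],
        t.excess_heat_capacity[inner],
        [np.interp(hi, t.temperatures, t.excess_heat_capacity)],
    ))
    return float(np.trapezoid(y, x))


def entropy_from_enthalpy(delta_H_cal: float, T_K: float) -> float:
    """dS = dH_cal / T, converted from kJ to J: 1000 * dH / T_K."""
    if T_K <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return 1000.0 * delta_H_cal / T_K


def characterize_event(
    t: Thermogram,
    baseline_anchors,
    integration_bounds=None,
    window=None,
    T_K: float | None = None,
) -> ThermoEvent:
    """Full event characterization of one thermotropic event.

    Two-point baseline subtraction, onset and maximum within ``window``
    (default: between the anchors), enthalpy over ``integration_bounds``
    (default: the anchors), and entropy at ``T_K`` (default: the event
    maximum in kelvin).
    """
    corrected = two_point_baseline(t, *baseline_anchors)
    window = tuple(window) if window is not None else tuple(baseline_anchors)
    bounds = tuple(integration_bounds) if integration_bounds is not None else tuple(baseline_anchors)
    flags: list = []
    peak = peak_maximum(corrected, window)
    flags.extend(peak.flags)
    try:
        onset = onset_temperature(corrected, window).T_onset
    except ValueError:
        onset = float("nan")
        flags.append("no onset: non-positive slope in window")
    dH = integrate_enthalpy(corrected, bounds)
    T_used = float(T_K) if T_K is not None else peak.T_max + CELSIUS_TO_KELVIN
    dS = entropy_from_enthalpy(dH, T_used)
    span = corrected.excess_heat_capacity
    scale = float(np.max(np.abs(t.excess_heat_capacity)))
    if scale == 0.0 or float(np.max(np.abs(span))) < 1e-9 * max(scale, 1.0):
        flags.append("zero event: curve is flat after baseline subtraction")
    if not (bounds[0] < peak.T_max < bounds[1]):
        flags.append("integration bounds do not bracket the event maximum")
    return ThermoEvent(
        T_onset=onset, T_max=peak.T_max, delta_H_cal=dH, delta_S=dS,
        integration_bounds=bounds, T_used_K=T_used, flags=tuple(flags),
    )
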