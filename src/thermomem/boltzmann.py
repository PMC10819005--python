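"""Boltzmann sigmoid fits for melting-curve transition temperatures.

The concentration profile obtained by projecting temperature-dependent
turbidity spectra onto one component is a melting curve: lipid bilayers
with a pretransition and a main phase transition trace a double sigmoid,
a single thermotropic event a single sigmoid. Both are modelled with the
standard Boltzmann form

    y(T) = A2 + (A1 - A2) / (1 + exp((T - T0)/dT))

for which the inflection point is exactly T0 and dT sets the transition
width (a measure of cooperativity). The double model shares one amplitude
span split by a mixing fraction f:

    y(T) = A2 + (A1 - A2) * [ f/(1 + exp((T - T01)/dT1))
                              + (1 - f)/(1 + exp((T - T02)/dT2)) ]

which is algebraically equivalent to two independent amplitudes but has a
smaller non-identifiability surface. Fitting is bounded nonlinear least
squares from three deterministic initial guesses; the best residual wins,
ties broken by smaller total width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .spectra import ConcentrationProfile, savitzky_golay

__all__ = [
    "TransitionFit",
    "single_boltzmann",
    "double_boltzmann",
    "boltzmann_initial_guess",
    "fit_single_boltzmann",
    "fit_double_boltzmann",
]


def single_boltzmann(T, A1, A2, T0, dT):
    """y(T) = A2 + (A1 - A2)/(1 + exp((T - T0)/dT)); inflection at T0."""
    T = np.asarray(T, dtype=float)
    return A2 + (A1 - A2) * expit(-(T - T0) / dT)


def double_boltzmann(T, A1, A2, T01, dT1, T02, dT2, f):
    """Shared-amplitude double sigmoid; inflection points at T01 and T02."""
    T = np.asarray(T, dtype=float)
    g1 = expit(-(T - T01) / dT1)
    g2 = expit(-(T - T02) / dT2)
    return A2 + (A1 - A2) * (f * g1 + (1.0 - f) * g2)


@dataclass
class TransitionFit:
    """Parameters and diagnostics of a single/double Boltzmann fit.

    ``inflection_temps`` holds one value (single model) or two, sorted
    ascending (double model). ``parameter_covariance`` is the Jacobian-based
    covariance at the optimum, rows/columns ordered as ``param_names``.
    """

    model: str  # "single" | "double"
    A1: float
    A2: float
    inflection_temps: tuple
    widths: tuple
    f: float | None
    r_squared: float
    parameter_covariance: np.ndarray
    param_names: tuple
    converged: bool
    flags: list = field(default_factory=list)
    n_points: int = 0
    ss_res: float = float("nan")

    def predict(self, T):
        if self.model == "single":
            return single_boltzmann(T, self.A1, self.A2, *self.inflection_temps, *self.widths)
        return double_boltzmann(
            T, self.A1, self.A2,
            self.inflection_temps[0], self.widths[0],
            self.inflection_temps[1], self.widths[1], self.f,
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "A1": self.A1,
            "A2": self.A2,
            "inflection_temps_C": list(self.inflection_temps),
            "widths_C": list(self.widths),
            "f": self.f,
            "r_squared": self.r_squared,
            "param_names": list(self.param_names),
            "parameter_covariance": np.asarray(self.parameter_covariance).tolist(),
            "converged": self.converged,
            "flags": list(self.flags),
            "n_points": self.n_points,
        }


def _profile_arrays(profile):
    if isinstance(profile, ConcentrationProfile):
        return profile.temperatures, profile.values
    T, y = profile
    return np.asarray(T, dtype=float), np.asarray(y, dtype=float)


def boltzmann_initial_guess(profile, n_transitions: int = 1):
    """Deterministic starting parameters from the data itself.

    Baselines come from the first/last 10% means; inflection candidates from
    extrema of the smoothed numerical derivative; widths from the derivative
    peak's half-maximum extent. A constant profile falls back to range
    midpoints and is flagged.
    """
    T, y = _profile_arrays(profile)
    n = T.size
    flags: list = []
    span = T[-1] - T[0] if n > 1 else 1.0
    if n < 3 or np.ptp(y) == 0.0:
        flags.append("constant profile: fallback initial guess")
        mid = float(np.mean(T)) if n else 0.0
        base = float(y[0]) if n else 0.0
        if n_transitions == 1:
            return np.array([base, base, mid, max(span / 10.0, 1e-3)]), flags
        return (
            np.array([base, base, mid - span / 4, max(span / 10.0, 1e-3),
                      mid + span / 4, max(span / 10.0, 1e-3), 0.5]),
            flags,
        )

    k = max(2, int(round(0.1 * n)))
    A1 = float(np.mean(y[:k]))
    A2 = float(np.mean(y[-k:]))
    ys = y
    w = min(11, n if n % 2 == 1 else n - 1)
    if w >= 5:
        ys = savitzky_golay(y, w, min(3, w - 1))
    dy = np.gradient(ys, T)
    mag = np.abs(dy)

    def peak_width(idx):
        half = mag[idx] / 2.0
        left = idx
        while left > 0 and mag[left] > half:
            left -= 1
        right = idx
        while right < n - 1 and mag[right] > half:
            right += 1
        fwhm = T[right] - T[left]
        # for a Boltzmann sigmoid the derivative FWHM is ~3.525 * dT
        return max(fwhm / 3.525, span / 50.0)

    if n_transitions == 1:
        i0 = int(np.argmax(mag))
        return np.array([A1, A2, float(T[i0]), peak_width(i0)]), flags

    # local maxima of |dy| separated by at least two grid steps
    cand = [i for i in range(1, n - 1) if mag[i] >= mag[i - 1] and mag[i] >= mag[i + 1]]
    cand.sort(key=lambda i: -mag[i])
    picked: list = []
    for i in cand:
        if all(abs(i - j) >= 2 for j in picked):
            picked.append(i)
        if len(picked) == 2:
            break
    if len(picked) < 2:
        flags.append("fewer than two derivative extrema: quantile fallback")
        t1 = T[0] + 0.25 * span
        t2 = T[0] + 0.75 * span
        return np.array([A1, A2, t1, span / 10.0, t2, span / 10.0, 0.5]), flags
    i1, i2 = sorted(picked)
    m1, m2 = mag[i1], mag[i2]
    f0 = float(m1 / (m1 + m2)) if (m1 + m2) > 0 else 0.5
    f0 = min(0.9, max(0.1, f0))
    return (
        np.array([A1, A2, float(T[i1]), peak_width(i1), float(T[i2]), peak_width(i2), f0]),
        flags,
    )


def _covariance(res, n, p):
    ss_res = 2.0 * res.cost
    dof = max(n - p, 1)
    J = res.jac
    try:
        cov = np.linalg.pinv(J.T @ J) * (ss_res / dof)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return cov, ss_res


def _run_multistart(resid, starts, bounds):
    best = None
    best_key = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0] + 1e-12, bounds[1] - 1e-12)
        try:
            res = least_squares(
                resid, x0, bounds=bounds, method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
            )
        except Exception:
            continue
        width_total = _total_width(res.x)
        key = (res.cost, width_total)  # ties broken by smaller total width
        if best is None or key < best_key:
            best, best_key = res, key
    return best


def _total_width(x):
    # parameter vectors: single [A1,A2,T0,dT]; double [A1,A2,T01,dT1,T02,dT2,f]
    return float(x[3]) if x.size == 4 else float(x[3] + x[5])


def _check_fittable(T, y, min_points, what):
    if T.size < min_points:
        raise ValueError(f"{what} requires at least {min_points} points (got {T.size})")
    if np.ptp(y) == 0.0:
        raise ValueError(f"constant profile: {what} inflection point is unidentifiable")


def fit_single_boltzmann(profile) -> TransitionFit:
    """Least-squares single Boltzmann fit; T0 is reported as the inflection point."""
    T, y = _profile_arrays(profile)
    _check_fittable(T, y, 6, "single Boltzmann fit")
    span = T[-1] - T[0]
    ymin, ymax = float(np.min(y)), float(np.max(y))
    ypad = 10.0 * (ymax - ymin)
    lb = np.array([ymin - ypad, ymin - ypad, T[0] - span, 1e-4 * span])
    ub = np.array([ymax + ypad, ymax + ypad, T[-1] + span, 10.0 * span])

    g0, flags = boltzmann_initial_guess((T, y), 1)
    k = max(2, int(round(0.1 * T.size)))
    A1, A2 = float(np.mean(y[:k])), float(np.mean(y[-k:]))
    starts = [
        g0,
        np.array([A1, A2, float(0.5 * (T[0] + T[-1])), span / 10.0]),
        np.array([A1, A2, float(np.sum(T * np.abs(np.gradient(y, T))) /
                                max(np.sum(np.abs(np.gradient(y, T))), 1e-300)),
                  span / 20.0]),
    ]

    def resid(x):
        return single_boltzmann(T, *x) - y

    res = _run_multistart(resid, starts, (lb, ub))
    if res is None:
        raise RuntimeError("single Boltzmann fit failed from every start")
    cov, ss_res = _covariance(res, T.size, 4)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    converged = bool(res.success)
    if not converged:
        flags.append(f"optimizer did not converge: {res.message}")
    A1o, A2o, T0, dT = (float(v) for v in res.x)
    return TransitionFit(
        model="single", A1=A1o, A2=A2o,
        inflection_temps=(T0,), widths=(dT,), f=None,
        r_squared=r2, parameter_covariance=cov,
        param_names=("A1", "A2", "T0", "dT"),
        converged=converged, flags=flags, n_points=int(T.size), ss_res=ss_res,
    )


def fit_double_boltzmann(profile) -> TransitionFit:
    """Least-squares double Boltzmann fit; inflection points reported sorted.

    If the two optima are closer than the larger width, the transitions are
    not separable at this resolution and the fit is flagged
    ``"unresolved transitions"`` rather than silently reported.
    """
    T, y = _profile_arrays(profile)
    _check_fittable(T, y, 10, "double Boltzmann fit")
    span = T[-1] - T[0]
    ymin, ymax = float(np.min(y)), float(np.max(y))
    ypad = 10.0 * (ymax - ymin)
    lb = np.array([ymin - ypad, ymin - ypad, T[0] - span, 1e-4 * span,
                   T[0] - span, 1e-4 * span, 1e-3])
    ub = np.array([ymax + ypad, ymax + ypad, T[-1] + span, 10.0 * span,
                   T[-1] + span, 10.0 * span, 1.0 - 1e-3])

    g0, flags = boltzmann_initial_guess((T, y), 2)
    k = max(2, int(round(0.1 * T.size)))
    A1, A2 = float(np.mean(y[:k])), float(np.mean(y[-k:]))
    starts = [
        g0,
        np.array([A1, A2, T[0] + 0.25 * span, span / 10.0,
                  T[0] + 0.75 * span, span / 10.0, 0.5]),
        np.array([A1, A2, T[0] + 0.35 * span, span / 20.0,
                  T[0] + 0.65 * span, span / 20.0, 0.3]),
    ]

    def resid(x):
        return double_boltzmann(T, *x) - y

    res = _run_multistart(resid, starts, (lb, ub))
    if res is None:
        raise RuntimeError("double Boltzmann fit failed from every start")
    cov, ss_res = _covariance(res, T.size, 7)
    x = res.x.copy()
    if x[2] > x[4]:  # reorder so T01 < T02; f -> 1-f; permute covariance
        perm = [0, 1, 4, 5, 2, 3, 6]
        x = x[perm]
        x[6] = 1.0 - x[6]
        P = np.eye(7)[perm]
        S = np.diag([1, 1, 1, 1, 1, 1, -1.0])
        cov = S @ P @ cov @ P.T @ S
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    converged = bool(res.success)
    if not converged:
        flags.append(f"optimizer did not converge: {res.message}")
    A1o, A2o, T01, dT1, T02, dT2, f = (float(v) for v in x)
    if abs(T02 - T01) < max(dT1, dT2):
        flags.append("unresolved transitions")
    return TransitionFit(
        model="double", A1=A1o, A2=A2o,
        inflection_temps=(T01, T02), widths=(dT1, dT2), f=f,
        r_squared=r2, parameter_covariance=cov,
        param_names=("A1", "A2", "T01", "dT1", "T02", "dT2", "f"),
        converged=converged, flags=flags, n_points=int(T.size), ss_res=ss_res,
    )
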