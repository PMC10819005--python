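"""Temperature-resolved absorbance spectra and rank-1 multivariate curve resolution.

Turbidity spectra of liposome suspensions recorded on a wavelength x
temperature grid form a data matrix ``D`` that, for a system whose
temperature-dependent variability is carried by a single species, obeys the
bilinear model ``D = c s^T + E``: one concentration profile ``c`` over
temperature, one spectral profile ``s`` over wavelength, and a residual
``E``. Projecting onto that single component turns a stack of spectra into
one melting curve whose inflection points are the phase-transition
temperatures of the bilayer.

This module holds the matrix container with its CSV dialect, the
Savitzky-Golay smoother used to condition raw spectra, wavelength-range
restriction, and the rank-1 factorization itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter


def _check_strictly_increasing(x: np.ndarray, name: str) -> None:
    if x.ndim != 1 or x.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
    if x.size > 1 and not np.all(np.diff(x) > 0):
        raise ValueError(f"{name} must be strictly increasing")


@dataclass
class SpectraMatrix:
    """Absorbance on a wavelength (rows) x temperature (columns) grid.

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing
    temperatures : array, deg C, strictly increasing
    absorbance : array (n_wavelengths, n_temperatures), AU
    label : free-text sample description
    """

    wavelengths: np.ndarray
    temperatures: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        _check_strictly_increasing(self.wavelengths, "wavelengths")
        _check_strictly_increasing(self.temperatures, "temperatures")
        if self.absorbance.shape != (self.wavelengths.size, self.temperatures.size):
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"({self.wavelengths.size}, {self.temperatures.size}) grid"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains missing or non-finite values")

    # -- CSV dialect: first column 'wavelength_nm', remaining headers are
    #    temperatures in deg C (numeric), UTF-8, decimal point.

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.absorbance, columns=self.temperatures)
        df.insert(0, "wavelength_nm", self.wavelengths)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "SpectraMatrix":
        df = pd.read_csv(path)
        if df.columns[0] != "wavelength_nm":
            raise ValueError("spectra CSV must start with a 'wavelength_nm' column")
        try:
            temps = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise ValueError("spectra CSV column headers must be numeric temperatures") from exc
        return cls(df["wavelength_nm"].to_numpy(), temps, df.iloc[:, 1:].to_numpy(), label=label)


@dataclass
class SpectralProfile:
    """One column of the spectral factor S: unit Euclidean norm over wavelength."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have equal length")
        nrm = np.linalg.norm(self.values)
        if abs(nrm - 1.0) > 1e-9:
            raise ValueError(f"spectral profile must have unit norm (got {nrm})")


@dataclass
class ConcentrationProfile:
    """One column of the concentration factor C: arbitrary units vs temperature."""

    temperatures: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temperatures.shape != self.values.shape:
            raise ValueError("temperatures and values must have equal length")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"temperature_C": self.temperatures, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConcentrationProfile":
        df = pd.read_csv(path)
        for col in ("temperature_C", "value"):
            if col not in df.columns:
                raise ValueError(f"concentration-profile CSV missing column '{col}'")
        return cls(df["temperature_C"].to_numpy(), df["value"].to_numpy())


@dataclass
class McrResult:
    """Rank-1 factorization D = c s^T + E of a spectra matrix."""

    concentration: ConcentrationProfile
    spectrum: SpectralProfile
    residual_matrix: np.ndarray
    explained_variance_fraction: float
    n_iterations: int = 0
    converged: bool = True

    def reconstruction(self) -> np.ndarray:
        return np.outer(self.spectrum.values, self.concentration.values)


def savitzky_golay(values, window_points: int = 11, poly_degree: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing: local least-squares polynomial per point.

    Interior points use the symmetric window (delegated to
    :func:`scipy.signal.savgol_filter`, which computes exactly the local
    polynomial value); endpoints are re-fit on asymmetric windows clipped to
    the available points, so a series that is exactly a polynomial of the
    fitted degree is reproduced everywhere.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("savitzky_golay expects a 1-D series")
    if window_points % 2 == 0:
        raise ValueError(
            f"window_points must be odd: a Savitzky-Golay window is symmetric about "
            f"the smoothed point (got {window_points}; nearest valid choices are "
            f"{window_points - 1} and {window_points + 1})"
        )
    if window_points < 5:
        raise ValueError("window_points must be an odd integer >= 5")
    if poly_degree >= window_points:
        raise ValueError("poly_degree must be smaller than window_points")
    if v.size < window_points:
        raise ValueError(
            f"series of length {v.size} is shorter than window_points={window_points}"
        )
    out = savgol_filter(v, window_points, poly_degree, mode="interp")
    half = window_points // 2
    for i in list(range(half)) + list(range(v.size - half, v.size)):
        lo = max(0, i - half)
        hi = min(v.size, i + half + 1)
        x = np.arange(lo, hi, dtype=float) - i
        deg = min(poly_degree, hi - lo - 1)
        coef = np.polynomial.polynomial.polyfit(x, v[lo:hi], deg)
        out[i] = coef[0]
    return out


def smooth_spectra(m: SpectraMatrix, window_points: int = 11, poly_degree: int = 3) -> SpectraMatrix:
    """Smooth each temperature's spectrum along the wavelength axis."""
    sm = np.column_stack(
        [savitzky_golay(m.absorbance[:, j], window_points, poly_degree)
         for j in range(m.temperatures.size)]
    )
    return SpectraMatrix(m.wavelengths, m.temperatures, sm, label=m.label)


def restrict_range(m: SpectraMatrix, lambda_min: float, lambda_max: float) -> SpectraMatrix:
    """Keep only wavelengths within [lambda_min, lambda_max] nm."""
    if lambda_min >= lambda_max:
        raise ValueError("lambda_min must be smaller than lambda_max")
    mask = (m.wavelengths >= lambda_min) & (m.wavelengths <= lambda_max)
    if not mask.any():
        raise ValueError(
            f"wavelength range [{lambda_min}, {lambda_max}] nm does not overlap the "
            f"grid [{m.wavelengths[0]}, {m.wavelengths[-1]}] nm"
        )
    return SpectraMatrix(m.wavelengths[mask], m.temperatures, m.absorbance[mask], label=m.label)


def mcr_rank1(m: SpectraMatrix, tol: float = 1e-13, max_iter: int = 1000) -> McrResult:
    """Best rank-1 bilinear factorization of the spectra matrix.

    Alternating least squares for one unconstrained component: holding the
    spectral profile fixed, the optimal concentration profile is a linear
    projection, and vice versa, so the iteration is a power method on
    ``D^T D`` and converges to the leading singular pair — the global
    least-squares optimum, unique up to sign and scale.

    Conventions: the spectral profile has unit Euclidean norm and its entry
    sum is non-negative; all magnitude is carried by the concentration
    profile. Explained variance is computed on the raw (uncentered) matrix,
    matching a bilinear model with no offset term.
    """
    D = m.absorbance
    if D.shape[0] < 2 or D.shape[1] < 2:
        raise ValueError("mcr_rank1 needs a matrix of at least 2 x 2")
    total = float(np.sum(D * D))
    if total == 0.0:
        raise ValueError("all-zero matrix: rank-1 factorization is undefined up to scale")

    # deterministic start: column-norm vector (never orthogonal to the
    # leading right singular vector for data with a dominant component)
    c = np.sqrt(np.sum(D * D, axis=0))
    c /= np.linalg.norm(c)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        s = D @ c
        s /= np.linalg.norm(s)
        c_new = D.T @ s
        c_dir = c_new / np.linalg.norm(c_new)
        if np.linalg.norm(c_dir - c) < tol:
            c = c_dir
            converged = True
            break
        c = c_dir
    s = D @ c
    sigma = np.linalg.norm(s)
    s /= sigma
    if s.sum() < 0:  # sign convention: predominantly non-negative spectrum
        s = -s
    conc_values = D.T @ s  # optimal concentration for the fixed unit spectrum
    recon = np.outer(s, conc_values)
    E = D - recon
    evf = 1.0 - float(np.sum(E * E)) / total
    evf = min(1.0, max(0.0, evf))
    return McrResult(
        concentration=ConcentrationProfile(m.temperatures, conc_values),
        spectrum=SpectralProfile(m.wavelengths, s),
        residual_matrix=E,
        explained_variance_fraction=evf,
        n_iterations=n_iter,
        converged=converged,
    )
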