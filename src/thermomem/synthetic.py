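"""Synthetic data with known ground truth for every downstream stage.

Three generators emulate the raw inputs of the analysis chain so that the
whole pipeline is testable without instrument data or simulations:

* :func:`gen_uvvis_series` — temperature-dependent turbidity spectra built
  as an exact rank-1 outer product of a smooth spectral profile (default
  Rayleigh-like, lambda^-4) and a single/double Boltzmann concentration
  profile, plus i.i.d. Gaussian noise;
* :func:`gen_dsc_curve` — endothermic Gaussian peaks of exactly specified
  area on a linear baseline;
* :func:`gen_toy_trajectory` — a coarse bilayer slab (one phosphorus, one
  choline nitrogen, two phosphate oxygens and two straight acyl chains per
  lipid) plus a charged peptide, with hydrogen bonds / salt bridges /
  contacts planted at exact distances in every frame.

All randomness comes from one explicit integer seed per call; generators
are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .dsc import Thermogram
from .spectra import SpectraMatrix
from .trajectory import MolecularSystem, Trajectory

__all__ = [
    "SpectraGenSpec", "DscGenSpec", "GaussianPeak", "ToySystemSpec",
    "PlantedContact", "gen_uvvis_series", "gen_dsc_curve", "gen_toy_trajectory",
]


# ---------------------------------------------------------------- UV-Vis

@dataclass
class SpectraGenSpec:
    """Ground truth for a temperature-dependent turbidity data matrix.

    ``transition_temps`` (1 or 2 values, deg C) and ``transition_widths``
    are the Boltzmann inflection points and widths; ``amplitudes`` the step
    height of each transition (AU); ``direction`` whether turbidity grows
    or falls with temperature; ``baseline`` a constant offset keeping the
    concentration profile positive (default 10% of the total amplitude).
    """

    wavelength_grid: np.ndarray
    temperature_grid: np.ndarray
    transition_temps: tuple
    transition_widths: tuple
    amplitudes: tuple
    direction: str = "decreasing"
    noise_sd: float = 0.0
    seed: int = 0
    baseline: float | None = None

    def __post_init__(self) -> None:
        self.wavelength_grid = np.asarray(self.wavelength_grid, dtype=float)
        self.temperature_grid = np.asarray(self.temperature_grid, dtype=float)
        self.transition_temps = tuple(float(t) for t in np.atleast_1d(self.transition_temps))
        self.transition_widths = tuple(float(w) for w in np.atleast_1d(self.transition_widths))
        self.amplitudes = tuple(float(a) for a in np.atleast_1d(self.amplitudes))
        for grid, name in ((self.wavelength_grid, "wavelength_grid"),
                           (self.temperature_grid, "temperature_grid")):
            if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
                raise ValueError(f"{name} must be strictly increasing with >= 2 points")
        n = len(self.transition_temps)
        if not 1 <= n <= 2:
            raise ValueError("transition_temps must contain 1 or 2 values")
        if len(self.transition_widths) != n or len(self.amplitudes) != n:
            raise ValueError("transition_widths and amplitudes must match transition_temps")
        if any(w <= 0 for w in self.transition_widths):
            raise ValueError("transition widths must be positive")
        if n == 2 and abs(self.transition_temps[0] - self.transition_temps[1]) \
                < max(self.transition_widths):
            raise ValueError(
                "transition temperatures overlap within their widths: "
                "ground truth would be ill-posed"
            )
        if self.direction not in ("increasing", "decreasing"):
            raise ValueError("direction must be 'increasing' or 'decreasing'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline is None:
            self.baseline = 0.1 * sum(self.amplitudes)

    def concentration_truth(self, temperatures=None) -> np.ndarray:
        """Noise-free concentration profile on the given (default own) grid."""
        T = np.asarray(temperatures if temperatures is not None
                       else self.temperature_grid, dtype=float)
        c = np.full_like(T, float(self.baseline))
        for t0, w, a in zip(self.transition_temps, self.transition_widths,
                            self.amplitudes):
            g = expit(-(T - t0) / w)  # 1 -> 0 with temperature
            c += a * (g if self.direction == "decreasing" else 1.0 - g)
        return c

    def spectrum_truth(self) -> np.ndarray:
        """Unit-norm Rayleigh-like spectral profile (lambda^-4)."""
        s = (self.wavelength_grid[0] / self.wavelength_grid) ** 4
        return s / np.linalg.norm(s)


def gen_uvvis_series(spec: SpectraGenSpec) -> SpectraMatrix:
    """Rank-1 data matrix D = s c^T plus seeded Gaussian noise."""
    s = spec.spectrum_truth()
    c = spec.concentration_truth()
    D = np.outer(s, c)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        D = D + rng.normal(0.0, spec.noise_sd, D.shape)
    return SpectraMatrix(spec.wavelength_grid, spec.temperature_grid, D,
                         label=f"synthetic turbidity (seed {spec.seed})")


# ---------------------------------------------------------------- DSC

@dataclass
class GaussianPeak:
    """One endothermic event: center/width in deg C, area in kJ mol^-1."""

    center: float
    width: float
    area: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.area < 0:
            raise ValueError("peak area must be non-negative")


@dataclass
class DscGenSpec:
    """Ground truth for a thermogram: Gaussian peaks on a linear baseline."""

    temperature_grid: np.ndarray
    peaks: tuple = ()
    baseline_intercept: float = 0.0
    baseline_slope: float = 0.0  # kJ mol^-1 K^-1 per deg C
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.temperature_grid = np.asarray(self.temperature_grid, dtype=float)
        if self.temperature_grid.ndim != 1 or self.temperature_grid.size < 2 \
                or not np.all(np.diff(self.temperature_grid) > 0):
            raise ValueError("temperature_grid must be strictly increasing with >= 2 points")
        self.peaks = tuple(
            p if isinstance(p, GaussianPeak) else GaussianPeak(**p) for p in self.peaks
        )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_dsc_curve(spec: DscGenSpec) -> Thermogram:
    """Thermogram with analytically known peak areas; seeded noise."""
    T = spec.temperature_grid
    cp = spec.baseline_intercept + spec.baseline_slope * T
    for p in spec.peaks:
        if p.center - 4 * p.width < T[0] or p.center + 4 * p.width > T[-1]:
            warnings.warn(
                f"peak at {p.center} deg C extends beyond the temperature grid by "
                f"more than 4 widths: its area is not fully representable",
                stacklevel=2,
            )
        cp = cp + p.area / (p.width * np.sqrt(2 * np.pi)) \
            * np.exp(-0.5 * ((T - p.center) / p.width) ** 2)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        cp = cp + rng.normal(0.0, spec.noise_sd, cp.shape)
    return Thermogram(T, cp, label=f"synthetic DSC (seed {spec.seed})")


# ---------------------------------------------------------------- toy system

# side-chain construction: (atom name, element, donor, acceptor, cationic, anionic)
_SIDECHAINS = {
    "LYS": ("NZ", "N", True, False, True, False),
    "ARG": ("NH1", "N", True, False, True, False),
    "SER": ("OG", "O", True, True, False, False),
    "GLU": ("OE1", "O", False, True, False, True),
    "ASP": ("OD1", "O", False, True, False, True),
}
_CC_STEP = 0.127          # nm, acyl C-C projection step
_DH_BOND = 0.10           # nm, donor-hydrogen bond length


@dataclass
class PlantedContact:
    """Exact residue-to-lipid-group distance realized in every frame.

    ``residue_index`` is 0-based within the peptide; ``partner_group`` is
    ``"phosphate"`` or ``"choline"``; ``distance`` in nm is the minimum
    distance from the residue's key side-chain heavy atom to the partner
    group, exact by construction.
    """

    residue_index: int
    partner_group: str
    distance: float

    def __post_init__(self) -> None:
        if self.partner_group not in ("phosphate", "choline"):
            raise ValueError("partner_group must be 'phosphate' or 'choline'")
        if self.distance <= 0:
            raise ValueError("planted distance must be positive")


@dataclass
class ToySystemSpec:
    """Bilayer slab + charged peptide with controllable planted geometry."""

    lipids_per_leaflet: int = 16
    box: tuple = (4.0, 4.0, 12.0)
    headgroup_z_planes: tuple = (3.0, 7.8)
    chain_tilt_deg: float = 0.0
    chain_carbons: int = 8
    peptide_residues: tuple = ("LYS", "ARG", "SER", "GLY")
    planted_contacts: tuple = ()
    n_frames: int = 5
    dt_ns: float = 1.0
    peptide_height: float = 1.2   # nm above the top headgroup plane
    peptide_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.box = tuple(float(b) for b in self.box)
        self.headgroup_z_planes = tuple(float(z) for z in self.headgroup_z_planes)
        self.planted_contacts = tuple(
            c if isinstance(c, PlantedContact) else PlantedContact(**c)
            for c in self.planted_contacts
        )
        if self.lipids_per_leaflet <= 0:
            raise ValueError("lipids_per_leaflet must be positive")
        if len(self.box) != 3 or any(b <= 0 for b in self.box):
            raise ValueError("box must be three positive lengths (nm)")
        if len(self.headgroup_z_planes) != 2:
            raise ValueError("exactly two headgroup planes (two leaflets) required")
        if not self.headgroup_z_planes[0] < self.headgroup_z_planes[1]:
            raise ValueError("headgroup planes must be ordered bottom < top")
        if self.chain_carbons < 8:
            raise ValueError("acyl chains need >= 8 carbons")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        half_min = min(self.box) / 2
        seen = set()
        for c in self.planted_contacts:
            if not 0 <= c.residue_index < len(self.peptide_residues):
                raise ValueError(f"planted residue_index {c.residue_index} out of range")
            if c.residue_index in seen:
                raise ValueError("at most one planted contact per residue")
            seen.add(c.residue_index)
            if c.distance >= half_min:
                raise ValueError(
                    f"planted distance {c.distance} nm exceeds half the smallest box "
                    f"edge ({half_min} nm): minimum image is ambiguous"
                )


class _Builder:
    def __init__(self):
        self.names, self.elements, self.residx, self.resname = [], [], [], []
        self.tag, self.pos = [], []
        self.donor, self.acceptor = [], []
        self.h_ref, self.cat, self.an = [], [], []
        self.is_p, self.is_n, self.is_cc, self.is_ca = [], [], [], []
        self.chain, self.cpos = [], []

    def add(self, name, element, residx, resname, tag, pos, *, donor=False,
            acceptor=False, h_ref=-1, cat=-1, an=-1, is_p=False, is_n=False,
            chain="", cpos=-1, is_ca=False):
        self.names.append(name)
        self.elements.append(element)
        self.residx.append(residx)
        self.resname.append(resname)
        self.tag.append(tag)
        self.pos.append(np.asarray(pos, dtype=float))
        self.donor.append(donor)
        self.acceptor.append(acceptor)
        self.h_ref.append(h_ref)
        self.cat.append(cat)
        self.an.append(an)
        self.is_p.append(is_p)
        self.is_n.append(is_n)
        self.is_cc.append(chain != "")
        self.chain.append(chain)
        self.cpos.append(cpos)
        self.is_ca.append(is_ca)
        return len(self.names) - 1


def gen_toy_trajectory(spec: ToySystemSpec):
    """Build the labelled toy system and its (mostly static) trajectory.

    Lipids sit on a lateral grid, phosphorus atoms exactly on the headgroup
    planes (so thickness equals the plane separation), acyl chains straight
    at the requested tilt. Peptide residues sit ``peptide_height`` nm above
    the upper leaflet except planted ones, whose key atom is moved to the
    exact requested distance above the partner group atom with its hydrogen
    collinear toward the partner (so a planted 0.30 nm phosphate contact is
    simultaneously a textbook hydrogen bond and salt bridge).

    Returns ``(MolecularSystem, Trajectory)``.
    """
    b = _Builder()
    bx, by, bz = spec.box
    z_bot, z_top = spec.headgroup_z_planes
    tilt = np.radians(spec.chain_tilt_deg)
    n = spec.lipids_per_leaflet
    nx = int(np.ceil(np.sqrt(n)))
    dx, dy = bx / nx, by / nx

    residx = 0
    top_o13 = []       # (x, y, atom index) of top-leaflet phosphate oxygen
    top_n = []
    lipid_of_res = {}
    for leaflet, z_plane in ((0, z_bot), (1, z_top)):
        inward = 1.0 if leaflet == 0 else -1.0   # chains point to the midplane
        chain_dir = np.array([np.sin(tilt), 0.0, inward * np.cos(tilt)])
        for l in range(n):
            ix, iy = l % nx, l // nx
            x = (ix + 0.5) * dx
            y = (iy + 0.5) * dy
            an_id = residx
            b.add("N", "N", residx, "DPPC", "lipid",
                  (x + 0.28, y, z_plane - inward * 0.14), is_n=True)
            b.add("P", "P", residx, "DPPC", "lipid", (x, y, z_plane),
                  is_p=True, an=an_id)
            i_o13 = b.add("O13", "O", residx, "DPPC", "lipid",
                          (x + 0.11, y, z_plane), acceptor=True, an=an_id)
            b.add("O14", "O", residx, "DPPC", "lipid",
                  (x - 0.11, y, z_plane), acceptor=True, an=an_id)
            if leaflet == 1:
                top_o13.append((x, y, i_o13))
                top_n.append((x, y, len(b.names) - 4))
            for chain_label, x_off in (("sn1", -0.08), ("sn2", 0.08)):
                start = np.array([x + x_off, y, z_plane + inward * 0.35])
                for c in range(spec.chain_carbons):
                    b.add(f"C{c + 1}{'A' if chain_label == 'sn1' else 'B'}", "C",
                          residx, "DPPC", "lipid",
                          start + c * _CC_STEP * chain_dir,
                          chain=chain_label, cpos=c + 1)
            lipid_of_res[residx] = (x, y)
            residx += 1

    n_lipids = residx
    planted_by_res = {c.residue_index: c for c in spec.planted_contacts}
    planted_atoms = set()
    cat_id = 0
    peptide_res_start = residx
    for r, resname in enumerate(spec.peptide_residues):
        x_r = min((0.5 + r) * 0.45, bx - 0.2)
        y_r = by / 2.0
        base = np.array([x_r, y_r, z_top + spec.peptide_height])
        planted = planted_by_res.get(r)
        side = _SIDECHAINS.get(resname)
        ca_pos = base + np.array([0.0, 0.0, 0.25])
        key_pos = base
        h_dir = np.array([0.0, 0.0, 1.0])   # point H away from the membrane
        if planted is not None:
            anchors = top_o13 if planted.partner_group == "phosphate" else top_n
            ax, ay, a_idx = min(
                anchors, key=lambda t: (t[0] - x_r) ** 2 + (t[1] - y_r) ** 2)
            target = b.pos[a_idx]
            key_pos = target + np.array([0.0, 0.0, planted.distance])
            ca_pos = key_pos + np.array([0.0, 0.0, 0.25])
            h_dir = np.array([0.0, 0.0, -1.0])  # collinear D-H...A
        if side is None:
            # no side chain (e.g. GLY): CA is the key atom
            i_ca = b.add("CA", "C", residx, resname, "protein",
                         key_pos if planted is not None else ca_pos, is_ca=True)
            if planted is not None:
                planted_atoms.add(i_ca)
        else:
            name, element, donor, acceptor, cationic, anionic = side
            i_ca = b.add("CA", "C", residx, resname, "protein", ca_pos, is_ca=True)
            i_key = b.add(name, element, residx, resname, "protein", key_pos,
                          donor=donor, acceptor=acceptor,
                          cat=cat_id if cationic else -1,
                          an=(n_lipids + residx) if anionic else -1)
            if cationic:
                cat_id += 1
            if donor:
                b.add("H" + name[1:] + "1", "H", residx, resname, "protein",
                      key_pos + _DH_BOND * h_dir, h_ref=i_key)
            if planted is not None:
                planted_atoms.update({i_ca, i_key, len(b.names) - 1})
        residx += 1

    system = MolecularSystem(
        names=np.array(b.names, dtype=object),
        elements=np.array(b.elements, dtype=object),
        residue_index=np.array(b.residx),
        residue_name=np.array(b.resname, dtype=object),
        molecule_tag=np.array(b.tag, dtype=object),
        hb_donor=np.array(b.donor),
        hb_acceptor=np.array(b.acceptor),
        hydrogen_donor_ref=np.array(b.h_ref),
        cationic_group=np.array(b.cat),
        anionic_group=np.array(b.an),
        is_phosphorus=np.array(b.is_p),
        is_choline_nitrogen=np.array(b.is_n),
        is_chain_carbon=np.array(b.is_cc),
        chain_label=np.array(b.chain, dtype=object),
        carbon_position=np.array(b.cpos),
        is_calpha=np.array(b.is_ca),
    )
    base_pos = np.stack(b.pos)
    positions = np.repeat(base_pos[None, :, :], spec.n_frames, axis=0)
    if spec.peptide_jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        movable = np.flatnonzero(
            (system.molecule_tag == "protein")
            & ~np.isin(np.arange(system.n_atoms), sorted(planted_atoms))
            & np.isin(system.residue_index,
                      [peptide_res_start + r for r in range(len(spec.peptide_residues))
                       if r not in planted_by_res])
        )
        positions[:, movable, :] += rng.normal(
            0.0, spec.peptide_jitter_sd, (spec.n_frames, movable.size, 3))
    traj = Trajectory(
        positions=positions,
        box=np.tile(np.array(spec.box), (spec.n_frames, 1)),
        time=np.arange(spec.n_frames, dtype=float) * spec.dt_ns,
    )
    return system, traj
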