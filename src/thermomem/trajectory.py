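"""Protein-membrane interaction and membrane-structure metrics.

Operates on labelled coordinate trajectories in orthorhombic periodic
boxes (nm, ns). Atom semantics — hydrogen-bond donors/acceptors, charged
groups, phosphorus, choline nitrogen, acyl-chain carbons, C-alpha — are
carried by :class:`MolecularSystem` role arrays rather than inferred here,
so toy systems can declare them explicitly and file readers can assign
them from lookup tables.

Geometric conventions (the underlying experiments' ecosystem defaults, all
exposed as parameters):

* contact: heavy-atom pair within 0.60 nm (minimum image)
* hydrogen bond: donor-acceptor distance <= 0.35 nm and
  hydrogen-donor-acceptor angle <= 30 deg
* salt bridge: charged N...O distance <= 0.40 nm between a formally
  cationic group (Lys NZ, Arg guanidinium) and an anionic group
  (phosphate oxygens), counted once per group pair per frame
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CONTACT_CUTOFF = 0.60   # nm
DEFAULT_HB_R_CUT = 0.35         # nm, donor-acceptor
DEFAULT_HB_ANGLE_CUT = 30.0     # deg, H-D-A
DEFAULT_SB_CUTOFF = 0.40        # nm, charged heavy atoms


# ---------------------------------------------------------------- containers

@dataclass
class MolecularSystem:
    """Static topology: names, residue bookkeeping and role flags.

    ``hydrogen_donor_ref[i]`` holds, for a hydrogen atom ``i``, the index of
    the donor heavy atom it is bonded to (-1 otherwise). Group ids in
    ``cationic_group`` / ``anionic_group`` are -1 for atoms outside any
    charged group. ``chain_label`` is ``"sn1"``/``"sn2"`` for acyl-chain
    carbons (empty otherwise) with 1-based ``carbon_position``.
    """

    names: np.ndarray
    elements: np.ndarray
    residue_index: np.ndarray        # 0-based, contiguous per molecule
    residue_name: np.ndarray
    molecule_tag: np.ndarray         # protein | lipid | ion | water
    hb_donor: np.ndarray = None
    hb_acceptor: np.ndarray = None
    hydrogen_donor_ref: np.ndarray = None
    cationic_group: np.ndarray = None
    anionic_group: np.ndarray = None
    is_phosphorus: np.ndarray = None
    is_choline_nitrogen: np.ndarray = None
    is_chain_carbon: np.ndarray = None
    chain_label: np.ndarray = None
    carbon_position: np.ndarray = None
    is_calpha: np.ndarray = None

    def __post_init__(self) -> None:
        n = len(self.names)
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.molecule_tag = np.asarray(self.molecule_tag, dtype=object)
        bool_defaults = ("hb_donor", "hb_acceptor", "is_phosphorus",
                         "is_choline_nitrogen", "is_chain_carbon", "is_calpha")
        for name in bool_defaults:
            v = getattr(self, name)
            setattr(self, name, np.zeros(n, dtype=bool) if v is None
                    else np.asarray(v, dtype=bool))
        int_defaults = ("hydrogen_donor_ref", "cationic_group", "anionic_group",
                        "carbon_position")
        for name in int_defaults:
            v = getattr(self, name)
            setattr(self, name, np.full(n, -1, dtype=int) if v is None
                    else np.asarray(v, dtype=int))
        if self.chain_label is None:
            self.chain_label = np.array([""] * n, dtype=object)
        else:
            self.chain_label = np.asarray(self.chain_label, dtype=object)
        for name in ("elements", "residue_index", "residue_name", "molecule_tag",
                     "hb_donor", "hb_acceptor", "hydrogen_donor_ref",
                     "cationic_group", "anionic_group", "is_phosphorus",
                     "is_choline_nitrogen", "is_chain_carbon", "chain_label",
                     "carbon_position", "is_calpha"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"role array '{name}' length mismatch")
        bad = np.flatnonzero((self.hydrogen_donor_ref >= 0)
                             & (self.elements != "H"))
        if bad.size:
            raise ValueError("hydrogen_donor_ref set on non-hydrogen atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def heavy(self) -> np.ndarray:
        return self.elements != "H"

    def select(self, *, molecule_tag=None, heavy=False, flag=None,
               residue_index=None) -> np.ndarray:
        """Atom indices matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if molecule_tag is not None:
            mask &= self.molecule_tag == molecule_tag
        if heavy:
            mask &= self.heavy
        if flag is not None:
            mask &= getattr(self, flag)
        if residue_index is not None:
            mask &= self.residue_index == residue_index
        return np.flatnonzero(mask)

    def residue_label(self, residue_index: int) -> str:
        """1-based report-style label, e.g. '129ARG'."""
        i = np.flatnonzero(self.residue_index == residue_index)
        name = self.residue_name[i[0]] if i.size else "?"
        return f"{residue_index + 1}{name}"


@dataclass
class Trajectory:
    """Per-frame positions (nm), orthorhombic box lengths (nm), times (ns)."""

    positions: np.ndarray   # (n_frames, n_atoms, 3)
    box: np.ndarray         # (n_frames, 3)
    time: np.ndarray        # (n_frames,)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        nf = self.positions.shape[0]
        if self.box.shape != (nf, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        if self.time.shape != (nf,):
            raise ValueError("time must have one entry per frame")
        if nf > 1 and not np.all(np.diff(self.time) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]


@dataclass
class InteractionSeries:
    """Per-frame protein-membrane interaction counts (Fig. 4/5-style series)."""

    time: np.ndarray
    min_distance: np.ndarray
    n_contacts: np.ndarray
    n_hbonds: np.ndarray
    n_salt_bridges: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ns": self.time,
            "min_distance_nm": self.min_distance,
            "n_contacts": self.n_contacts,
            "n_hbonds": self.n_hbonds,
            "n_salt_bridges": self.n_salt_bridges,
        })


@dataclass
class OrderParameterProfile:
    """Deuterium order parameter S_CD per acyl-chain carbon position."""

    chain: str
    carbon_positions: np.ndarray
    s_cd: np.ndarray


# ---------------------------------------------------------------- geometry

def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors to their nearest periodic image."""
    return d - box * np.round(d / box)


def _pair_distances(pos, box, sel_a, sel_b) -> np.ndarray:
    d = pos[np.asarray(sel_a)][:, None, :] - pos[np.asarray(sel_b)][None, :, :]
    d = minimum_image(d, box)
    return np.sqrt(np.sum(d * d, axis=-1))


def min_distance(pos: np.ndarray, box: np.ndarray, sel_a, sel_b) -> float:
    """Minimum over all A x B pairs of the minimum-image distance (nm)."""
    sel_a = np.asarray(sel_a)
    sel_b = np.asarray(sel_b)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("min_distance: empty selection")
    dist = _pair_distances(pos, box, sel_a, sel_b)
    same = sel_a[:, None] == sel_b[None, :]
    if same.any():
        dist = np.where(same, np.inf, dist)
    return float(dist.min())


def count_contacts(pos, box, sel_a, sel_b,
                   cutoff: float = DEFAULT_CONTACT_CUTOFF) -> int:
    """Number of A-B pairs within ``cutoff`` nm (minimum image)."""
    sel_a = np.asarray(sel_a)
    sel_b = np.asarray(sel_b)
    if sel_a.size == 0 or sel_b.size == 0:
        raise ValueError("count_contacts: empty selection")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff > np.min(box) / 2:
        raise ValueError(
            f"cutoff {cutoff} nm exceeds half the smallest box edge "
            f"({np.min(box) / 2:.3f} nm): minimum image is ambiguous"
        )
    dist = _pair_distances(pos, box, sel_a, sel_b)
    within = dist <= cutoff
    same = sel_a[:, None] == sel_b[None, :]
    within &= ~same
    return int(np.count_nonzero(within))


def detect_hbonds(system: MolecularSystem, pos, box, donor_sel, acceptor_sel,
                  r_cut: float = DEFAULT_HB_R_CUT,
                  angle_cut_deg: float = DEFAULT_HB_ANGLE_CUT) -> list:
    """Geometric hydrogen bonds as (donor, hydrogen, acceptor) index triples.

    Criterion: minimum-image donor-acceptor distance <= ``r_cut`` and
    hydrogen-donor-acceptor angle <= ``angle_cut_deg``.
    """
    donor_sel = np.asarray(donor_sel)
    acceptor_sel = np.asarray(acceptor_sel)
    if donor_sel.size == 0 or acceptor_sel.size == 0:
        return []
    hydrogens_of: dict = {}
    for h in np.flatnonzero(system.hydrogen_donor_ref >= 0):
        hydrogens_of.setdefault(int(system.hydrogen_donor_ref[h]), []).append(int(h))
    missing = [int(d) for d in donor_sel if int(d) not in hydrogens_of]
    if missing:
        raise ValueError(
            f"donor atoms without a referenced hydrogen: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    dist = _pair_distances(pos, box, donor_sel, acceptor_sel)
    bonds = []
    cos_cut = np.cos(np.radians(angle_cut_deg))
    for i, d in enumerate(donor_sel):
        close = np.flatnonzero(dist[i] <= r_cut)
        for j in close:
            a = int(acceptor_sel[j])
            if a == int(d):
                continue
            va = minimum_image(pos[a] - pos[d], box)
            for h in hydrogens_of[int(d)]:
                vh = minimum_image(pos[h] - pos[d], box)
                denom = np.linalg.norm(va) * np.linalg.norm(vh)
                if denom == 0:
                    continue
                if np.dot(va, vh) / denom >= cos_cut:
                    bonds.append((int(d), h, a))
    return bonds


def detect_salt_bridges(system: MolecularSystem, pos, box,
                        cation_groups=None, anion_groups=None,
                        cutoff: float = DEFAULT_SB_CUTOFF) -> list:
    """Salt bridges as (cationic_group_id, anionic_group_id) pairs.

    A bridge exists when the minimum distance between the charged heavy
    atoms of the two groups is <= ``cutoff``; each group pair is counted at
    most once per frame.
    """
    if cation_groups is None:
        cation_groups = np.unique(system.cationic_group[system.cationic_group >= 0])
    if anion_groups is None:
        anion_groups = np.unique(system.anionic_group[system.anionic_group >= 0])
    cat_atoms = {int(g): np.flatnonzero((system.cationic_group == g) & system.heavy)
                 for g in cation_groups}
    an_atoms = {int(g): np.flatnonzero((system.anionic_group == g) & system.heavy)
                for g in anion_groups}
    for g, atoms in list(cat_atoms.items()) + list(an_atoms.items()):
        if atoms.size == 0:
            raise ValueError(f"charged group {g} has no charged heavy atoms")
    bridges = []
    for cg, ca in cat_atoms.items():
        for ag, aa in an_atoms.items():
            if _pair_distances(pos, box, ca, aa).min() <= cutoff:
                bridges.append((cg, ag))
    return bridges


# ---------------------------------------------------------------- series

@dataclass
class InteractionParams:
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    hb_r_cut: float = DEFAULT_HB_R_CUT
    hb_angle_cut_deg: float = DEFAULT_HB_ANGLE_CUT
    sb_cutoff: float = DEFAULT_SB_CUTOFF


def _hb_partners(system, sel_a, sel_b):
    """Donor/acceptor index pairs for H-bonds across two selections."""
    a = np.asarray(sel_a)
    b = np.asarray(sel_b)
    don_a = a[system.hb_donor[a]]
    acc_a = a[system.hb_acceptor[a]]
    don_b = b[system.hb_donor[b]]
    acc_b = b[system.hb_acceptor[b]]
    return (don_a, acc_b), (don_b, acc_a)


def _frame_interactions(system, pos, box, protein_sel, lipid_sel, params):
    p_heavy = protein_sel[system.heavy[protein_sel]]
    l_heavy = lipid_sel[system.heavy[lipid_sel]]
    md = min_distance(pos, box, p_heavy, l_heavy)
    nc = count_contacts(pos, box, p_heavy, l_heavy, params.contact_cutoff)
    nhb = 0
    for don, acc in _hb_partners(system, protein_sel, lipid_sel):
        if don.size and acc.size:
            nhb += len(detect_hbonds(system, pos, box, don, acc,
                                     params.hb_r_cut, params.hb_angle_cut_deg))
    cat = np.unique(system.cationic_group[protein_sel])
    cat = cat[cat >= 0]
    an = np.unique(system.anionic_group[lipid_sel])
    an = an[an >= 0]
    nsb = 0
    if cat.size and an.size:
        nsb = len(detect_salt_bridges(system, pos, box, cat, an, params.sb_cutoff))
    return md, nc, nhb, nsb


def interaction_series(system: MolecularSystem, traj: Trajectory,
                       protein_sel=None, lipid_sel=None,
                       params: InteractionParams | None = None) -> InteractionSeries:
    """Apply the four interaction detectors to every frame."""
    if params is None:
        params = InteractionParams()
    if protein_sel is None:
        protein_sel = system.select(molecule_tag="protein")
    if lipid_sel is None:
        lipid_sel = system.select(molecule_tag="lipid")
    protein_sel = np.asarray(protein_sel)
    lipid_sel = np.asarray(lipid_sel)
    nf = traj.n_frames
    md = np.empty(nf)
    nc = np.empty(nf, dtype=int)
    nhb = np.empty(nf, dtype=int)
    nsb = np.empty(nf, dtype=int)
    for f in range(nf):
        md[f], nc[f], nhb[f], nsb[f] = _frame_interactions(
            system, traj.positions[f], traj.box[f], protein_sel, lipid_sel, params)
    return InteractionSeries(traj.time.copy(), md, nc, nhb, nsb)


def per_residue_interactions(system: MolecularSystem, traj: Trajectory,
                             window_ns: float,
                             params: InteractionParams | None = None,
                             protein_sel=None, lipid_sel=None) -> pd.DataFrame:
    """Per-residue mean H-bond and contact counts over the trailing window.

    Frames with ``time > t_end - window_ns`` are averaged. Returns a
    DataFrame with columns ``residue``, ``avg_hbonds``, ``avg_contacts``
    sorted by ``avg_hbonds`` descending (report presentation order).
    """
    if params is None:
        params = InteractionParams()
    if protein_sel is None:
        protein_sel = system.select(molecule_tag="protein")
    if lipid_sel is None:
        lipid_sel = system.select(molecule_tag="lipid")
    protein_sel = np.asarray(protein_sel)
    lipid_sel = np.asarray(lipid_sel)
    span = traj.time[-1] - traj.time[0]
    if window_ns > span and traj.n_frames > 1:
        raise ValueError(f"window {window_ns} ns exceeds trajectory span {span} ns")
    sel_frames = np.flatnonzero(traj.time > traj.time[-1] - window_ns)
    if sel_frames.size == 0:
        sel_frames = np.array([traj.n_frames - 1])
    residues = np.unique(system.residue_index[protein_sel])
    hb_sum = {int(r): 0 for r in residues}
    ct_sum = {int(r): 0 for r in residues}
    l_heavy = lipid_sel[system.heavy[lipid_sel]]
    for f in sel_frames:
        pos, box = traj.positions[f], traj.box[f]
        for don, acc in _hb_partners(system, protein_sel, lipid_sel):
            if not (don.size and acc.size):
                continue
            for d, h, a in detect_hbonds(system, pos, box, don, acc,
                                         params.hb_r_cut, params.hb_angle_cut_deg):
                prot_atom = d if system.molecule_tag[d] == "protein" else a
                hb_sum[int(system.residue_index[prot_atom])] += 1
        for r in residues:
            res_atoms = protein_sel[
                (system.residue_index[protein_sel] == r) & system.heavy[protein_sel]]
            if res_atoms.size:
                ct_sum[int(r)] += count_contacts(pos, box, res_atoms, l_heavy,
                                                 params.contact_cutoff)
    nf = sel_frames.size
    df = pd.DataFrame({
        "residue": [system.residue_label(int(r)) for r in residues],
        "residue_index": residues + 1,
        "avg_hbonds": [hb_sum[int(r)] / nf for r in residues],
        "avg_contacts": [ct_sum[int(r)] / nf for r in residues],
    })
    return df.sort_values("avg_hbonds", ascending=False, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------- membrane

def area_per_lipid(box: np.ndarray, n_lipids_per_leaflet: int) -> float:
    """Lateral box area divided by lipids per leaflet (nm^2)."""
    if n_lipids_per_leaflet <= 0:
        raise ValueError("n_lipids_per_leaflet must be positive")
    return float(box[0] * box[1] / n_lipids_per_leaflet)


def membrane_thickness(pos: np.ndarray, phosphorus_sel) -> float:
    """Distance between mean phosphorus z of the two leaflets (nm).

    Leaflets are split by the mean phosphorus z (the bilayer midplane).
    """
    phosphorus_sel = np.asarray(phosphorus_sel)
    if phosphorus_sel.size == 0:
        raise ValueError("membrane_thickness: no phosphorus atoms selected")
    z = pos[phosphorus_sel, 2]
    mid = z.mean()
    top = z[z > mid]
    bottom = z[z <= mid]
    if top.size == 0 or bottom.size == 0:
        raise ValueError("all phosphorus atoms in one leaflet: no bilayer found")
    return float(abs(top.mean() - bottom.mean()))


def axis_order_parameter(vectors: np.ndarray) -> float:
    """Mean second Legendre polynomial of the angle to z: <(3 cos^2 t - 1)/2>."""
    v = np.asarray(vectors, dtype=float).reshape(-1, 3)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length axis vector")
    cos2 = (v[:, 2] / norms) ** 2
    return float(np.mean(1.5 * cos2 - 0.5))


def deuterium_order_parameters(system: MolecularSystem, traj: Trajectory,
                               chains=("sn1", "sn2")) -> dict:
    """S_CD per carbon position for each acyl chain.

    With no explicit hydrogens, the local chain axis at carbon i is the
    C(i-1) -> C(i+1) vector; C-H bonds lie perpendicular to it, so the
    reported value is S_CD = -S_axis/2 where S_axis is the axis's second
    Legendre order parameter relative to the bilayer normal (z). Terminal
    carbons have no axis and are absent from the profile. Range:
    S_CD = -0.5 for chains exactly along z, 0 for isotropic chains.
    """
    profiles = {}
    for chain in chains:
        mask = system.is_chain_carbon & (system.chain_label == chain)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        by_res: dict = {}
        for i in idx:
            by_res.setdefault(int(system.residue_index[i]), []).append(
                (int(system.carbon_position[i]), int(i)))
        sums: dict = {}
        counts: dict = {}
        for frame in range(traj.n_frames):
            pos = traj.positions[frame]
            box = traj.box[frame]
            for carbons in by_res.values():
                carbons = sorted(carbons)
                pos_of = dict(carbons)
                for cpos, ci in carbons:
                    if (cpos - 1) not in pos_of or (cpos + 1) not in pos_of:
                        continue
                    v = minimum_image(pos[pos_of[cpos + 1]] - pos[pos_of[cpos - 1]], box)
                    nrm = np.linalg.norm(v)
                    if nrm == 0:
                        continue
                    p2 = 1.5 * (v[2] / nrm) ** 2 - 0.5
                    sums[cpos] = sums.get(cpos, 0.0) + p2
                    counts[cpos] = counts.get(cpos, 0) + 1
        if not sums:
            continue
        positions = np.array(sorted(sums))
        s_cd = np.array([-0.5 * sums[p] / counts[p] for p in positions])
        profiles[chain] = OrderParameterProfile(chain, positions, s_cd)
    return profiles


# ---------------------------------------------------------------- PCA

def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation matrix minimizing RMSD of centered P onto centered Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


@dataclass
class PcaResult:
    eigenvalues: np.ndarray     # descending, nm^2
    eigenvectors: np.ndarray    # columns, 3N
    projections: np.ndarray     # (n_frames, 3N)
    mean: np.ndarray            # 3N

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())


def calpha_pca(traj: Trajectory, calpha_sel, fit: bool = True) -> PcaResult:
    """Essential-dynamics PCA of C-alpha coordinates.

    Each frame is translationally and rotationally (Kabsch) fitted onto the
    first frame's C-alpha set, then the 3N x 3N positional covariance
    (population normalisation over frames) is eigen-decomposed. Eigenvalues
    are returned descending; projections are per-frame coordinates along
    each mode.
    """
    calpha_sel = np.asarray(calpha_sel)
    if calpha_sel.size == 0:
        raise ValueError("calpha_pca: empty C-alpha selection")
    if traj.n_frames < 2:
        raise ValueError("calpha_pca needs at least 2 frames")
    ref = traj.positions[0][calpha_sel]
    ref = ref - ref.mean(axis=0)
    coords = np.empty((traj.n_frames, calpha_sel.size * 3))
    for f in range(traj.n_frames):
        X = traj.positions[f][calpha_sel]
        X = X - X.mean(axis=0)
        if fit:
            R = _kabsch(X, ref)
            X = X @ R.T
        coords[f] = X.ravel()
    mean = coords.mean(axis=0)
    Xc = coords - mean
    C = (Xc.T @ Xc) / traj.n_frames
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    projections = Xc @ evecs
    return PcaResult(evals, evecs, projections, mean)
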