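"""Structure/trajectory file I/O and role assignment.

Coordinate formats (PDB, GRO, XTC) carry no hydrogen-bond or charge
semantics, so reading returns a :class:`~thermomem.trajectory.MolecularSystem`
whose role flags are filled from an editable lookup table keyed by residue
and atom name. The shipped default table covers the coarse toy naming used
by the synthetic generator plus the common charged/donor atoms of standard
amino acids; real force-field naming schemes can be supplied as a custom
table (a plain dict, loadable from YAML).

Parsing and writing delegate to MDAnalysis; units are converted at the
boundary (MDAnalysis uses Angstrom and ps, this package nm and ns).
"""

from __future__ import annotations

import re
import warnings

import numpy as np

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

from .trajectory import MolecularSystem, Trajectory

NM_PER_ANGSTROM = 0.1
_CHAIN_CARBON_RE = re.compile(r"^C(\d+)([AB])$")

#: role lookup: resname -> atom name -> set of role keywords.
#: keywords: donor, acceptor, cation, anion, phosphorus, choline, calpha
DEFAULT_ROLE_TABLE = {
    "DPPC": {
        "P": {"phosphorus", "anion"},
        "O13": {"acceptor", "anion"},
        "O14": {"acceptor", "anion"},
        "N": {"choline"},
    },
    "LYS": {"CA": {"calpha"}, "NZ": {"donor", "cation"}},
    "ARG": {"CA": {"calpha"}, "NH1": {"donor", "cation"},
            "NH2": {"donor", "cation"}, "NE": {"donor", "cation"}},
    "SER": {"CA": {"calpha"}, "OG": {"donor", "acceptor"}},
    "THR": {"CA": {"calpha"}, "OG1": {"donor", "acceptor"}},
    "GLU": {"CA": {"calpha"}, "OE1": {"acceptor", "anion"},
            "OE2": {"acceptor", "anion"}},
    "ASP": {"CA": {"calpha"}, "OD1": {"acceptor", "anion"},
            "OD2": {"acceptor", "anion"}},
}

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_WATER_RESNAMES = {"SOL", "HOH", "TIP3", "WAT"}
_ION_RESNAMES = {"NA", "CL", "SOD", "CLA", "K", "MG", "CA2"}


def _molecule_tag(resname: str) -> str:
    if resname in _PROTEIN_RESNAMES:
        return "protein"
    if resname in _WATER_RESNAMES:
        return "water"
    if resname in _ION_RESNAMES:
        return "ion"
    return "lipid"


def _guess_element(name: str) -> str:
    stripped = name.lstrip("0123456789")
    return stripped[0].upper() if stripped else "X"


def assign_roles(system: MolecularSystem, positions: np.ndarray | None = None,
                 role_table: dict | None = None,
                 hydrogen_bond_length: float = 0.125) -> MolecularSystem:
    """Fill role flags in place from a (resname, atom name) lookup table.

    Chain carbons are recognized by the ``C<position><A|B>`` naming pattern
    (A = sn1, B = sn2). Charged groups get one id per residue. If
    ``positions`` (frame 0, nm) is given, each hydrogen is attached to the
    nearest donor heavy atom of its residue within ``hydrogen_bond_length``
    nm, populating ``hydrogen_donor_ref``.
    """
    table = DEFAULT_ROLE_TABLE if role_table is None else role_table
    system.cationic_group[:] = -1
    system.anionic_group[:] = -1
    system.hydrogen_donor_ref[:] = -1
    system.is_chain_carbon[:] = False
    system.carbon_position[:] = -1
    system.chain_label[:] = ""
    cat_ids: dict = {}
    an_ids: dict = {}
    for i in range(system.n_atoms):
        roles = table.get(str(system.residue_name[i]), {}).get(str(system.names[i]), set())
        system.hb_donor[i] = "donor" in roles
        system.hb_acceptor[i] = "acceptor" in roles
        system.is_phosphorus[i] = "phosphorus" in roles
        system.is_choline_nitrogen[i] = "choline" in roles
        system.is_calpha[i] = "calpha" in roles or (
            str(system.names[i]) == "CA" and system.molecule_tag[i] == "protein")
        res = int(system.residue_index[i])
        if "cation" in roles:
            system.cationic_group[i] = cat_ids.setdefault(res, len(cat_ids))
        if "anion" in roles:
            system.anionic_group[i] = an_ids.setdefault(res, len(an_ids))
        m = _CHAIN_CARBON_RE.match(str(system.names[i]))
        if m and system.molecule_tag[i] == "lipid":
            system.is_chain_carbon[i] = True
            system.carbon_position[i] = int(m.group(1))
            system.chain_label[i] = "sn1" if m.group(2) == "A" else "sn2"
    if positions is not None:
        donors = np.flatnonzero(system.hb_donor)
        for h in np.flatnonzero(system.elements == "H"):
            res_donors = donors[system.residue_index[donors] == system.residue_index[h]]
            if res_donors.size == 0:
                continue
            d = np.linalg.norm(positions[res_donors] - positions[h], axis=1)
            j = int(np.argmin(d))
            if d[j] <= hydrogen_bond_length:
                system.hydrogen_donor_ref[h] = int(res_donors[j])
    return system


def _pdb_cryst_records(path) -> list:
    """Box lengths (nm) from CRYST1 records of a PDB file, in file order.

    Needed because a multi-model PDB commonly carries a single CRYST1
    header, which frame-wise readers keyed to MODEL blocks skip.
    """
    boxes = []
    try:
        with open(path) as fh:
            for line in fh:
                if line.startswith("CRYST1"):
                    boxes.append(np.array([float(line[6:15]), float(line[15:24]),
                                           float(line[24:33])]) * NM_PER_ANGSTROM)
    except (OSError, UnicodeDecodeError, ValueError):
        return []
    return boxes


def read_system(topology, trajectory=None, role_table: dict | None = None):
    """Read a structure (+ optional trajectory) into package containers.

    ``topology`` may be a PDB (multi-model blocks become frames) or GRO
    file; ``trajectory`` an additional multi-frame PDB/GRO/XTC. Returns
    ``(MolecularSystem, Trajectory)`` with roles assigned from
    ``role_table`` (default table if None). Times missing from the file
    fall back to the frame index in ns.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology), *([str(trajectory)] if trajectory else []))
    n = len(u.atoms)
    names = np.array([a.name for a in u.atoms], dtype=object)
    try:
        elements = np.array([e if e else _guess_element(nm)
                             for e, nm in zip(u.atoms.elements, names)], dtype=object)
    except (mda.exceptions.NoDataError, AttributeError):
        elements = np.array([_guess_element(nm) for nm in names], dtype=object)
    resnames = np.array([a.resname.strip() for a in u.atoms], dtype=object)
    resids = u.atoms.resindices.astype(int)
    tags = np.array([_molecule_tag(rn) for rn in resnames], dtype=object)

    frame_source = str(trajectory) if trajectory else str(topology)
    crysts = _pdb_cryst_records(frame_source) if frame_source.lower().endswith(
        (".pdb", ".ent")) else []
    frames, boxes, times = [], [], []
    warn_ctx = warnings.catch_warnings()
    warn_ctx.__enter__()
    warnings.simplefilter("ignore")
    for k, ts in enumerate(u.trajectory):
        frames.append(u.atoms.positions * NM_PER_ANGSTROM)
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            boxes.append(ts.dimensions[:3] * NM_PER_ANGSTROM)
        elif crysts:
            boxes.append(crysts[k] if k < len(crysts) else crysts[0])
        else:
            raise ValueError(f"frame {k} has no periodic box (CRYST1/box vectors missing)")
        t = getattr(ts, "time", 0.0) / 1000.0  # ps -> ns
        times.append(t)
    warn_ctx.__exit__(None, None, None)
    times = np.asarray(times)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(frames), dtype=float)

    system = MolecularSystem(
        names=names, elements=elements, residue_index=resids,
        residue_name=resnames, molecule_tag=tags,
    )
    traj = Trajectory(np.asarray(frames), np.asarray(boxes), times)
    assign_roles(system, traj.positions[0], role_table)
    return system, traj


def _as_universe(system: MolecularSystem, traj: Trajectory) -> mda.Universe:
    n_res = int(system.residue_index.max()) + 1
    u = mda.Universe.empty(
        system.n_atoms, n_residues=n_res,
        atom_resindex=system.residue_index,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=False,
    )
    u.add_TopologyAttr("names", [str(x) for x in system.names])
    u.add_TopologyAttr("elements", [str(x) for x in system.elements])
    resnames = [""] * n_res
    for i in range(system.n_atoms):
        resnames[int(system.residue_index[i])] = str(system.residue_name[i])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_res + 1))
    coords = traj.positions / NM_PER_ANGSTROM
    dims = np.zeros((traj.n_frames, 6))
    dims[:, :3] = traj.box / NM_PER_ANGSTROM
    dims[:, 3:] = 90.0
    u.load_new(coords.astype(np.float64), format=MemoryReader, dimensions=dims)
    for k, ts in enumerate(u.trajectory):
        ts.time = traj.time[k] * 1000.0  # ns -> ps
    return u


def write_structure(system: MolecularSystem, traj: Trajectory, path,
                    multiframe: bool | None = None) -> None:
    """Write PDB (multi-model for several frames), GRO, or XTC by extension."""
    u = _as_universe(system, traj)
    path = str(path)
    if multiframe is None:
        multiframe = traj.n_frames > 1 and not path.endswith(".gro")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(path, n_atoms=system.n_atoms, multiframe=multiframe) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
                if not multiframe:
                    break
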