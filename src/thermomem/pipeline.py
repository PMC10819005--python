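"""End-to-end pipelines: synthesize -> analyze -> report.

Each runner takes a configuration dict (defaults < config file < explicit
overrides), executes one analysis chain, writes machine-readable artifacts
(JSON report with a provenance block; CSV profiles/series) into the output
directory, and returns the report dict. Stage failures raise
:class:`PipelineError` with a stage-tagged message; outputs carry no
timestamps so identical config + seed reproduce byte-identical reports.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .boltzmann import fit_double_boltzmann, fit_single_boltzmann
from .dsc import Thermogram, characterize_event, subtract_reference
from .spectra import SpectraMatrix, mcr_rank1, restrict_range, smooth_spectra
from .synthetic import (DscGenSpec, SpectraGenSpec, ToySystemSpec,
                        gen_dsc_curve, gen_toy_trajectory, gen_uvvis_series)
from .trajectory import (InteractionParams, area_per_lipid, calpha_pca,
                         deuterium_order_parameters, interaction_series,
                         membrane_thickness, per_residue_interactions)
from .structio import read_system, write_structure


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


DEFAULTS: dict = {
    "seed": 1,
    "out_dir": "results",
    "spectra": {
        "input": None,                 # CSV path; None -> synthesize
        "sg_window": 11,
        "sg_degree": 3,
        "lambda_min": 250.0,
        "lambda_max": 300.0,
        "model": "double",             # single | double
    },
    "dsc": {
        "input": None,
        "reference": None,
        "baseline_anchors": [39.5, 44.5],
        "integration_bounds": None,    # default: the anchors
        "window": None,
        "T_K": 315.0,
    },
    "traj": {
        "structure": None,
        "trajectory": None,
        "contact_cutoff": 0.60,
        "hb_r_cut": 0.35,
        "hb_angle_deg": 30.0,
        "sb_cutoff": 0.40,
        "window_ns": None,             # default: full span
        "n_lipids_per_leaflet": None,  # default: lipid residue count / 2
    },
    # synthetic-input ground truths: the study conditions of the demo
    "simulate": {
        "uvvis": {
            "wavelength_nm": [250.0, 500.0, 1.0],   # start, stop, step
            "temperature_C": [30.0, 52.0, 1.0],
            "transition_temps": [34.0, 41.7],
            "transition_widths": [1.5, 0.5],
            "amplitudes": [0.3, 0.7],
            "direction": "decreasing",
            "noise_sd": 0.0,
        },
        "dsc": {
            "temperature_C": [30.0, 52.0, 0.01],
            "peaks": [
                {"center": 35.4, "width": 1.2, "area": 5.0},
                {"center": 41.9, "width": 0.45, "area": 26.9},
            ],
            "baseline_intercept": 0.5,
            "baseline_slope": 0.01,
            "noise_sd": 0.0,
        },
        "toy": {
            "lipids_per_leaflet": 32,
            "box": [4.0, 4.0, 12.0],
            "headgroup_z_planes": [3.0, 7.8],
            "chain_tilt_deg": 0.0,
            "peptide_residues": ["LYS", "ARG", "SER", "GLY"],
            "planted_contacts": [
                {"residue_index": 0, "partner_group": "phosphate", "distance": 0.30},
                {"residue_index": 1, "partner_group": "phosphate", "distance": 0.32},
            ],
            "n_frames": 10,
        },
    },
}


def deep_update(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = deep_update(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge defaults < YAML/JSON config file < explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            file_cfg = yaml.safe_load(fh) or {}
        if not isinstance(file_cfg, dict):
            raise PipelineError("config", f"config file {path} is not a mapping")
        cfg = deep_update(cfg, file_cfg)
    return deep_update(cfg, overrides)


def _provenance(cfg: dict) -> dict:
    return {
        "package": "thermomem",
        "version": __version__,
        "seed": cfg.get("seed"),
        "config": cfg,
    }


def _write_report(report: dict, out_dir: Path, name: str) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def _grid(start_stop_step) -> np.ndarray:
    start, stop, step = start_stop_step
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


# ---------------------------------------------------------------- simulate

def run_simulate(cfg: dict) -> dict:
    """Write the three synthetic inputs (spectra CSV, DSC CSV, PDB) to disk."""
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg["simulate"]
    seed = int(cfg["seed"])

    uv = sim["uvvis"]
    spectra = gen_uvvis_series(SpectraGenSpec(
        wavelength_grid=_grid(uv["wavelength_nm"]),
        temperature_grid=_grid(uv["temperature_C"]),
        transition_temps=uv["transition_temps"],
        transition_widths=uv["transition_widths"],
        amplitudes=uv["amplitudes"],
        direction=uv["direction"],
        noise_sd=uv["noise_sd"],
        seed=seed,
    ))
    spectra.to_csv(out / "spectra.csv")

    ds = sim["dsc"]
    curve = gen_dsc_curve(DscGenSpec(
        temperature_grid=_grid(ds["temperature_C"]),
        peaks=ds["peaks"],
        baseline_intercept=ds["baseline_intercept"],
        baseline_slope=ds["baseline_slope"],
        noise_sd=ds["noise_sd"],
        seed=seed,
    ))
    curve.to_csv(out / "thermogram.csv")

    toy = dict(sim["toy"])
    system, traj = gen_toy_trajectory(ToySystemSpec(**toy, seed=seed))
    write_structure(system, traj, out / "toy_system.pdb")

    report = {
        "provenance": _provenance(cfg),
        "files": {
            "spectra": "spectra.csv",
            "thermogram": "thermogram.csv",
            "toy_system": "toy_system.pdb",
        },
    }
    _write_report(report, out, "simulate_report.json")
    return report


# ---------------------------------------------------------------- spectra

def run_spectra_pipeline(cfg: dict, spectra: SpectraMatrix | None = None) -> dict:
    """Smooth -> restrict wavelength range -> rank-1 MCR -> Boltzmann fit."""
    p = cfg["spectra"]
    out = Path(cfg["out_dir"])
    if spectra is None:
        if p["input"] is None:
            raise PipelineError("spectra-fit", "no input spectra CSV configured")
        try:
            spectra = SpectraMatrix.from_csv(p["input"])
        except Exception as exc:
            raise PipelineError("spectra-fit", f"cannot read '{p['input']}': {exc}") from exc
    try:
        smoothed = smooth_spectra(spectra, int(p["sg_window"]), int(p["sg_degree"]))
        restricted = restrict_range(smoothed, float(p["lambda_min"]), float(p["lambda_max"]))
        mcr = mcr_rank1(restricted)
    except ValueError as exc:
        raise PipelineError("spectra-fit", str(exc)) from exc
    try:
        if p["model"] == "double":
            fit = fit_double_boltzmann(mcr.concentration)
        elif p["model"] == "single":
            fit = fit_single_boltzmann(mcr.concentration)
        else:
            raise ValueError(f"unknown Boltzmann model '{p['model']}'")
    except ValueError as exc:
        raise PipelineError("boltzmann-fit", str(exc)) from exc

    out.mkdir(parents=True, exist_ok=True)
    mcr.concentration.to_csv(out / "concentration_profile.csv")
    fitted = fit.predict(mcr.concentration.temperatures)
    pd.DataFrame({
        "temperature_C": mcr.concentration.temperatures,
        "value": mcr.concentration.values,
        "fitted": fitted,
    }).to_csv(out / "boltzmann_fit.csv", index=False)

    report = {
        "provenance": _provenance(cfg),
        "stages": {
            "smooth": {"sg_window": p["sg_window"], "sg_degree": p["sg_degree"]},
            "restrict": {"lambda_min": p["lambda_min"], "lambda_max": p["lambda_max"],
                         "n_wavelengths": int(restricted.wavelengths.size)},
            "mcr": {
                "explained_variance_fraction": mcr.explained_variance_fraction,
                "n_iterations": mcr.n_iterations,
                "converged": mcr.converged,
            },
        },
        "fit": fit.to_dict(),
    }
    _write_report(report, out, "spectra_report.json")
    return report


# ---------------------------------------------------------------- DSC

def run_dsc_pipeline(cfg: dict, thermogram: Thermogram | None = None,
                     reference: Thermogram | None = None) -> dict:
    """Reference subtraction -> two-point baseline -> onset/maximum ->
    enthalpy integration -> entropy."""
    p = cfg["dsc"]
    out = Path(cfg["out_dir"])
    if thermogram is None:
        if p["input"] is None:
            raise PipelineError("dsc-fit", "no input thermogram CSV configured")
        try:
            thermogram = Thermogram.from_csv(p["input"])
        except Exception as exc:
            raise PipelineError("dsc-fit", f"cannot read '{p['input']}': {exc}") from exc
    if reference is None and p["reference"] is not None:
        try:
            reference = Thermogram.from_csv(p["reference"])
        except Exception as exc:
            raise PipelineError("dsc-fit", f"cannot read reference '{p['reference']}': {exc}") from exc
    try:
        if reference is not None:
            thermogram = subtract_reference(thermogram, reference)
        event = characterize_event(
            thermogram,
            baseline_anchors=tuple(p["baseline_anchors"]),
            integration_bounds=p["integration_bounds"],
            window=p["window"],
            T_K=p["T_K"],
        )
    except ValueError as exc:
        raise PipelineError("dsc-fit", str(exc)) from exc
    report = {"provenance": _provenance(cfg), "event": event.to_dict()}
    _write_report(report, out, "dsc_report.json")
    return report


# ---------------------------------------------------------------- trajectory

def run_traj_pipeline(cfg: dict, system=None, traj=None) -> dict:
    """All trajectory metrics: interaction series, per-residue table,
    membrane geometry, order parameters, C-alpha PCA."""
    p = cfg["traj"]
    out = Path(cfg["out_dir"])
    if system is None or traj is None:
        if p["structure"] is None:
            raise PipelineError("traj-metrics", "no input structure configured")
        try:
            system, traj = read_system(p["structure"], p["trajectory"])
        except Exception as exc:
            raise PipelineError("traj-metrics", f"cannot read structure: {exc}") from exc
    params = InteractionParams(
        contact_cutoff=float(p["contact_cutoff"]),
        hb_r_cut=float(p["hb_r_cut"]),
        hb_angle_cut_deg=float(p["hb_angle_deg"]),
        sb_cutoff=float(p["sb_cutoff"]),
    )
    try:
        series = interaction_series(system, traj, params=params)
        span = float(traj.time[-1] - traj.time[0])
        window = float(p["window_ns"]) if p["window_ns"] is not None else span
        table = per_residue_interactions(system, traj, window, params=params)
        n_leaflet = p["n_lipids_per_leaflet"]
        if n_leaflet is None:
            lipid_res = np.unique(system.residue_index[system.molecule_tag == "lipid"])
            n_leaflet = max(lipid_res.size // 2, 1)
        apl = [area_per_lipid(traj.box[f], int(n_leaflet)) for f in range(traj.n_frames)]
        p_sel = system.select(flag="is_phosphorus")
        thickness = [membrane_thickness(traj.positions[f], p_sel)
                     for f in range(traj.n_frames)]
        scd = deuterium_order_parameters(system, traj)
        ca_sel = system.select(flag="is_calpha")
        pca = calpha_pca(traj, ca_sel) if traj.n_frames >= 2 and ca_sel.size else None
    except ValueError as exc:
        raise PipelineError("traj-metrics", str(exc)) from exc

    out.mkdir(parents=True, exist_ok=True)
    series.to_frame().to_csv(out / "interaction_series.csv", index=False)
    table.to_csv(out / "per_residue_interactions.csv", index=False)
    report = {
        "provenance": _provenance(cfg),
        "interaction_series_mean": {
            "min_distance_nm": float(series.min_distance.mean()),
            "n_contacts": float(series.n_contacts.mean()),
            "n_hbonds": float(series.n_hbonds.mean()),
            "n_salt_bridges": float(series.n_salt_bridges.mean()),
        },
        "membrane": {
            "area_per_lipid_nm2": float(np.mean(apl)),
            "thickness_nm": float(np.mean(thickness)),
            "n_lipids_per_leaflet": int(n_leaflet),
        },
        "order_parameters": {
            chain: {int(pos): float(v)
                    for pos, v in zip(prof.carbon_positions, prof.s_cd)}
            for chain, prof in scd.items()
        },
        "per_residue_top": table.head(10).to_dict(orient="records"),
        "pca_eigenvalues_nm2": (pca.eigenvalues.tolist() if pca is not None else None),
        "window_ns": window,
    }
    _write_report(report, out, "traj_report.json")
    return report


# ---------------------------------------------------------------- demo

def run_full_demo(cfg: dict) -> dict:
    """Full synthetic round trip: simulate, then run all three analyses."""
    out = Path(cfg["out_dir"])
    run_simulate(cfg)
    cfg_spec = deep_update(cfg, {"spectra": {"input": str(out / "spectra.csv")}})
    spectra_report = run_spectra_pipeline(cfg_spec)
    cfg_dsc = deep_update(cfg, {"dsc": {"input": str(out / "thermogram.csv")}})
    dsc_report = run_dsc_pipeline(cfg_dsc)
    cfg_traj = deep_update(cfg, {"traj": {"structure": str(out / "toy_system.pdb")}})
    traj_report = run_traj_pipeline(cfg_traj)
    summary = {
        "provenance": _provenance(cfg),
        "spectra": {k: spectra_report[k] for k in ("stages", "fit")},
        "dsc": dsc_report["event"],
        "traj": {k: traj_report[k] for k in
                 ("interaction_series_mean", "membrane", "order_parameters")},
    }
    _write_report(summary, out, "demo_summary.json")
    return summary
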