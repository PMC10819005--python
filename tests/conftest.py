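import numpy as np
import pytest

from thermomem import SpectraGenSpec, ToySystemSpec, gen_toy_trajectory, gen_uvvis_series

# DPPC-like double-transition study conditions: pretransition at 34.0 degC,
# main transition at 41.7 degC, turbidity decreasing with temperature.
DPPC_T0 = (34.0, 41.7)
DPPC_WIDTHS = (1.5, 0.5)
DPPC_AMPLITUDES = (0.3, 0.7)


@pytest.fixture
def wavelengths():
    return np.arange(250.0, 501.0, 1.0)


@pytest.fixture
def temperatures():
    return np.arange(30.0, 53.0, 1.0)  # 23 points spanning 30-52 degC


@pytest.fixture
def dppc_spectra(wavelengths, temperatures):
    """Noise-free rank-1 turbidity matrix with the double-transition truth."""
    spec = SpectraGenSpec(wavelengths, temperatures, DPPC_T0, DPPC_WIDTHS,
                          DPPC_AMPLITUDES, direction="decreasing", noise_sd=0.0,
                          seed=0)
    return spec, gen_uvvis_series(spec)


@pytest.fixture
def planted_toy():
    """Small bilayer + peptide with one planted H-bond/salt-bridge contact
    (LYS to phosphate, 0.30 nm) and one planted choline contact (ARG, 0.35 nm)."""
    spec = ToySystemSpec(
        lipids_per_leaflet=9,
        box=(4.0, 4.0, 12.0),
        headgroup_z_planes=(3.0, 7.8),
        peptide_residues=("LYS", "ARG", "SER", "GLY"),
        planted_contacts=(
            {"residue_index": 0, "partner_group": "phosphate", "distance": 0.30},
            {"residue_index": 1, "partner_group": "choline", "distance": 0.35},
        ),
        n_frames=4,
        seed=11,
    )
    system, traj = gen_toy_trajectory(spec)
    return spec, system, traj
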