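# thermomem

Analysis toolkit for characterizing how a peripheral protein — the model
case is myelin basic protein (MBP), an intrinsically disordered, highly
cationic protein — adsorbs on a zwitterionic phosphatidylcholine (DPPC)
bilayer across its gel-to-fluid phase transition. It bundles the three
computational chains such a study needs, each exercisable end to end on
synthetic data with known ground truth:

1. **Temperature-dependent UV-Vis turbidity.** A stack of spectra recorded
   over temperature forms a matrix `D` (wavelength × temperature) obeying
   the bilinear model `D = C Sᵀ + E`. Projecting onto one component
   (rank-1 multivariate curve resolution) yields a single concentration
   profile `c(T)` — a melting curve — which is fitted with a single or
   double Boltzmann sigmoid

   `y(T) = A₂ + (A₁ − A₂) / (1 + exp((T − T₀)/dT))`

   whose inflection point `T₀` is the transition temperature. A DPPC
   bilayer shows two: the pretransition `T_p` and the main chain-melting
   transition `T_m`.

2. **Differential scanning calorimetry.** Reference subtraction, manual
   two-point baseline, onset (tangent at the steepest ascending point) and
   curve maximum, calorimetric enthalpy by integrating the excess molar
   heat capacity, and the entropy change `ΔS = ΔH_cal / T` (T in kelvin,
   conventionally the main-transition maximum).

3. **Trajectory interaction metrics.** From labelled coordinate
   trajectories in orthorhombic periodic boxes: minimum distances,
   contacts, geometric hydrogen bonds, salt bridges (charged N···O pairs
   between Lys/Arg groups and lipid phosphates), per-residue interaction
   tables, area per lipid, bilayer thickness from phosphorus planes,
   deuterium order parameters `S_CD = ⟨(3cos²θ − 1)/2⟩`, and
   essential-dynamics PCA of Cα coordinates.

A synthetic-data module generates rank-1 turbidity matrices, Gaussian-peak
thermograms, and coarse bilayer+peptide trajectories with planted
interactions, so every stage can be validated against exact ground truth.

## Worked example

Run the bundled synthetic round trip (generate inputs, analyze them,
write reports):

```sh
thermomem full-demo --seed 1 --out demo
```

`demo/demo_summary.json` then contains (abridged):

```json
{
  "spectra": {"fit": {"inflection_temps_C": [34.0, 41.7], "r_squared": 1.0}},
  "dsc": {"T_onset_C": 41.000, "T_max_C": 41.900,
          "delta_H_cal_kJ_per_mol": 26.889, "delta_S_J_per_K_mol": 85.363},
  "traj": {"membrane": {"area_per_lipid_nm2": 0.5, "thickness_nm": 4.8},
           "interaction_series_mean": {"n_hbonds": 2.0, "n_salt_bridges": 2.0}}
}
```

Reading: the spectra chain recovered both planted transition temperatures
(pretransition 34.0 °C, main transition 41.7 °C) exactly from the
synthesized turbidity matrix; the DSC chain integrated the planted
26.9 kJ mol⁻¹ main-transition peak to 0.04% and converted it at 315 K to
85.4 J K⁻¹ mol⁻¹; and the toy bilayer's gel-phase geometry (0.5 nm² per
lipid, 4.8 nm thick) and the two planted protein–phosphate contacts were
read back exactly. Library use without the CLI is a few lines:

```python
import numpy as np
from thermomem import (SpectraGenSpec, gen_uvvis_series, smooth_spectra,
                       restrict_range, mcr_rank1, fit_double_boltzmann)

spec = SpectraGenSpec(np.arange(250., 501.), np.arange(30., 53.),
                      transition_temps=[34.0, 41.7],
                      transition_widths=[1.5, 0.5], amplitudes=[0.3, 0.7])
m = gen_uvvis_series(spec)
profile = mcr_rank1(restrict_range(smooth_spectra(m), 250, 300)).concentration
print(fit_double_boltzmann(profile).inflection_temps)   # (34.0, 41.7)
```

## Documentation

`docs/methods.md` describes the models, conventions, numerical choices and
known limitations in detail.
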