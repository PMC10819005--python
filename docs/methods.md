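# Methods

This note documents the models implemented in `thermomem`, the conventions
and numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the package's known limitations. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Rank-1 curve resolution of temperature-dependent spectra

**Model.** A temperature series of turbidity spectra is stored as a matrix
`D` (n_wavelengths × n_temperatures). For a system whose
temperature-dependent variability is carried by one effective species, `D`
follows the bilinear model `D = c sᵀ + E` with a concentration profile `c`
over temperature, a spectral profile `s` over wavelength, and residual `E`.
The model has no offset term, so explained variance is computed on the raw
(uncentered) matrix: `EV = 1 − ‖E‖²_F / ‖D‖²_F`.

**Algorithm.** `mcr_rank1` runs unconstrained rank-1 alternating least
squares: with `s` fixed the optimal `c` is `Dᵀs/‖s‖²` and vice versa, so
the iteration is a power method on `DᵀD` and converges to the leading
singular pair — the global least-squares optimum, unique up to sign and
scale. Convergence is declared when the normalized concentration direction
moves by less than 1e-13 (max 1000 iterations; the iteration count and a
convergence flag are reported). The start vector is the column-norm
vector, which is deterministic and has positive overlap with the leading
right singular vector for any data with a dominant component. Sign/scale
convention: the spectral profile has unit Euclidean norm and non-negative
entry sum; all magnitude lives in the concentration profile. The test
suite cross-checks the factorization against a full SVD, which is kept as
an independent oracle rather than the implementation.

No non-negativity, closure or unimodality constraints are applied: for a
single component the unconstrained optimum is unique, and constraints
would only matter for multi-component resolution, which is out of scope.

**Conditioning.** Spectra are smoothed along the wavelength axis with a
Savitzky–Golay filter (default 3rd-degree polynomial, 11-point window)
before resolution, and restricted to the wavelength band where turbidity
is most temperature-sensitive (default 250–300 nm; both configurable).
An 11-point window is used as the nearest valid (odd) reading of a
10-point smoothing convention: a Savitzky–Golay window must be symmetric
about the smoothed point. Endpoints are re-fit on asymmetric windows
clipped to the available points, so polynomials up to the filter degree
are reproduced exactly everywhere, not just in the interior.

## 2. Boltzmann transition fits

**Functional forms.** Melting curves are fitted with the standard
(Origin-style) Boltzmann sigmoid; its inflection point is exactly `T0`,
which is what is reported as the transition temperature. The double model
shares one amplitude span `A1 − A2` split by a mixing fraction
`f ∈ (0, 1)`:

    y(T) = A2 + (A1 − A2) [ f σ₁(T) + (1 − f) σ₂(T) ],
    σᵢ(T) = 1 / (1 + exp((T − T0ᵢ)/dTᵢ))

This parameterization is algebraically interconvertible with two
independent amplitudes but has a smaller non-identifiability surface.

**Optimization.** Bounded nonlinear least squares (trust-region
reflective, tolerances 1e-15) from three deterministic starts: (i) a
data-driven guess — baselines from the first/last 10% means, inflection
candidates from extrema of the Savitzky–Golay-smoothed numerical
derivative, widths from the derivative peak's half-maximum extent divided
by 3.525 (the derivative FWHM of a Boltzmann sigmoid in units of `dT`);
(ii) range midpoint / quartile positions; (iii) the derivative centroid
with narrower widths. The lowest residual wins; ties break toward smaller
total width. `T0` bounds extend one grid span beyond the data so
transitions at the edge remain representable; widths are bounded in
`[1e-4, 10] × span`.

**Diagnostics.** `R² = 1 − SS_res/SS_tot`; parameter covariance from the
Jacobian at the optimum, `σ² (JᵀJ)⁻¹` with `σ² = SS_res/(n − p)` (pinv if
ill-conditioned). Double-fit inflection points are reported sorted
ascending (covariance permuted consistently, `f → 1 − f`). If the two
optima are closer than the larger width the fit is flagged
`"unresolved transitions"`; constant profiles are rejected rather than
fitted; optimizer non-convergence sets `converged = False` with the
solver's message instead of fabricating values.

## 3. DSC thermodynamics

Thermograms are excess **molar** heat capacity (kJ mol⁻¹ K⁻¹) on a
strictly increasing temperature grid (°C); conversion from instrument raw
power is out of scope. The chain is:

* **Reference subtraction** — the solvent scan is linearly interpolated
  onto the sample grid and subtracted over the temperature overlap.
* **Two-point baseline** — the straight line through the curve values at
  two anchor temperatures is removed; the result is exactly zero at the
  anchors, and any linear input is annihilated to machine precision.
* **Curve maximum** — grid argmax refined by a parabola through the top
  three points (sub-grid accuracy). Plateaus return their leftmost point
  flagged `"plateau"`; a maximum at the window edge is flagged
  `"no interior maximum"`.
* **Onset** — tangent at the steepest ascending point (numerical gradient)
  extrapolated to the zero baseline; the calorimetry-standard
  construction. For a Gaussian peak (center μ, width σ) the steepest point
  is μ − σ and the onset analytically μ − 2σ, which the tests use as a
  closed form. The construction is scale-free: amplitude scaling leaves
  the onset unchanged.
* **Enthalpy** — trapezoidal integration on the native grid (no
  re-gridding, to avoid fabricating resolution); bounds falling between
  grid points contribute interpolated nodes. °C differences equal K
  differences, so the result is directly kJ mol⁻¹.
* **Entropy** — `ΔS = 1000 · ΔH_cal / T_K` (J K⁻¹ mol⁻¹). `T_K` is
  caller-supplied; the pipeline default is 315 K (the main-transition
  maximum of DPPC in kelvin, the field's conventional choice), and the
  event's own maximum is used when no temperature is given.

## 4. Trajectory metrics

Units are nm and ns; boxes are orthorhombic and all pair distances use the
minimum-image convention (triclinic cells are out of scope). Atom
semantics are carried by explicit role arrays on `MolecularSystem` —
hydrogen-bond donor/acceptor flags, hydrogen→donor references, charged
group ids, phosphorus/choline/chain-carbon/Cα markers — assigned either by
the synthetic generator or, for files, from an editable
residue-name/atom-name lookup table (coordinate formats carry no such
semantics).

Interaction criteria, all exposed as parameters, follow the long-standing
defaults of the MD analysis ecosystem since the underlying experiments
define none:

* contact: heavy-atom pair within **0.60 nm**;
* hydrogen bond: donor–acceptor ≤ **0.35 nm** and hydrogen–donor–acceptor
  angle ≤ **30°**;
* salt bridge: charged heavy atoms (Lys/Arg N vs phosphate O/P) of two
  formally charged groups within **0.40 nm**, counted once per group pair
  per frame.

Headgroup partitioning of contacts (phosphate vs choline) is obtained by
running the contact counter against the phosphorus/choline selections; no
separate operation exists. Per-residue tables average H-bond and contact
counts over the trailing time window (frames with `t > t_end − W`) and are
sorted by average H-bonds descending, with 1-based residue labels like
`129ARG`. Membrane thickness is the distance between mean phosphorus z of
the two leaflets, split at the mean phosphorus z per frame (no flip-flop
tracking). Area per lipid is the lateral box area over lipids per leaflet.

**Order parameters.** With no explicit hydrogens, the local chain axis at
carbon *i* is the C(i−1)→C(i+1) vector; C–H bonds lie perpendicular to
it, giving `S_CD = −S_axis/2` where `S_axis = ⟨(3cos²θ − 1)/2⟩` against
the bilayer normal. Closed forms used in validation: chains exactly along
z give −0.5; isotropic axes give 0. Terminal carbons have no axis and are
absent from the profile.

**PCA.** Each frame's Cα set is translationally and rotationally (Kabsch,
reflection-corrected) fitted onto the first frame's, then the 3N×3N
positional covariance (population normalisation, divide by n_frames) is
eigen-decomposed; eigenvalues are reported descending with per-frame
projections. Whether to fit to the first frame or an iterated mean
structure, and whether to mass-weight, are genuinely open conventions;
first-frame fitting without mass weighting was chosen for determinism and
because the toy systems carry no masses.

## 5. Synthetic data: what it does and does not emulate

* `gen_uvvis_series` builds `D` as an exact rank-1 outer product of a
  smooth positive spectral profile — default shape λ⁻⁴, the Rayleigh-like
  wavelength dependence of particle turbidity, normalized to unit norm —
  and a single/double Boltzmann concentration profile with a constant
  positive baseline (default 10% of the total amplitude), plus i.i.d.
  Gaussian noise. Transitions closer than the larger width are rejected as
  ill-posed ground truth. It does **not** emulate instrument drift,
  wavelength-correlated noise, or multi-component mixtures, so passing
  tests show correct recovery under the bilinear model, not robustness to
  model violations.
* `gen_dsc_curve` superposes symmetric Gaussian peaks of exactly specified
  area on a linear baseline. Real lipid transitions are asymmetric and
  sharper than Gaussian; symmetric peaks are used because ground-truth
  area and onset then have closed forms. A peak extending beyond the grid
  by more than 4 widths triggers a warning (its area is not fully
  representable on the grid).
* `gen_toy_trajectory` builds a coarse bilayer slab (per lipid: one
  phosphorus exactly on the headgroup plane, two phosphate oxygens, one
  choline nitrogen, two straight 8+-carbon acyl chains at the requested
  tilt) and a coarse peptide (Cα plus at most one side-chain heavy atom
  and its hydrogen per residue). Planted contacts place a residue's key
  atom at an exact distance above the nearest atom of the requested lipid
  group, with the donor hydrogen collinear toward it, so a planted 0.30 nm
  phosphate contact is simultaneously a textbook hydrogen bond and salt
  bridge in every frame. Membrane geometry (plane z, tilt, planted group
  distances) is recoverable exactly. No force-field realism, dynamics,
  flip-flops or conformational sampling are intended: frames are static
  except optional seeded jitter on non-planted peptide atoms.

All generators draw every random number from one explicit integer seed per
call and are bit-reproducible; there is no global random state.

**Demo study conditions.** The bundled demo plants the DPPC reference
values as generator truth: turbidity transitions at 34.0 and 41.7 °C
(widths 1.5/0.5 °C, amplitude split 0.3/0.7, decreasing with temperature,
30–52 °C scan, 250–500 nm range), a DSC main transition of 26.9 kJ mol⁻¹
at 41.9 °C (σ = 0.45 °C) plus a 5.0 kJ mol⁻¹ pretransition at 35.4 °C
(σ = 1.2 °C; a literature-typical pretransition enthalpy, since no
reference value is printed for it), baseline anchors at 39.5/44.5 °C
(≥ 3.8 pretransition widths from the pretransition center, ≥ 5σ from the
main peak), entropy at 315 K, and a gel-like bilayer of 32 lipids per
leaflet in a 4×4 nm lateral box (0.5 nm² per lipid) with phosphorus
planes 4.8 nm apart.

## 6. Problem sizes and determinism

The validation suite and the acceptance script run on deliberately small
problems — 251×23 spectra matrices, 2201-point thermograms, toy systems of
a few hundred atoms (200-lipid leaflets only where the geometry metrics
need them), 200 noisy spectra replicates, 10⁵ Monte-Carlo axes — sizes at
which every detector can also be checked against exhaustive brute-force
enumeration and each chain completes in seconds. Identical configuration
and seed reproduce byte-identical reports; reports carry a provenance
block (package version, seed, full config echo) and no timestamps.

## 7. Known limitations

* One-component resolution only; rotational-ambiguity handling and
  constrained multi-component ALS are not implemented.
* The Boltzmann uncertainty estimates are Jacobian-based asymptotic
  standard errors; no profile likelihood or bootstrap.
* DSC: no multi-scan averaging, scan-rate correction, or van't Hoff /
  cooperative-unit analysis.
* Trajectories: orthorhombic boxes only; no DSSP, energetics, density
  profiles, or free-energy analysis; interaction counts depend on the
  (configurable) geometric criteria, so absolute counts from production
  simulations with other conventions are not directly comparable.
* File I/O relies on MDAnalysis; multi-model PDB files that carry a single
  header CRYST1 record are handled by a fallback parse of the header.
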