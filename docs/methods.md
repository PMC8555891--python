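# Methods

## Scope and modelling assumptions

The package models the early-time (< 1 ms electromagnetic/thermal,
< 1 ms acoustic) response of the head to a single high-peak-power
microwave pulse. The chain is strictly one-way coupled: EM fields set a
heating rate, heating sets a thermoelastic source, and the mechanical
response is read out against injury thresholds. Feedback (temperature-
dependent dielectrics, perfusion, thermoregulation), multi-pulse trains
and electroporation are out of scope.

Everything is deterministic. There is no random number generator anywhere
in the pipeline; re-running a scenario reproduces byte-identical summary
artifacts.

## Head phantom and tissue constants

The phantom is a layered sphere or ellipsoid: shells labelled outside-in
skin (3 mm), skull (7 mm), CSF (3 mm), a 10 mm gray-matter cortex and a
white-matter core, with an optional CSF-labelled ellipsoidal ventricle
inclusion (10 × 20 × 10 mm semi-axes) at the centre. The ellipsoid
narrows left–right by 15% relative to the anterior–posterior semi-axis.
The anterior–posterior head length defaults to 0.17 m; the idealised
brain-only sphere used in the auditory-frequency analysis is 0.15 m
across (head length minus skull and CSF shells).

Tissue constants live in one table (`phantom.py`). Dielectric values are
literature-typical (Gabriel-style) pairs (ε_r, σ) tabulated at 0.4, 0.9,
1.0, 1.8, 2.45 and 3.0 GHz and interpolated in log-frequency; no
dispersion model is fitted because each scenario is a single carrier.
Acoustic and thermal constants are frequency independent: brain bulk wave
speed 1450 m/s (water-like), CSF 1480 m/s, bulk moduli K = ρc²; brain
c_p = 3600 J kg⁻¹ K⁻¹; soft-tissue volumetric thermal expansion
β = 3α ≈ 3.6 × 10⁻⁴ /°C (water near body temperature); bone expansion
0.27 × 10⁻⁴ /°C linear, and zero in the mechanics (bone heats weakly and
its expansion is neglected there).

Probes sit on the midline at 25% (frontal), 50% (periventricular) and 75%
(occipital) of the brain's anterior–posterior extent, snapped to the
nearest brain voxel.

## FDTD dosimetry

Standard Yee staggering with material coefficients sampled per voxel
node (staircase surfaces). The time step is 0.9× the 3D CFL bound,
rounded so that one source period is an integer number of steps.
Boundaries are 10-cell convolutional PML (cubic conductivity grading,
σ_max = 0.8(m+1)/(η₀Δx), small linearly graded α for late-time
stability).

The plane wave enters through a total-field/scattered-field box. The
incident field is evaluated analytically on the grid's own 1D numerical
dispersion relation, sin(ωΔt/2) = (c₀Δt/Δx)·sin(kΔx/2), with the matched
discrete magnetic amplitude; in steady state this satisfies the discrete
vacuum equations exactly, so TF/SF cancellation is exact to round-off
(measured vacuum leakage ~10⁻⁵ of the incident RMS). The source is
ramped over 3 cycles; the start-up transient radiates into the PML.

Runs proceed whole cycles, accumulating the per-node mean square of all
three E components; the solver declares steady state when the
domain-mean RMS changes by < 0.5% between consecutive cycles (minimum 20
cycles) and errors out if the cycle budget is exhausted. A resolution
guard refuses grids coarser than a tenth of the shortest in-tissue
wavelength. Propagation along ±x/±y with vertical (z) polarisation is
reduced to the +y code path by transposing/flipping the label volume.

SAR = σE_rms²/ρ per voxel (exactly zero where σ = 0). SAR* = SAR/P_IN
with P_IN the incident power density (E₀²/2η₀, converted at
10 W/m² per mW/cm²); SAR* is invariant to the source amplitude. The
10-g average grows a cube centred on each voxel one voxel per side at a
time until the enclosed in-body tissue mass reaches 10 g (air voxels
count toward neither mass nor average; cubes clip at the array bounds),
averages SAR* over the cube's in-body voxels, and reports the group
maximum. A brute-force search fixes these semantics in the tests.

Validation: an embedded Mie-series oracle (Bohren–Huffman internal and
scattered expansions with complex permittivity ε_r + iσ/ωε₀, truncation
at the Wiscombe order and at least ka + 10, tail checked to 10⁻⁸).
Against it the solver achieves ~2.7% interior RMS error on a 5 cm,
ε_r = 50, σ = 1.4 S/m sphere at 1 GHz and 2 mm cells (10% required,
error decreasing under refinement).

## Pulse heating

ΔT = P_IN · SAR* · τ_d / c_p per voxel, valid while the thermal diffusion
length √(4Dτ_d) (D = 2 × 10⁻⁷ m²/s for brain) is small against the
heated features; the code warns at τ_d ≥ 1 ms. The temperature ramps
linearly to ΔT at t = τ_d and is then held constant — conduction is far
too slow to matter on acoustic time scales. Only white matter, gray
matter and CSF expand in the mechanics.

## Thermoelastic solvers

Both solvers integrate the linear acoustic system
∂p/∂t = −K∇·v + Kβ ∂T/∂t, ρ∂v/∂t = −∇p with staggered leapfrog at
0.9× CFL. Brain, CSF and ventricles are treated as fluids: the shear
modulus of brain tissue is ~5 orders of magnitude below its bulk
modulus, so the pressure response dominates; principal strain is
reported from the integrated velocity field (displacement) gradients.
At the strains involved (≲10⁻⁵) logarithmic and small strain coincide.

**Spherical (1D)**: pressure at shell centres, radial velocity at faces,
v(0) = 0 regularity, outer boundary either pressure-release (ghost
p = −p_N, free surface) or rigid. Under instantaneous uniform heating
with a rigid wall it reproduces the inertial-confinement pressure
p = KβΔT to machine precision; with a free surface its dominant
eigenfrequency matches the analytic radial mode c/2a to < 2% at 128
shells; for slow ramps the residual stress decays as ~1/(ω₁τ_d)
(measured 5.2%, 1.9%, 1.0% of KβΔT at τ_d/τ_c = 20, 50, 100), so the
equilibrium-limit check uses τ_d = 50τ_c.

**Cartesian (3D)**: heterogeneous ρ, K, β on the (optionally coarsened,
nearest-neighbour resampled) phantom grid. The skull is rigid by default
(zero normal velocity at fluid–non-fluid faces) — a deliberate
overestimate of confinement; a stiff-fluid skull with a free outer
surface is selectable. The solver accumulates the per-voxel minimum
pressure online and tracks the global maximum principal strain and
strain rate (closed-form symmetric 3×3 eigenvalues, evaluated every few
steps), so no 4D history is stored. It warns when the acoustic impedance
contrast exceeds 100.

The tensile "arrival" at a probe is defined as the first time the
pressure falls below half its global minimum: under strong confinement,
late reverberation extrema can exceed the first-pass focus, and the
arrival metric tracks the converging front the way the per-region
timing of the focused tensile wave is usually read.

## Auditory-frequency analysis

Spectra are rectangular-window FFTs with 4× zero padding; the dominant
peak is the largest interior local maximum above 1 kHz, refined by
parabolic interpolation across the peak bin. For the brain-sized free
sphere the heating profile decays from the irradiated surface with the
tissue's plane-wave power penetration depth at the carrier (~2 cm at
1 GHz, computed from the dielectric table). Probes mirror the phantom's
anatomical probes (half-radius, centre, half-radius), and the reported
dominant frequency is the median over probes: the exact centre of an
ideal sphere is a degenerate focus where all harmonics arrive
coherently, and the median is robust to that single pathological probe.
The result, 9.67 kHz for the 0.15 m brain sphere, equals the analytic
fundamental c/2a and sits in the 7–10 kHz band expected for
microwave-evoked cochlear response in humans.

On directional effects: in the idealised ellipsoid the frontal and
occipital midline probes lock onto whichever sloshing mode the load
direction excites, so their dominant peaks are not direction invariant
at desk scale; the deep periventricular probe's dominant frequency is
(same pitch, direction-dependent loudness). Full three-probe invariance
requires the mode mixing of realistic anatomy.

## Injury thresholds and exposure arithmetic

Thresholds are centralised in `INJURY_THRESHOLDS`: cavitation band
−100…−150 kPa (flag at the conservative −100 kPa edge), axonal strain
18% (3–6% quoted for high rates), football-impact tensile band
20–120 kPa. Exposure utilities implement the far-field link budget
S = P·10^(G/10)/4πR², single-pulse energy P_IN·τ_d, and the IEEE ERL
f_MHz/200 W/m² (400 MHz–2 GHz) with its 30-minute energy budget.

Power sweeps exploit linearity: one full run is scaled across the
requested power densities and one independent re-run verifies
proportionality to 1%.

## Problem sizes and numerical defaults

Default desk-scale resolutions: 2 mm EM grid on the head-only domain,
2.5 mm wave grid, 256 shells in the spherical solver, 10-cell PML,
≥ 20 FDTD cycles, wave probe sampling at the solver step (< 1 µs). The
test suite uses smaller analogues (a 0.10 m spherical head at 3 mm for
end-to-end runs, a 5 cm sphere for the Mie validation) chosen so the
whole chain remains exercised end to end at interactive turnaround.

## What the synthetic phantom does and does not show

The generator emulates layered gross anatomy, realistic tissue contrast
and head dimensions, so geometry-driven conclusions — transit-time
scaling, pulse-duration dependence of focusing, direction-invariance of
the dominant frequency, linearity in incident power — transfer to
realistic heads. It does not contain gyri, vasculature, brainstem
anatomy, sinuses or realistic ventricle shape, and the rigid-skull
default overstates confinement; absolute pressure magnitudes and exact
focus locations in a segmented MRI head can differ substantially, so
such magnitudes are treated as trends here, not predictions.

## Known limitations

- Staircased tissue interfaces (no conformal FDTD); single-frequency
  dielectrics.
- Fluid-only mechanics: no shear wave propagation, no skull flexure;
  tied-contact elastic skulls are not modelled.
- Strain is reported from center-averaged displacement gradients on a
  coarse grid; it is a global-extremum tracker, not a per-voxel injury
  map.
- The 10-g average uses cubical kernels only (one of the shapes the
  IEEE guideline admits).
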