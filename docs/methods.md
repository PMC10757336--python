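# Methods

`stimtwin` is a desk-scale digital twin of a perfusion bioreactor with
capacitively-coupled (CCoupled) electrical stimulation for bone tissue
engineering. It predicts the physical microenvironment — fluid-induced wall
shear stress and electric-field magnitude — that a candidate
scaffold/holder/protocol combination delivers to the cultured volume, and
automates the design decision loop that picks the combination whose dose
lands inside published osteoinductive windows. This note records the models,
their assumptions, the numerical choices, and what the package's synthetic
inputs do and do not represent.

## Geometry model

All inputs are generated parametrically; there are no external datasets.

* **Orthogonal ("woodpile") scaffold.** 10.0 × 10.0 × 2.75 mm envelope of
  alternating layers of parallel cylinders (500 µm filament diameter,
  500 µm pore, layers rotated 90° and interpenetrating by 10 % of the
  filament diameter, i.e. a 450 µm vertical pitch). The printed part's
  0.02 mm intersection fillets are below any practical voxel size and are
  omitted — a known geometric simplification.
* **Honeycomb scaffold.** 10.2 × 10.2 × 3.0 mm envelope of prismatic walls
  (250 µm truss) around hexagonal channels (300 µm across flats), channels
  along the envelope's local z axis. Electrical properties default to the
  scaffold polymer (PCL) because the property table provides none for the
  ceramic variant; the material is a parameter of `ScaffoldSpec`.
* **Holders.** The printed holders are replaced by *simplified parametric*
  solids that keep only the functional differences: the **horizontal**
  holder supports the scaffold lying flat over a suction plenum drained by
  two lateral collector channels that merge into a single exit pipe; the
  **vertical** holder supports it upright over an intake slot and a single
  bottom outlet channel. Exit-pipe cross sections are identical
  (1.32 × 1.32 mm — chosen so that one quarter of the maximum pump rate
  gives the connector mean velocity of 0.120 m/s; the true connector area
  is not published and is an explicit calibration parameter). Blueprint
  geometry is out of scope.
* **Chamber.** Medium cylinder of radius 20 mm and height 30 mm; z is the
  chamber (gravity) axis; the region outside the cylinder is the
  pressure-reference "open" boundary of the flow model; the floor is a
  printed plate pierced by the exit pipe.
* **Electrodes.** 33 × 18 mm ITO-on-PET plates facing each other along x,
  22 mm apart, PET film (175 µm) toward the medium. Electric solves use the
  paired layout of the device — each electrode pair spans **two**
  side-by-side scaffold+holder units — because with a single centered unit
  an unrealistically large share of the current bypasses the scaffold
  through open medium.

Geometry is *implicit*: scenes are ordered lists of vectorized
point-membership predicates, rasterized onto an isotropic voxel grid at any
requested resolution (cell-center sampling by default; optional k³
supersampling with majority vote). This makes the two-level solves below
exact re-voxelizations rather than image resampling. Coarse grids sample
strut lattices with supersampling (center sampling can miss 500 µm struts
entirely at 500 µm cells) but prismatic honeycombs with center sampling
(majority voting seals their channels, which must stay connected for flow).

## Flow model

Steady incompressible **Stokes** flow,

    -µ ∇²u + ∇p = 0,   ∇·u = 0,

with µ = 6.89 × 10⁻⁴ Pa·s and ρ = 994 kg/m³ for the culture medium at
37 °C. (The property table labels the 6.89 × 10⁻⁴ Pa·s entry "kinematic
viscosity", but the units are those of dynamic viscosity and the value is
water-like dynamic viscosity at 37 °C; it is treated as µ.) Inertia is
dropped deliberately: the chamber operates at Re ≪ 1, and the linearity of
Stokes flow is used throughout (protocol rescaling without re-solving). A
per-run Reynolds diagnostic `reynolds()` verifies applicability; the
characteristic length behind the published laminar-limit statement is not
defined there, so Re is a configurable diagnostic, not a validated output.

Discretization: staggered MAC finite differences on the voxel grid. Solid
cells are removed from the unknown set; no-slip is imposed at face level for
normal components and by ghost reflection for tangential components (wall on
the fluid–solid cell interface). Boundary conditions: gauge-pressure
"do-nothing" openings (the standard-atmosphere chamber inlet maps to gauge
0), imposed mean normal velocity on the outlet patch, optional symmetry
sides for benchmarks. Fluid pockets with no path to any driven boundary are
frozen as solids (they make the saddle system singular and are artifacts of
coarse lattice voxelization).

The symmetric saddle system is solved by MINRES with a block-diagonal
preconditioner: FFT (DCT-II) solves of the uniform velocity Laplacian for
mostly-open geometries, Jacobi scaling for strongly perforated thin-channel
grids (the solver tries the alternative automatically if the first choice
stagnates), and the scaled pressure mass matrix µI for the Schur block.
MINRES stops in its preconditioned norm; on heterogeneous chamber grids the
true relative residual floors a few decades above the 10⁻⁶ solve tolerance
while divergence and momentum balance are physically converged (discrete
divergence ≲ 10⁻⁴ relative), so the hard failure gate is 2 × 10³ × tol.
Benchmark-grade grids converge to ~10⁻⁸ and the tight continuity invariants
are asserted there.

Derived fields: shear rate γ̇ = √(2 D:D) from the symmetric velocity
gradient (Newtonian fluid, τ = µγ̇). Wall-adjacent cells use the one-sided
quadratic stencil through the wall point, which recovers the *wall* velocity
gradient exactly for parabolic profiles; interior cells use central
differences. Verified: circular-duct peak/mean = 2.0 (±0.2 % at 24 cells
across), planar wall shear 6µU/h (±2 % at 32 cells), linearity to 10⁻⁸.

## Electric model

Quasistatic frequency-domain current conservation with complex admittivity,

    ∇·(σ*(x) ∇V) = 0,   σ* = σ + i·2πf·ε₀·ε_r,

driven at 5 V amplitude (10 V peak-to-peak) and 60 kHz with Dirichlet
potentials on the two electrode conductors (ITO imposed as equipotential —
justified by its ≥12 orders of magnitude conductivity contrast). The 175 µm
PET film is lumped as a face (contact) impedance Z = d/σ*_PET on the
electrode surface by default; resolving it explicitly on fine grids
reproduces the 1D layered-media oracle to <0.1 %. Near-insulating cells
(PCL, C8; |σ*| < 10⁻³ of the medium's) are excluded as interior no-flux
boundaries unless `resolve_insulators` is set, and conducting pockets with
no path to an electrode are excluded (floating potential).

Cell-centered finite volumes with harmonic-mean face admittances; sparse LU
for small systems, otherwise LGMRES preconditioned by an FFT solve of the
uniform Neumann Laplacian with a shift matched to the total Dirichlet
coupling (which controls the near-null constant mode of the weakly-grounded
system). Reported E is the face current density divided by the local
admittivity, averaged to cell centers — consistent across lumped-PET faces
and material interfaces; |E| is the phasor magnitude.

The **1D layered oracle** (series impedances Z_k = d_k/σ*_k per unit area)
is the independent closed form for plate-capacitor stacks: for
PET | medium 10 mm | PET at 5 V, 60 kHz it gives J = 5/34.95 Ω·m² and
|E|_medium = 0.0954 V/m, independent of the medium gap because the film
impedance dominates. The lumped-circuit helpers implement the bench
arithmetic: series measurement-resistor correction (inferred reactive source
impedance) and current-to-field rescaling by linearity.

The bench validation cell defaults to medium flush with the plate footprint
(fringing suppressed); with a medium margin beyond the plate edges the model
develops a real ~6 % edge-leakage droop, whereas the physical fixture is
reported to produce a uniform field. The margin is a parameter for
sensitivity studies. The terminal-current *magnitude* of the validation cell
depends on the unpublished effective electrode–medium overlap and is
geometry-calibrated, not a validated output; the field value is.

## Two-level chamber solves

Chamber-scale problems span ~40 mm while the lattices need ≤100 µm cells, so
both physics use classic submodeling: a coarse global solve (flow: full
chamber at 500 µm; EM: electrode plate footprint box at 200–400 µm,
fringing suppressed), then a fine solve (100–150 µm) on a box around the
scaffold (margin 1.25–1.5 mm) with Dirichlet boundary data interpolated from
the coarse solution. For flow, only the *normal* boundary faces are fixed
(fixing tangential layers over-constrains corner-cell continuity) and the
interpolated data is made mass-consistent per connected fluid component; for
EM the complex potential is inpainted across excluded cells before
interpolation. ROI statistics are evaluated on the fine grid. The imposed
outlet velocity is recomputed from the discretized patch area so the
volumetric flux is exact at any resolution.

Problem sizes used by the shipped tests and the acceptance script (chosen as
this package's standard desk-scale operating points): flow 500 µm / 150 µm,
electric 300–400 µm / 100 µm for comparative studies and 200 µm / 100 µm for
the headline ROI-average field. At those sizes a full four-hypothesis design
loop runs in roughly 10 minutes on one CPU. Finer grids move the ROI-average
|E| of the fabrication candidate within a ±8 % band of 0.118 V/m.

## ROI dose statistics and the decision loop

The ROI is the axis-aligned scaffold envelope box. Dose distributions are
volume-weighted histograms over *medium* cells only (struts are not culture
medium; a flag includes them for sensitivity studies with resolved-insulator
solves), normalized to their peak — equivalent to the reference
node-occurrence convention up to discretization, and better defined. Default
bin width is 1/100 of the ROI maximum. Note the node-based convention
over-weights strut-adjacent mesh nodes where |E| is elevated, one reason
volume-weighted averages sit slightly below node-weighted ones.

Osteoinductive windows: τ ∈ [1.47, 24] mPa and [0.20, 13.35] mPa (two
published ranges; the scoring takes the best fraction over them), |E| ∈
[10⁻⁵, 1.3 × 10³] V/m. A hypothesis *passes* when some pump-rate scaling
≤ the equipment maximum (50 mL/min; scan over 40 logarithmic steps using
Stokes linearity) puts at least the required ROI volume fraction (default
0.5) inside a shear window, and the baseline field fraction meets the field
window. Among passers the largest ROI-mean |E| wins (widest multimodal
stimulation). This codifies a published narrative that mixes tunability and
field magnitude; the trace of every decision is logged in the report so the
rule can be audited. With the default four hypotheses at the baseline
protocol the loop selects horizontal + orthogonal: both vertical holders
deliver shear far below the windows at any admissible pump rate, and the
orthogonal scaffold carries the larger ROI-mean field.

## Synthetic bench recordings

`synthetic_dye_recording` emulates the camera measurement of a dye front
advected at constant speed: timestamps at the frame rate and positions with
i.i.d. Gaussian noise (default frame rate 30 Hz, noise ~0.1–0.2 mm,
deterministic per seed). It reproduces the estimator's input format, not
real tracer physics (no dispersion, no front smearing, no perspective
error); passing recovery tests therefore validates the estimators, not the
measurement technique. The two-point estimator matches the bench arithmetic
(7 mm / 2.963 s = 2.36 mm/s); the least-squares slope averages frame noise
and is preferred on noisy recordings.

## Known limitations

* Holder/channel geometry is functionally simplified; absolute dose values
  inherit that choice. In particular the honeycomb ROI-average |E| comes
  out near 0.10 V/m rather than the published 0.035 V/m: the simplified
  sealed plenum floats at a potential that drives axial currents through
  the hexagonal channels, where the published geometry evidently screens
  in-plane. The orthogonal > honeycomb ordering is insensitive to this and
  is what the tests assert.
* Coarse-grid lattice aliasing leaves a few-percent scatter in chamber
  quantities across coarse resolutions (the ROI-average |E| of the
  candidate spans 0.108–0.118 V/m over 200–400 µm global grids).
* Frequency-dependent measured impedance spectra, electrode placement
  optimization, transient/pulsatile flow, nutrient transport, scaffold
  surface micro-topology and any cellular-response prediction are out of
  scope.
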