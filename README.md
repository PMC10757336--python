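# stimtwin

A desk-scale digital twin of a perfusion bioreactor with capacitively
coupled (CCoupled) electrical stimulation for bone tissue engineering.

Perfusion bioreactors feed oxygen and nutrients to cell-seeded scaffolds
while the flow itself exerts an osteogenic mechanical stimulus — wall shear
stress τ = µγ̇ in the 10⁻⁴–10⁻² Pa range; capacitively coupled plate
electrodes add a pure electric-field stimulus (|E| up to ~kV/m) without
faradaic byproducts. Whether a given scaffold geometry, holder orientation
and pump/voltage protocol actually delivers doses inside the published
osteoinductive windows is impossible to see from bench measurements alone,
so the development workflow is model-driven: solve the physics for every
candidate, score the predicted microenvironment in the scaffold envelope
(the region of interest, ROI), pick the winner, fabricate it, and validate
the model against the few quantities a bench can measure.

`stimtwin` implements that whole loop as a Python library for computational
tissue-engineering researchers:

* **Parametric geometry** — orthogonal (woodpile) and honeycomb lattice
  scaffolds, simplified scaffold holders (horizontal/vertical), culture
  chamber, ITO-PET plate electrodes and the plate–medium–plate bench
  validation cell, all as implicit scenes voxelized at any resolution.
* **Stokes flow solver** — steady creeping flow (−µ∇²u + ∇p = 0, ∇·u = 0)
  on staggered MAC voxel grids with pressure-inlet / velocity-outlet /
  no-slip boundaries; derived shear rate γ̇ = √(2 D:D), shear stress
  τ = µγ̇ and Reynolds diagnostics.
* **Quasistatic electric solver** — ∇·(σ*∇V) = 0 with complex admittivity
  σ* = σ + i·2πf·ε₀·ε_r, equipotential electrode conductors, the thin PET
  film as a face impedance Z = d/σ*_PET, plus the closed-form 1D
  layered-media oracle and lumped-circuit bench arithmetic.
* **ROI dose analysis** — volume-weighted, peak-normalized histograms of τ
  and |E| over the scaffold envelope, in-window volume fractions against
  osteoinductive ranges (τ: 1.47–24 mPa and 0.20–13.35 mPa; |E|:
  10⁻⁵–1.3 × 10³ V/m).
* **Design loop** — evaluates scaffold × holder × protocol hypotheses with
  both solvers, applies the codified selection rule and emits an auditable
  decision trace; validation helpers reproduce the bench arithmetic
  (dye-front velocimetry, series-resistor correction, current-to-field
  rescaling).

Chamber-scale solves use a two-level strategy (coarse global grid + fine
scaffold-local submodel with interpolated boundary data); see
`docs/methods.md` for models, assumptions and numerical choices.

## Worked example

The bench validation cell — two 33 × 18 mm ITO-PET electrodes 10 mm apart
with culture medium between them, driven by a 10 V peak-to-peak, 60 kHz
sine:

```python
from stimtwin.em import EMBC, layered_1d_oracle, solve_em, apply_series_resistor
from stimtwin.geometry import build_validation_cell
from stimtwin.materials import default_registry

reg = default_registry()
stack = [(175e-6, reg["PET"]), (10e-3, reg["medium"]), (175e-6, reg["PET"])]
oracle = layered_1d_oracle(stack, v_amp=5.0, f=60e3)
print(f"1D oracle |E| in medium: {oracle.e_in('medium'):.4f} V/m")

cell = build_validation_cell(gap=10e-3, resolution=500e-6)
sol = solve_em(cell, EMBC(v_amp=5.0, f=60e3))
med = cell.mask("medium")
print(f"3D solve  |E| in medium: {sol.e_mag[med].mean():.4f} V/m")

i_corr, scale = apply_series_resistor(5.0, i_base=3.21e-5, r_s=21.89e3)
print(f"with 21.89 kOhm meter resistor: {i_corr * 1e6:.1f} uA, "
      f"|E| -> {0.095 * scale:.3f} V/m")
```

prints

```
1D oracle |E| in medium: 0.0954 V/m
3D solve  |E| in medium: 0.0954 V/m
with 21.89 kOhm meter resistor: 31.8 uA, |E| -> 0.094 V/m
```

The film-dominated series impedance (2 × 17.5 Ω·m² versus 0.007 Ω·m² of
medium) makes the medium field ≈0.095 V/m regardless of the gap — the
uniform field the bench fixture is designed to produce — and the
series-resistor correction shows why a measurement resistor barely perturbs
it. Rescaling the prediction to a measured current of 24.3 µA (versus the
predicted 32.1 µA, a 24 % difference) gives the corresponding field
estimate of 0.072 V/m via `field_from_measured_current`.

Chamber-scale prediction for the fabrication candidate (this is the
expensive call, ~1 min at the comparative resolutions):

```python
from stimtwin.geometry import orthogonal_scaffold
from stimtwin.submodel import solve_em_chamber
import numpy as np

res = solve_em_chamber(orthogonal_scaffold(), "horizontal",
                       coarse_h=400e-6, fine_h=100e-6)
roi = res.roi_mask & res.fine.grid.mask("medium")
print(f"ROI-average |E|: {np.nanmean(res.fine.e_mag[roi]):.4f} V/m")
```

prints `ROI-average |E|: 0.1180 V/m` — the volume-average field the
orthogonal scaffold sees between the chamber electrodes at the baseline
protocol.

A thin CLI wraps the same library (`stimtwin generate / solve-flow /
solve-em / analyze / design / validate`, YAML run configs, VTK/CSV/JSON
outputs, exit code 2 for config errors and 3 for solver non-convergence).

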