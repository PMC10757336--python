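"""Two-level (coarse global + fine submodel) chamber solves.

Chamber-scale problems span ~40 mm while the scaffold lattice needs
<= 100 um cells to resolve 250-500 um struts; a uniform grid fine enough for
the lattice would exceed 10^8 cells.  Both physics here are elliptic, so the
classic submodeling strategy applies: solve the whole chamber on a coarse
grid (the lattice voxelized coarsely), then re-solve a small box around the
scaffold on a fine grid with Dirichlet boundary data interpolated from the
coarse solution, and evaluate ROI dose statistics on the fine solve.  The
scene-based geometry makes the re-voxelization at arbitrary resolution
exact rather than an image-resampling approximation.

The electric problem additionally restricts the global domain to the
electrode plate footprint (fringing suppressed): the film-dominated series
impedance makes the current density through the plates nearly uniform, and
medium outside the footprint carries little current.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._numerics import fill_nan_by_diffusion, trilinear_sampler
from .em import EMBC, EMSolution, solve_em
from .flow import FlowBC, FlowSolution, solve_flow
from .geometry import (
    CHAMBER_HEIGHT,
    CHAMBER_RADIUS,
    ElectrodeAssembly,
    ScaffoldSpec,
    chamber_scene,
    scaffold_envelope_box,
)
from .grid import LabeledVoxelGrid
from .materials import MaterialRegistry, default_registry

__all__ = ["ChamberEMResult", "ChamberFlowResult", "solve_em_chamber", "solve_flow_chamber"]

MM = 1e-3


@dataclass
class ChamberEMResult:
    coarse: EMSolution
    fine: EMSolution
    roi_mask: np.ndarray  # on the fine grid


@dataclass
class ChamberFlowResult:
    coarse: FlowSolution
    fine: FlowSolution
    roi_mask: np.ndarray  # on the fine grid
    outlet_flow: float  # imposed volumetric outflow, m^3/s


def _fine_box(scaffold: ScaffoldSpec, orientation: str, margin: float,
              clip_lo, clip_hi, h: float, center=(0.0, 0.0, 0.0)):
    lo, hi = scaffold_envelope_box(scaffold, center=center, orientation=orientation)
    lo = np.maximum(lo - margin, np.asarray(clip_lo) + 2 * h)
    hi = np.minimum(hi + margin, np.asarray(clip_hi) - 2 * h)
    return lo, hi


def solve_em_chamber(
    scaffold: ScaffoldSpec,
    holder: str,
    electrodes: ElectrodeAssembly | None = None,
    bc: EMBC | None = None,
    registry: MaterialRegistry | None = None,
    *,
    coarse_h: float = 400e-6,
    fine_h: float = 100e-6,
    margin: float = 1.5 * MM,
    tol: float = 1e-8,
    scaffold_y_offsets: tuple = (-7 * MM, 7 * MM),
) -> ChamberEMResult:
    """Electric-field solve of scaffold-holder assemblies between electrodes.

    Defaults: the chamber electrode pair 22 mm apart at 10 V peak-to-peak
    (5 V amplitude) and 60 kHz, stimulating the paired side-by-side
    scaffold+holder units it spans in the bioreactor.  ROI statistics refer
    to the first scaffold.  Returns coarse and fine solutions plus the ROI
    mask on the fine grid.
    """
    electrodes = electrodes or ElectrodeAssembly()
    bc = bc or EMBC(v_amp=5.0, f=60e3)
    registry = registry or default_registry()
    orientation = "flat" if holder == "horizontal" else "upright"

    scene, meta = chamber_scene(scaffold, holder, electrodes,
                                scaffold_y_offsets=scaffold_y_offsets)
    ex1 = electrodes.gap / 2 + electrodes.plate_thickness
    py, pz = electrodes.plate_size[0] / 2, electrodes.plate_size[1] / 2
    box_lo = (-ex1, -py, -pz)
    box_hi = (ex1, py, pz)

    coarse = scene.voxelize(box_lo, box_hi, coarse_h, metadata=meta, supersample=3)
    sol_c = solve_em(coarse, bc, registry, tol=tol)

    # inpaint excluded cells, then interpolate the complex potential
    V = fill_nan_by_diffusion(sol_c.potential)
    axes = tuple(coarse.cell_centers(a) for a in range(3))
    interp = trilinear_sampler(axes, V)

    lo, hi = _fine_box(scaffold, orientation, margin, box_lo, box_hi, coarse_h,
                       center=(0.0, scaffold_y_offsets[0], 0.0))
    fine = scene.voxelize(lo, hi, fine_h, metadata=meta)
    shell = np.zeros(fine.shape, dtype=bool)
    shell[[0, -1], :, :] = True
    shell[:, [0, -1], :] = True
    shell[:, :, [0, -1]] = True
    pts = np.stack(
        np.meshgrid(*[fine.cell_centers(a) for a in range(3)], indexing="ij"),
        axis=-1,
    )[shell]
    dirichlet = np.full(fine.shape, np.nan, dtype=complex)
    dirichlet[shell] = interp(pts)
    sol_f = solve_em(fine, bc, registry, dirichlet_boundary=dirichlet, tol=tol)

    from .roi import extract_roi

    roi = extract_roi(fine, scaffold)
    return ChamberEMResult(coarse=sol_c, fine=sol_f, roi_mask=roi)


def _interp_face_fields(coarse: LabeledVoxelGrid, u_faces) -> list:
    """Trilinear samplers of the three staggered velocity components."""
    h = coarse.spacing
    samplers = []
    for ax in range(3):
        axes = []
        for a in range(3):
            n = coarse.shape[a]
            if a == ax:  # face centers along the normal axis
                axes.append(coarse.origin[a] + np.arange(n + 1) * h)
            else:
                axes.append(coarse.origin[a] + (np.arange(n) + 0.5) * h)
        samplers.append(trilinear_sampler(tuple(axes), u_faces[ax]))
    return samplers


def solve_flow_chamber(
    scaffold: ScaffoldSpec | None,
    holder: str,
    q_outlet: float = 12.5e-6 / 60.0,
    registry: MaterialRegistry | None = None,
    *,
    coarse_h: float = 500e-6,
    fine_h: float = 150e-6,
    margin: float = 1.25 * MM,
    tol: float = 1e-6,
    fine_maxiter: int = 40000,
) -> ChamberFlowResult:
    """Perfusion solve of a scaffold-holder assembly in the chamber.

    ``q_outlet`` is the volumetric outflow drawn through this holder's exit
    channel (one quarter of the pump rate for the four-scaffold manifold;
    default 12.5 mL/min).  The imposed outlet velocity is computed from the
    discretized patch area so the volumetric flux is exact at any
    resolution.  Medium enters through the open chamber boundary at gauge
    pressure 0.
    """
    registry = registry or default_registry()
    orientation = "flat" if holder == "horizontal" else "upright"

    scene, meta = chamber_scene(scaffold, holder, None)
    r = CHAMBER_RADIUS
    box_lo = (-r, -r, -CHAMBER_HEIGHT / 2)
    box_hi = (r, r, CHAMBER_HEIGHT / 2)
    # Coarse-grid sampling is geometry dependent: a prismatic channel
    # lattice must keep its channels connected (center sampling) or the
    # imposed outflow has no path, while a strut lattice at cell-size
    # feature scale can vanish entirely under center sampling and needs
    # majority-vote supersampling to stay present.
    ss = 1 if (scaffold is not None and scaffold.kind == "honeycomb") else 3
    coarse = scene.voxelize(box_lo, box_hi, coarse_h, metadata=meta, supersample=ss)

    bc_c = _outlet_bc(coarse, q_outlet, registry)
    sol_c = solve_flow(coarse, bc_c, registry=registry, tol=tol, method="minres")

    if scaffold is None:
        roi = np.ones(coarse.shape, dtype=bool)
        return ChamberFlowResult(coarse=sol_c, fine=sol_c, roi_mask=roi,
                                 outlet_flow=q_outlet)

    samplers = _interp_face_fields(coarse, sol_c.u_faces)
    lo, hi = _fine_box(scaffold, orientation, margin, box_lo, box_hi, coarse_h)
    fine = scene.voxelize(lo, hi, fine_h, metadata=meta)

    dirichlet = []
    for ax in range(3):
        fshape = list(fine.shape)
        fshape[ax] += 1
        arr = np.full(tuple(fshape), np.nan)
        # fix only the normal faces on the two boundary planes: fixing the
        # tangential boundary-layer faces too would over-constrain the
        # continuity equations of corner cells (interpolated data is not
        # locally divergence-free on the fine grid)
        bmask = np.zeros(tuple(fshape), dtype=bool)
        sel = [slice(None)] * 3
        sel[ax] = 0
        bmask[tuple(sel)] = True
        sel[ax] = fshape[ax] - 1
        bmask[tuple(sel)] = True
        coords = []
        h = fine.spacing
        for a in range(3):
            n = fine.shape[a]
            if a == ax:
                coords.append(fine.origin[a] + np.arange(n + 1) * h)
            else:
                coords.append(fine.origin[a] + (np.arange(n) + 0.5) * h)
        pts = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)[bmask]
        arr[bmask] = samplers[ax](pts)
        dirichlet.append(arr)

    bc_f = FlowBC()
    sol_f = solve_flow(fine, bc_f, registry=registry, tol=tol, method="minres",
                       dirichlet_faces=tuple(dirichlet), maxiter=fine_maxiter)

    from .roi import extract_roi

    roi = extract_roi(fine, scaffold)
    return ChamberFlowResult(coarse=sol_c, fine=sol_f, roi_mask=roi,
                             outlet_flow=q_outlet)


def _outlet_bc(grid: LabeledVoxelGrid, q_outlet: float,
               registry: MaterialRegistry) -> FlowBC:
    """Outlet velocity from the discrete patch area so the flux is exact."""
    from .flow import _cell_categories, _outlet_face_mask

    outlet = grid.metadata.get("outlet")
    if outlet is None:
        raise ValueError("grid metadata carries no outlet patch")
    ax = outlet["axis"]
    fshape = list(grid.shape)
    fshape[ax] += 1
    mask = _outlet_face_mask(grid, outlet, tuple(fshape), ax)
    cat = _cell_categories(grid, registry)
    # count only faces adjacent to a fluid cell
    sel = [slice(None)] * 3
    if outlet.get("side", "min") == "min":
        sel[ax] = 0
        n_faces = int((mask[tuple(sel)] & (cat.take(0, axis=ax) == 1)).sum())
    else:
        sel[ax] = fshape[ax] - 1
        n_faces = int((mask[tuple(sel)] & (cat.take(-1, axis=ax) == 1)).sum())
    if n_faces == 0:
        raise ValueError("outlet patch contains no fluid faces at this resolution")
    v = q_outlet / (n_faces * grid.spacing**2)
    return FlowBC(outlet_velocity=v)
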