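"""Parametric generation of scaffolds, chamber assemblies and test cells.

This module is the pipeline's synthetic-input layer: it turns a handful of
printed design parameters into labeled voxel grids.  Two scaffold families
are provided:

orthogonal ("woodpile")
    Alternating layers of parallel cylinders (diameter = filament size)
    rotated 90 degrees per layer.  Vertical layer pitch is
    ``filament * (1 - superposition)`` so consecutive layers interpenetrate
    slightly, as printed; in-plane pitch is ``filament + pore``.
honeycomb
    Prismatic walls of thickness = truss around hexagonal channels of
    across-flats width = macropore; channels run along the envelope's local
    z axis.

The holders are *simplified parametric* stand-ins for the printed parts,
keeping only their functional differences: the horizontal holder supports the
scaffold lying flat over a suction plenum drained by two lateral channels
that merge into a single exit pipe; the vertical holder supports the scaffold
upright over a single bottom outlet channel.  Exit-pipe cross sections are
identical for the two holders.  Blueprint-exact channel shapes are out of
scope (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .grid import LabeledVoxelGrid, Scene

__all__ = [
    "ScaffoldSpec",
    "ElectrodeAssembly",
    "orthogonal_scaffold",
    "honeycomb_scaffold",
    "scaffold_predicate",
    "generate_scaffold",
    "assemble_chamber",
    "build_validation_cell",
    "synthetic_dye_recording",
    "CHAMBER_RADIUS",
    "CHAMBER_HEIGHT",
    "EXIT_CHANNEL_HALF",
]

MM = 1e-3
UM = 1e-6

#: Culture-chamber medium cylinder (radius, height).
CHAMBER_RADIUS = 20 * MM
CHAMBER_HEIGHT = 30 * MM
#: Half-width of the square holder exit channel (same for both holders).
EXIT_CHANNEL_HALF = 1.5 * MM


@dataclass(frozen=True)
class ScaffoldSpec:
    """Parametric lattice scaffold.

    Defaults reproduce the two reference designs: a 10.0 x 10.0 x 2.75 mm
    orthogonal lattice with 500 um filament and pore and 10 % layer
    superposition, and a 10.2 x 10.2 x 3.0 mm honeycomb with 250 um truss
    and 300 um macropore.
    """

    kind: Literal["orthogonal", "honeycomb"]
    envelope: tuple[float, float, float]
    filament_or_truss: float
    pore: float
    superposition_frac: float = 0.0
    material: str = "PCL"

    def __post_init__(self) -> None:
        if self.kind not in ("orthogonal", "honeycomb"):
            raise ValueError(f"unknown scaffold kind {self.kind!r}")
        if any(L <= 0 for L in self.envelope):
            raise ValueError("envelope lengths must be > 0")
        if self.filament_or_truss < 0 or self.pore <= 0:
            raise ValueError("filament/truss must be >= 0 and pore > 0")
        if not (0.0 <= self.superposition_frac < 0.5):
            raise ValueError("superposition_frac must be in [0, 0.5)")


def orthogonal_scaffold(**overrides) -> ScaffoldSpec:
    spec = ScaffoldSpec(
        kind="orthogonal",
        envelope=(10.0 * MM, 10.0 * MM, 2.75 * MM),
        filament_or_truss=500 * UM,
        pore=500 * UM,
        superposition_frac=0.10,
    )
    return replace(spec, **overrides) if overrides else spec


def honeycomb_scaffold(**overrides) -> ScaffoldSpec:
    spec = ScaffoldSpec(
        kind="honeycomb",
        envelope=(10.2 * MM, 10.2 * MM, 3.0 * MM),
        filament_or_truss=250 * UM,
        pore=300 * UM,
    )
    return replace(spec, **overrides) if overrides else spec


@dataclass(frozen=True)
class ElectrodeAssembly:
    """Pair of parallel, coaxial ITO-on-PET plate electrodes along x.

    ``gap`` is the inner conductor-face separation; the PET film of thickness
    ``pet_thickness`` faces the medium.  With ``pet_resolved`` false the PET
    film is not voxelized but carried as metadata and applied by the EM
    solver as a face (contact) impedance — the default for chamber-scale
    grids where a 175 um film cannot be resolved.
    """

    plate_size: tuple[float, float] = (33 * MM, 18 * MM)  # (y, z) extents
    pet_thickness: float = 175 * UM
    gap: float = 22 * MM
    plate_thickness: float = 1 * MM
    pet_resolved: bool = False

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("electrode gap must be > 0")
        if self.pet_thickness < 0:
            raise ValueError("pet_thickness must be >= 0")


# ---------------------------------------------------------------------------
# implicit scaffold predicates
# ---------------------------------------------------------------------------


def _orthogonal_inside(spec: ScaffoldSpec, x, y, z):
    """Membership test in local coordinates (layers stack along local z)."""
    Lx, Ly, Lz = spec.envelope
    d = spec.filament_or_truss
    r = d / 2.0
    pitch_in = spec.filament_or_truss + spec.pore
    pitch_z = d * (1.0 - spec.superposition_frac)
    n_layers = max(1, int(math.floor((Lz - d) / pitch_z + 1e-9)) + 1)
    z_first = -0.5 * (n_layers - 1) * pitch_z

    in_env = (np.abs(x) <= Lx / 2) & (np.abs(y) <= Ly / 2) & (np.abs(z) <= Lz / 2)
    inside = np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
    m0 = np.floor((z - z_first) / pitch_z).astype(int)
    for dm in (-1, 0, 1):
        m = np.clip(m0 + dm, 0, n_layers - 1)
        zc = z_first + m * pitch_z
        # even layers: cylinders along x (axes vary in y); odd: along y
        for parity, t in ((0, y), (1, x)):
            L_t = Ly if parity == 0 else Lx
            n_cyl = max(1, int(math.floor((L_t - d) / pitch_in + 1e-9)) + 1)
            tc = (np.round(t / pitch_in + 0.5 * (n_cyl - 1))
                  - 0.5 * (n_cyl - 1)) * pitch_in
            tc = np.clip(tc, -0.5 * (n_cyl - 1) * pitch_in, 0.5 * (n_cyl - 1) * pitch_in)
            hit = ((m % 2) == parity) & ((t - tc) ** 2 + (z - zc) ** 2 <= r * r)
            inside |= hit
    return inside & in_env


_SQ3_2 = math.sqrt(3.0) / 2.0


def _honeycomb_channel(spec: ScaffoldSpec, x, y):
    """True where (x, y) falls inside a hexagonal channel (local coords)."""
    w = spec.pore  # across-flats channel width
    p = spec.pore + spec.filament_or_truss  # center-to-center pitch
    # triangular lattice basis a1 = (p, 0), a2 = (p/2, p*sqrt(3)/2)
    j_f = y / (p * _SQ3_2)
    i_f = x / p - 0.5 * j_f
    inside = np.zeros(np.broadcast(x, y).shape, dtype=bool)
    i0 = np.floor(i_f)
    j0 = np.floor(j_f)
    for di in (0.0, 1.0):
        for dj in (0.0, 1.0):
            cx = (i0 + di) * p + (j0 + dj) * p * 0.5
            cy = (j0 + dj) * p * _SQ3_2
            dx = x - cx
            dy = y - cy
            h = np.maximum(np.abs(dx),
                           np.maximum(np.abs(0.5 * dx + _SQ3_2 * dy),
                                      np.abs(-0.5 * dx + _SQ3_2 * dy)))
            inside |= h < w / 2
    return inside


def _honeycomb_inside(spec: ScaffoldSpec, x, y, z):
    Lx, Ly, Lz = spec.envelope
    in_env = (np.abs(x) <= Lx / 2) & (np.abs(y) <= Ly / 2) & (np.abs(z) <= Lz / 2)
    if spec.filament_or_truss == 0:
        return np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
    chan = _honeycomb_channel(spec, x, y)
    return in_env & np.broadcast_to(~chan, np.broadcast(x, y, z).shape)


_ORIENTATIONS = {"flat", "upright"}


def scaffold_predicate(
    spec: ScaffoldSpec,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    orientation: str = "flat",
):
    """World-coordinate membership predicate for a scaffold.

    ``flat`` keeps the local stacking/channel axis along world z (scaffold
    lying down); ``upright`` rotates the scaffold 90 degrees about y so the
    local z axis points along world x (scaffold standing, thin side facing
    the electrodes).
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    cx, cy, cz = center
    inner = _orthogonal_inside if spec.kind == "orthogonal" else _honeycomb_inside

    def pred(x, y, z):
        dx, dy, dz = x - cx, y - cy, z - cz
        if orientation == "upright":
            # rotation about y: world x <- local z, world z <- -local x
            dx, dz = -dz, dx
        return inner(spec, dx, dy, dz)

    return pred


def scaffold_envelope_box(
    spec: ScaffoldSpec,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    orientation: str = "flat",
) -> tuple[np.ndarray, np.ndarray]:
    """World-coordinate (lo, hi) corners of the scaffold envelope."""
    Lx, Ly, Lz = spec.envelope
    half = np.array([Lx, Ly, Lz]) / 2
    if orientation == "upright":
        half = half[[2, 1, 0]]
    c = np.asarray(center, float)
    return c - half, c + half


def generate_scaffold(spec: ScaffoldSpec, resolution: float) -> LabeledVoxelGrid:
    """Voxelize a free-standing scaffold in a medium-filled envelope box.

    ``resolution`` must put at least 3 cells across a pore, otherwise the
    lattice aliases away; a coarser request is refused with the computed
    minimum.
    """
    max_h = spec.pore / 3.0
    if resolution > max_h * (1 + 1e-9):
        raise ValueError(
            f"resolution {resolution:g} m too coarse for pore {spec.pore:g} m; "
            f"need <= {max_h:g} m (3 cells per pore)"
        )
    lo, hi = scaffold_envelope_box(spec)
    scene = Scene(background=("medium", "medium"))
    scene.add("scaffold", spec.material, scaffold_predicate(spec))
    grid = scene.voxelize(lo, hi, resolution, metadata={
        "scaffold_box": (tuple(lo), tuple(hi)),
        "scaffold_spec": spec,
    })
    return grid


# ---------------------------------------------------------------------------
# chamber assembly
# ---------------------------------------------------------------------------


def _box(lo, hi):
    (x0, y0, z0), (x1, y1, z1) = lo, hi

    def pred(x, y, z):
        return ((x >= x0) & (x < x1) & (y >= y0) & (y < y1)
                & (z >= z0) & (z < z1))

    return pred


def _cyl_z(radius, z0, z1):
    def pred(x, y, z):
        return (x * x + y * y <= radius * radius) & (z >= z0) & (z < z1)

    return pred


def _holder_scene_items(holder: str, scaffold_lo_z: float,
                        y0: float = 0.0) -> list[tuple[str, str | None, object]]:
    """Simplified holder solids and carved channels, scaffold-centered frame.

    ``y0`` shifts the whole holder sideways (multi-holder chambers).
    Returns scene items in paint order (solids first, channels carved after).
    """

    def _boxy(lo, hi):
        return _box((lo[0], lo[1] + y0, lo[2]), (hi[0], hi[1] + y0, hi[2]))

    e = EXIT_CHANNEL_HALF
    zb = -CHAMBER_HEIGHT / 2  # chamber bottom
    items: list[tuple[str, str | None, object]] = []
    if holder == "horizontal":
        s = scaffold_lo_z  # underside of the flat scaffold
        items += [
            ("holder", "C8", _boxy((-7 * MM, -7 * MM, -6 * MM), (7 * MM, 7 * MM, s))),
            ("holder", "C8", _boxy((-3 * MM, -3 * MM, zb), (3 * MM, 3 * MM, -6 * MM))),
            # suction plenum open to the scaffold underside
            ("medium", "medium",
             _boxy((-5 * MM, -5 * MM, -3.5 * MM), (5 * MM, 5 * MM, s))),
            # two lateral collector channels beneath the plenum floor
            ("medium", "medium",
             _boxy((-1.75 * MM, 1.75 * MM, -5 * MM), (1.75 * MM, 5 * MM, -3.5 * MM))),
            ("medium", "medium",
             _boxy((-1.75 * MM, -5 * MM, -5 * MM), (1.75 * MM, -1.75 * MM, -3.5 * MM))),
            # central junction where the two channels merge
            ("medium", "medium",
             _boxy((-1.75 * MM, -1.75 * MM, -5 * MM), (1.75 * MM, 1.75 * MM, -3.5 * MM))),
            # single exit pipe down through the chamber floor
            ("medium", "medium", _boxy((-e, -e, zb), (e, e, -4 * MM))),
        ]
    elif holder == "vertical":
        s = scaffold_lo_z  # bottom edge of the upright scaffold
        items += [
            ("holder", "C8", _boxy((-3 * MM, -7 * MM, -8 * MM), (3 * MM, 7 * MM, s))),
            ("holder", "C8", _boxy((-3 * MM, -3 * MM, zb), (3 * MM, 3 * MM, -8 * MM))),
            # intake slot under the scaffold bottom face
            ("medium", "medium",
             _boxy((-1.4 * MM, -5 * MM, -6.5 * MM), (1.4 * MM, 5 * MM, s))),
            # single bottom outlet channel
            ("medium", "medium", _boxy((-e, -e, zb), (e, e, -6 * MM))),
        ]
    else:
        raise ValueError(f"holder must be 'horizontal' or 'vertical', got {holder!r}")
    return items


def chamber_scene(
    scaffold: ScaffoldSpec | None,
    holder: str,
    electrodes: ElectrodeAssembly | None = None,
    scaffold_y_offsets: Sequence[float] = (0.0,),
) -> tuple[Scene, dict]:
    """Implicit scene for a scaffold-holder-chamber (optionally + electrodes).

    The (first) scaffold center sits at world (0, y_offset, 0) for both
    holders; the chamber is the medium cylinder of radius ``CHAMBER_RADIUS``
    and height ``CHAMBER_HEIGHT``, the region outside it is labeled ``open``
    (the pressure-reference boundary of the flow model), and the chamber
    floor is a printed plate pierced by the holder exit pipe(s).

    ``scaffold_y_offsets`` places one scaffold-plus-holder unit per entry
    along y.  Electric solves use the paired layout (each electrode pair
    stimulates two side-by-side scaffolds, so the plate footprint is shared
    between two holder units); flow solves model one holder per outlet.
    ROI metadata always refers to the first scaffold.
    """
    zb, zt = -CHAMBER_HEIGHT / 2, CHAMBER_HEIGHT / 2
    scene = Scene(background=("open", None))
    scene.add("medium", "medium", _cyl_z(CHAMBER_RADIUS, zb, zt))
    scene.add("floor", "C8", _cyl_z(CHAMBER_RADIUS, zb, zb + 1 * MM))

    orientation = "flat" if holder == "horizontal" else "upright"
    if scaffold is not None:
        env_lo, env_hi = scaffold_envelope_box(
            scaffold, center=(0.0, scaffold_y_offsets[0], 0.0),
            orientation=orientation)
        scaffold_lo_z = float(env_lo[2])
    else:
        scaffold_lo_z = -1.375 * MM

    for y0 in scaffold_y_offsets:
        for label, mat, pred in _holder_scene_items(holder, scaffold_lo_z, y0):
            scene.add(label, mat, pred)

    y_first = scaffold_y_offsets[0]
    meta: dict = {
        "holder": holder,
        "outlet": {"axis": 2, "side": "min",
                   "box": (-EXIT_CHANNEL_HALF, y_first - EXIT_CHANNEL_HALF,
                           EXIT_CHANNEL_HALF, y_first + EXIT_CHANNEL_HALF)},
    }
    if scaffold is not None:
        for y0 in scaffold_y_offsets:
            scene.add("scaffold", scaffold.material,
                      scaffold_predicate(scaffold, center=(0.0, y0, 0.0),
                                         orientation=orientation))
        meta["scaffold_box"] = (tuple(env_lo), tuple(env_hi))
        meta["scaffold_spec"] = scaffold
        meta["scaffold_orientation"] = orientation

    if electrodes is not None:
        if scaffold is not None:
            half_gap = electrodes.gap / 2
            if env_hi[0] > half_gap or env_lo[0] < -half_gap:
                raise ValueError("electrode plates intersect the scaffold")
        ex0 = electrodes.gap / 2
        py, pz = electrodes.plate_size[0] / 2, electrodes.plate_size[1] / 2
        if electrodes.pet_resolved and electrodes.pet_thickness > 0:
            t = electrodes.pet_thickness
            scene.add("PET", "PET", _box((ex0 - t, -py, -pz), (ex0, py, pz)))
            scene.add("PET", "PET", _box((-ex0, -py, -pz), (-ex0 + t, py, pz)))
        scene.add("electrode_active", "ITO",
                  _box((ex0, -py, -pz), (ex0 + electrodes.plate_thickness, py, pz)))
        scene.add("electrode_ground", "ITO",
                  _box((-ex0 - electrodes.plate_thickness, -py, -pz), (-ex0, py, pz)))
        meta["electrodes"] = electrodes
        if not electrodes.pet_resolved:
            meta["pet_face_impedance"] = {
                "thickness": electrodes.pet_thickness, "material": "PET",
            }
    return scene, meta


def assemble_chamber(
    scaffold: ScaffoldSpec | None,
    holder: str,
    electrodes: ElectrodeAssembly | None = None,
    resolution: float = 500 * UM,
    bbox: tuple | None = None,
    supersample: int = 1,
) -> LabeledVoxelGrid:
    """Voxelized chamber assembly; see :func:`chamber_scene`."""
    scene, meta = chamber_scene(scaffold, holder, electrodes)
    if bbox is None:
        r = CHAMBER_RADIUS
        lo = (-r, -r, -CHAMBER_HEIGHT / 2)
        hi = (r, r, CHAMBER_HEIGHT / 2)
        if electrodes is not None:
            ex1 = electrodes.gap / 2 + electrodes.plate_thickness
            lo = (min(lo[0], -ex1), lo[1], lo[2])
            hi = (max(hi[0], ex1), hi[1], hi[2])
    else:
        lo, hi = bbox
    return scene.voxelize(lo, hi, resolution, metadata=meta, supersample=supersample)


# ---------------------------------------------------------------------------
# validation cell
# ---------------------------------------------------------------------------


def build_validation_cell(
    gap: float = 10 * MM,
    plate_size: tuple[float, float] = (33 * MM, 18 * MM),
    pet_thickness: float = 175 * UM,
    resolution: float = 500 * UM,
    margin: float = 0.0,
    pet_resolved: bool = False,
    enclosure_material: str | None = "C8",
) -> LabeledVoxelGrid:
    """Plate - medium - plate capacitively-coupled test cell.

    Mirrors the bench validation fixture: two ITO-PET film electrodes mounted
    ``gap`` apart with culture medium between them, inside a non-conducting
    enclosure.  ``margin`` adds medium beyond the plate edges (fringing);
    zero margin gives the fringing-suppressed, effectively one-dimensional
    variant used for oracle cross-checks (``enclosure_material=None``
    additionally makes the enclosure a strict no-flux boundary even when
    insulators are resolved).  With ``pet_resolved`` the PET film
    is voxelized (requires a resolution well below ``pet_thickness``),
    otherwise it is handed to the EM solver as a face impedance.
    """
    if gap <= 0:
        raise ValueError("gap must be > 0")
    py, pz = plate_size[0] / 2, plate_size[1] / 2
    hx = gap / 2
    # snap conductor thickness to whole voxels so material interfaces land
    # on grid planes (otherwise layer thicknesses alias by up to one cell)
    target_t = 0.5 * MM if pet_resolved else 1 * MM
    plate_t = resolution * max(2, round(target_t / resolution))
    t_pet = pet_thickness if pet_resolved else 0.0

    scene = Scene(background=("enclosure", enclosure_material))
    scene.add("medium", "medium",
              _box((-hx, -py - margin, -pz - margin), (hx, py + margin, pz + margin)))
    if pet_resolved and pet_thickness > 0:
        # the film faces the medium, outside the gap: medium slab keeps
        # the full ``gap`` thickness
        scene.add("PET", "PET", _box((hx, -py, -pz), (hx + t_pet, py, pz)))
        scene.add("PET", "PET", _box((-hx - t_pet, -py, -pz), (-hx, py, pz)))
    scene.add("electrode_active", "ITO",
              _box((hx + t_pet, -py, -pz), (hx + t_pet + plate_t, py, pz)))
    scene.add("electrode_ground", "ITO",
              _box((-hx - t_pet - plate_t, -py, -pz), (-hx - t_pet, py, pz)))

    lo = (-hx - t_pet - plate_t, -py - margin - resolution, -pz - margin - resolution)
    hi = (hx + t_pet + plate_t, py + margin + resolution, pz + margin + resolution)
    meta: dict = {"gap": gap, "plate_size": plate_size}
    if not pet_resolved and pet_thickness > 0:
        meta["pet_face_impedance"] = {"thickness": pet_thickness, "material": "PET"}
    return scene.voxelize(lo, hi, resolution, metadata=meta)


# ---------------------------------------------------------------------------
# synthetic dye-front recording
# ---------------------------------------------------------------------------


def synthetic_dye_recording(
    true_velocity: float,
    path_length: float,
    frame_rate: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    t0: float = 0.0,
) -> np.ndarray:
    """Synthetic (timestamp, dye-front position) samples.

    Emulates a camera recording of a dye front advected at constant
    ``true_velocity`` over ``path_length``, sampled at ``frame_rate`` with
    i.i.d. Gaussian position noise of standard deviation ``noise_sd``
    (meters).  Returns an (n, 2) array of (t, x) rows; deterministic given
    ``seed``.
    """
    if path_length <= 0 or frame_rate <= 0:
        raise ValueError("path_length and frame_rate must be > 0")
    if true_velocity < 0 or noise_sd < 0:
        raise ValueError("true_velocity and noise_sd must be >= 0")
    if true_velocity == 0:
        n = 2
        times = t0 + np.arange(n) / frame_rate
        positions = np.zeros(n)
    else:
        duration = path_length / true_velocity
        n = max(2, int(math.floor(duration * frame_rate)) + 1)
        times = t0 + np.arange(n) / frame_rate
        positions = true_velocity * (times - t0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, noise_sd, size=n)
    return np.column_stack([times, positions])
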