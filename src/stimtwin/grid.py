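"""Labeled voxel grids and implicit-geometry scenes.

The shared discretization for both physics solvers is a regular isotropic
voxel grid in which every cell carries a material label.  Geometry is defined
*implicitly* (vectorized point-membership predicates painted in order), so the
same scene can be voxelized at any resolution or cropped to a sub-box — the
basis of the coarse-global / fine-submodel solve strategy used for chamber
scale problems.

Conventions
-----------
* 0-based indexing; cell (i, j, k) occupies the half-open box
  ``[origin + i*h, origin + (i+1)*h)`` per axis; membership is evaluated at
  the cell center.
* z is the chamber axis (gravity); capacitively-coupled electrodes face each
  other along x.
* All lengths in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["LabeledVoxelGrid", "Scene"]

# predicate signature: f(x, y, z) -> bool array, with x/y/z broadcastable
Predicate = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


@dataclass
class Scene:
    """Ordered list of implicit solids; later entries overwrite earlier ones."""

    background: tuple[str, str | None] = ("open", None)
    items: list[tuple[str, str | None, Predicate]] = field(default_factory=list)

    def add(self, label: str, material: str | None, predicate: Predicate) -> "Scene":
        self.items.append((label, material, predicate))
        return self

    def voxelize(
        self,
        lo: Sequence[float],
        hi: Sequence[float],
        spacing: float,
        metadata: dict | None = None,
        supersample: int = 1,
    ) -> "LabeledVoxelGrid":
        """Rasterize the scene on a grid covering ``[lo, hi]`` at ``spacing``.

        With ``supersample`` = k each cell is sampled at k^3 interior points
        and assigned a label by majority (>= 50 % occupancy), which keeps
        volume fractions accurate when features approach the cell size —
        important for coarse global grids where plain center sampling
        aliases against periodic lattices.
        """
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        if np.any(hi <= lo):
            raise ValueError("voxelize: hi must exceed lo on every axis")
        if supersample < 1:
            raise ValueError("supersample must be >= 1")
        shape = tuple(int(round((hi[a] - lo[a]) / spacing)) for a in range(3))
        if any(n < 1 for n in shape):
            raise ValueError(f"voxelize: empty grid {shape}")
        grid = LabeledVoxelGrid.empty(
            shape, spacing, lo, background=self.background[0],
            background_material=self.background[1],
        )
        k = supersample
        offsets = (np.arange(k) + 0.5) / k  # fractions of a cell edge
        for label, material, pred in self.items:
            lid = grid.ensure_label(label, material)
            if k == 1:
                X = grid.cell_centers(0)[:, None, None]
                Y = grid.cell_centers(1)[None, :, None]
                Z = grid.cell_centers(2)[None, None, :]
                mask = np.broadcast_to(pred(X, Y, Z), shape)
            else:
                count = np.zeros(shape, dtype=np.int16)
                base = [lo[a] + np.arange(shape[a]) * spacing for a in range(3)]
                for ox in offsets:
                    X = (base[0] + ox * spacing)[:, None, None]
                    for oy in offsets:
                        Y = (base[1] + oy * spacing)[None, :, None]
                        for oz in offsets:
                            Z = (base[2] + oz * spacing)[None, None, :]
                            count += np.broadcast_to(pred(X, Y, Z), shape)
                mask = count * 2 >= k**3
            grid.labels[mask] = lid
        grid.metadata.update(metadata or {})
        grid.scene = self
        return grid


class LabeledVoxelGrid:
    """Regular isotropic voxel grid with per-cell material labels."""

    def __init__(
        self,
        labels: np.ndarray,
        spacing: float,
        origin: Sequence[float],
        label_names: list[str],
        material_map: dict[str, str | None],
        metadata: dict | None = None,
    ) -> None:
        labels = np.asarray(labels)
        if labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if spacing <= 0:
            raise ValueError("spacing must be > 0")
        self.labels = labels
        self.spacing = float(spacing)
        self.origin = np.asarray(origin, dtype=float).copy()
        self.label_names = list(label_names)
        self.material_map = dict(material_map)
        self.metadata: dict = dict(metadata or {})
        self.scene: Scene | None = None

    # ---- construction --------------------------------------------------

    @classmethod
    def empty(
        cls,
        shape: Sequence[int],
        spacing: float,
        origin: Sequence[float],
        background: str = "open",
        background_material: str | None = None,
    ) -> "LabeledVoxelGrid":
        labels = np.zeros(tuple(shape), dtype=np.uint8)
        return cls(labels, spacing, origin, [background], {background: background_material})

    # ---- label bookkeeping ---------------------------------------------

    def ensure_label(self, name: str, material: str | None = None) -> int:
        if name in self.label_names:
            lid = self.label_names.index(name)
            if material is not None:
                self.material_map[name] = material
            return lid
        if len(self.label_names) >= 255:
            raise ValueError("too many labels for uint8 storage")
        self.label_names.append(name)
        self.material_map[name] = material
        return len(self.label_names) - 1

    def label_id(self, name: str) -> int:
        try:
            return self.label_names.index(name)
        except ValueError:
            raise KeyError(f"no label {name!r}; present: {self.label_names}") from None

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of cells carrying any of the given labels."""
        out = np.zeros(self.shape, dtype=bool)
        for name in names:
            if name in self.label_names:
                out |= self.labels == self.label_id(name)
        return out

    def count(self, name: str) -> int:
        if name not in self.label_names:
            return 0
        return int(np.count_nonzero(self.labels == self.label_id(name)))

    def material_of_id(self, lid: int) -> str | None:
        return self.material_map.get(self.label_names[lid])

    # ---- geometry ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def cell_volume(self) -> float:
        return self.spacing**3

    def cell_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.origin.copy()
        hi = self.origin + np.asarray(self.shape) * self.spacing
        return lo, hi

    def box_mask(self, lo: Sequence[float], hi: Sequence[float]) -> np.ndarray:
        """Cells whose centers lie in the closed world-coordinate box."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        axes = [self.cell_centers(a) for a in range(3)]
        m = (
            (axes[0] >= lo[0]) & (axes[0] <= hi[0])
        )[:, None, None] & (
            (axes[1] >= lo[1]) & (axes[1] <= hi[1])
        )[None, :, None] & (
            (axes[2] >= lo[2]) & (axes[2] <= hi[2])
        )[None, None, :]
        return np.broadcast_to(m, self.shape).copy()

    def crop(self, lo: Sequence[float], hi: Sequence[float]) -> "LabeledVoxelGrid":
        """Sub-grid of cells whose centers fall inside the world box."""
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        sl = []
        for a in range(3):
            c = self.cell_centers(a)
            idx = np.nonzero((c >= lo[a]) & (c <= hi[a]))[0]
            if idx.size == 0:
                raise ValueError("crop: empty selection on axis %d" % a)
            sl.append(slice(idx[0], idx[-1] + 1))
        sub = LabeledVoxelGrid(
            self.labels[tuple(sl)].copy(),
            self.spacing,
            self.origin + np.array([s.start for s in sl]) * self.spacing,
            self.label_names,
            self.material_map,
            metadata=dict(self.metadata),
        )
        sub.scene = self.scene
        return sub

    def volume_fraction(self, *names: str) -> float:
        return float(np.count_nonzero(self.mask(*names))) / self.labels.size

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"LabeledVoxelGrid(shape={self.shape}, spacing={self.spacing:g} m, "
            f"labels={self.label_names})"
        )
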