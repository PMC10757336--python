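"""Region-of-interest dose statistics against osteogenic stimulation windows.

The dose a cultured cell population receives is summarized over the ROI —
the axis-aligned envelope box of the culture scaffold — as volume-weighted
distributions of wall shear stress tau (Pa) and electric field magnitude
|E| (V/m), normalized to their peak (the convention of the reference
histograms), together with in-window volume fractions against literature
osteoinductive ranges:

* tau in [1.47, 24] mPa and [0.20, 13.35] mPa (two published ranges);
* |E| in [1e-5, 1.3e3] V/m.

Statistics run over *fluid* (medium) cells only by default: the solid
scaffold struts are not culture medium.  ``include_solids`` exists for
sensitivity studies with solvers that resolve intrascaffold fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ScaffoldSpec, scaffold_envelope_box
from .grid import LabeledVoxelGrid

__all__ = [
    "ROIHistogram",
    "MicroenvironmentTarget",
    "SHEAR_WINDOWS_PA",
    "FIELD_WINDOW_V_PER_M",
    "extract_roi",
    "histogram",
    "score_against_target",
    "rescale_histogram",
]

#: Literature osteoinductive wall-shear windows, Pa.
SHEAR_WINDOWS_PA = ((1.47e-3, 24e-3), (0.20e-3, 13.35e-3))
#: Literature osteogenic field-magnitude window, V/m.
FIELD_WINDOW_V_PER_M = (1.0e-5, 1.3e3)


@dataclass
class ROIHistogram:
    """Volume-weighted distribution of a scalar dose field over the ROI."""

    edges: np.ndarray  # bin edges, field units
    volume: np.ndarray  # m^3 per bin
    normalized: np.ndarray  # volume / max(volume); peak = 1
    roi_volume: float  # total fluid volume histogrammed, m^3
    mean: float
    max: float
    units: str = ""
    values: np.ndarray | None = None  # flat cell values (for fractions)
    cell_volume: float = 0.0

    def in_window_fraction(self, lo: float, hi: float) -> float:
        """Fraction of ROI fluid volume with lo <= value <= hi."""
        if not lo < hi:
            raise ValueError("window must satisfy lo < hi")
        if self.values is None:
            raise ValueError("histogram was built without raw values")
        return float(np.mean((self.values >= lo) & (self.values <= hi)))


@dataclass(frozen=True)
class MicroenvironmentTarget:
    """Stimulation windows a candidate design should cover.

    ``required_fraction`` is the ROI volume fraction that must fall inside a
    window for the design to pass.
    """

    shear_windows: tuple = SHEAR_WINDOWS_PA  # Pa
    field_window: tuple = FIELD_WINDOW_V_PER_M  # V/m
    required_fraction: float = 0.5

    def __post_init__(self) -> None:
        for lo, hi in [*self.shear_windows, self.field_window]:
            if not lo < hi:
                raise ValueError(f"window [{lo}, {hi}] must have lo < hi")
        if not 0 < self.required_fraction <= 1:
            raise ValueError("required_fraction must be in (0, 1]")


def extract_roi(
    grid: LabeledVoxelGrid,
    scaffold_spec: ScaffoldSpec | None = None,
) -> np.ndarray:
    """Cell mask of the scaffold envelope box (the ROI).

    Uses the envelope recorded at assembly time when available, else the
    box of the given spec in the grid's scaffold orientation.  Raises if the
    grid contains no scaffold cells.
    """
    if grid.count("scaffold") == 0:
        raise ValueError("grid contains no scaffold cells; no ROI to extract")
    box = grid.metadata.get("scaffold_box")
    if box is None:
        if scaffold_spec is None:
            raise ValueError("no scaffold box in metadata and no spec given")
        orientation = grid.metadata.get("scaffold_orientation", "flat")
        lo, hi = scaffold_envelope_box(scaffold_spec, orientation=orientation)
        box = (tuple(lo), tuple(hi))
    return grid.box_mask(*box)


def histogram(
    field_values: np.ndarray,
    grid: LabeledVoxelGrid,
    roi_mask: np.ndarray,
    bins: np.ndarray | int | None = None,
    units: str = "",
    include_solids: bool = False,
    fluid_label: str = "medium",
) -> ROIHistogram:
    """Volume-weighted ROI histogram of a cell scalar field.

    ``bins`` may be explicit edges, a bin count (default 100 between 0 and
    the ROI max — 1/100 of the maximum is the default bin width), or None.
    NaN cells (outside the solved domain) are excluded.
    """
    if field_values.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    sel = roi_mask.copy()
    if not include_solids:
        sel &= grid.mask(fluid_label)
    vals = field_values[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no fluid cells with finite field values in ROI")
    vmax = float(vals.max())
    if bins is None:
        bins = 100
    if np.isscalar(bins):
        edges = np.linspace(0.0, vmax if vmax > 0 else 1.0, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    counts, edges = np.histogram(vals, bins=edges)
    vol = counts * grid.cell_volume
    peak = vol.max()
    normalized = vol / peak if peak > 0 else vol
    return ROIHistogram(
        edges=edges,
        volume=vol,
        normalized=normalized,
        roi_volume=float(vals.size * grid.cell_volume),
        mean=float(vals.mean()),
        max=vmax,
        units=units,
        values=vals,
        cell_volume=grid.cell_volume,
    )


def score_against_target(
    hist: ROIHistogram,
    target: MicroenvironmentTarget,
    kind: str,
) -> dict:
    """In-window volume fractions and pass/fail for one dose field.

    ``kind`` is ``"shear"`` (tau histogram, Pa) or ``"field"`` (|E|
    histogram, V/m); mixing them up is a unit error and rejected using the
    units recorded on the histogram.
    """
    expected_units = {"shear": "Pa", "field": "V/m"}
    if kind not in expected_units:
        raise ValueError("kind must be 'shear' or 'field'")
    if hist.units and hist.units != expected_units[kind]:
        raise ValueError(
            f"unit mismatch: histogram carries {hist.units!r}, "
            f"scoring expects {expected_units[kind]!r}"
        )
    windows = target.shear_windows if kind == "shear" else (target.field_window,)
    fractions = [hist.in_window_fraction(lo, hi) for lo, hi in windows]
    best = max(fractions)
    return {
        "windows": [list(w) for w in windows],
        "fractions": fractions,
        "best_fraction": best,
        "passed": best >= target.required_fraction,
    }


def rescale_histogram(hist: ROIHistogram, factor: float) -> ROIHistogram:
    """Histogram of the dose field scaled by ``factor`` without re-solving.

    Valid because both governing problems (Stokes flow, quasistatic
    conduction) are linear in their drive: scaling the pump rate or the
    electrode amplitude scales every field value by the same factor.
    Equivalent to re-binning a fresh solve at the scaled protocol.
    """
    if factor < 0:
        raise ValueError("scale factor must be >= 0")
    return ROIHistogram(
        edges=hist.edges * factor,
        volume=hist.volume.copy(),
        normalized=hist.normalized.copy(),
        roi_volume=hist.roi_volume,
        mean=hist.mean * factor,
        max=hist.max * factor,
        units=hist.units,
        values=None if hist.values is None else hist.values * factor,
        cell_volume=hist.cell_volume,
    )
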