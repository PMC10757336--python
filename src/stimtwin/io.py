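"""File formats, run configuration and reporting.

Conventions: STL for surfaces, legacy-ASCII VTK structured points for voxel
fields (readable by ParaView/VisIt; a matching reader is provided for
round-trips), CSV for histograms, JSON for reports, YAML for run
configuration.  Files are SI throughout; the config accepts ``mm``/``um``
suffixed keys for convenience.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grid import LabeledVoxelGrid

__all__ = [
    "RunConfig",
    "write_vtk",
    "read_vtk",
    "write_histogram_csv",
    "read_histogram_csv",
    "write_report",
    "export_stl",
]


_UNIT_SUFFIXES = {"_mm": 1e-3, "_um": 1e-6}


def _normalize_units(d: dict) -> dict:
    """Resolve mm/um-suffixed keys to SI base keys."""
    out = {}
    for k, v in d.items():
        if isinstance(v, dict):
            out[k] = _normalize_units(v)
            continue
        for suf, scale in _UNIT_SUFFIXES.items():
            if k.endswith(suf):
                out[k[: -len(suf)]] = (
                    [x * scale for x in v] if isinstance(v, (list, tuple)) else v * scale
                )
                break
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Serializable description of one pipeline run.

    A saved config reproduces a run bit-identically for the deterministic
    stages (geometry, solves, analysis); ``seed`` covers the synthetic
    recording generators.
    """

    scaffold: dict = field(default_factory=dict)
    holder: str = "horizontal"
    electrodes: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    materials: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**_normalize_units(raw))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# VTK structured points (legacy ASCII), cell data
# ---------------------------------------------------------------------------


def write_vtk(path, grid: LabeledVoxelGrid, fields: dict[str, np.ndarray],
              units: dict[str, str] | None = None) -> None:
    """Write cell-centered scalar fields on a voxel grid as legacy VTK.

    Complex fields are written as magnitude.  Units are recorded in the
    header comment line (the legacy format's metadata slot).
    """
    units = units or {}
    for name, arr in fields.items():
        if arr.shape != grid.shape:
            raise ValueError(f"field {name!r} shape {arr.shape} != grid {grid.shape}")
    nx, ny, nz = grid.shape
    unit_note = ",".join(f"{k}[{v}]" for k, v in units.items()) or "SI units"
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"stimtwin fields; {unit_note}; spacing m\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write("ORIGIN %.12g %.12g %.12g\n" % tuple(grid.origin))
        fh.write("SPACING %.12g %.12g %.12g\n" % ((grid.spacing,) * 3))
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            if np.iscomplexobj(arr):
                arr = np.abs(arr)
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK orders x fastest
            flat = np.asarray(arr, dtype=float).transpose(2, 1, 0).ravel()
            np.savetxt(fh, flat.reshape(-1, 1), fmt="%.17g")


def read_vtk(path) -> tuple[dict, dict[str, np.ndarray]]:
    """Read a file written by :func:`write_vtk`.

    Returns (metadata, fields) where metadata holds shape, spacing, origin.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta: dict = {}
    fields: dict[str, np.ndarray] = {}
    i = 0
    shape = None
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        key = parts[0]
        if key == "DIMENSIONS":
            shape = tuple(int(p) - 1 for p in parts[1:4])
            meta["shape"] = shape
        elif key == "ORIGIN":
            meta["origin"] = np.array([float(p) for p in parts[1:4]])
        elif key == "SPACING":
            meta["spacing"] = float(parts[1])
        elif key == "SCALARS":
            name = parts[1]
            n = shape[0] * shape[1] * shape[2]
            data = np.loadtxt(lines[i + 2 : i + 2 + n])
            fields[name] = data.reshape(shape[2], shape[1], shape[0]).transpose(2, 1, 0)
            i += 1 + n
        i += 1
    return meta, fields


# ---------------------------------------------------------------------------
# histograms and reports
# ---------------------------------------------------------------------------


def write_histogram_csv(path, hist) -> None:
    df = pd.DataFrame(
        {
            "bin_lo": hist.edges[:-1],
            "bin_hi": hist.edges[1:],
            "volume_m3": hist.volume,
            "normalized": hist.normalized,
        }
    )
    df.to_csv(path, index=False)


def read_histogram_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _hist_summary(hist) -> dict:
    return {
        "mean": hist.mean,
        "max": hist.max,
        "roi_volume_m3": hist.roi_volume,
        "units": hist.units,
        "n_bins": int(len(hist.volume)),
    }


def write_report(design_report, out_dir) -> Path:
    """JSON report + per-hypothesis CSV histograms for a design-loop run.

    The report contains every number needed to regenerate dose-distribution
    plots: windows, fractions, means, selections and pointers to the CSVs.
    Raises if the report is incomplete (a hypothesis without histograms).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, r in enumerate(design_report.results):
        if r.tau_hist is None or r.e_hist is None:
            raise ValueError(f"incomplete report: hypothesis {i} lacks histograms")
        name = r.hypothesis.name.replace("+", "_")
        tau_csv = out / f"hist_tau_{name}.csv"
        e_csv = out / f"hist_e_{name}.csv"
        write_histogram_csv(tau_csv, r.tau_hist)
        write_histogram_csv(e_csv, r.e_hist)
        entries.append(
            {
                "name": r.hypothesis.name,
                "holder": r.hypothesis.holder,
                "scaffold_kind": r.hypothesis.scaffold.kind,
                "protocol": {
                    "q_m3_per_s": r.hypothesis.protocol.q,
                    "v_amp_V": r.hypothesis.protocol.v_amp,
                    "f_Hz": r.hypothesis.protocol.f,
                },
                "tau": _hist_summary(r.tau_hist),
                "e": _hist_summary(r.e_hist),
                "shear_score": r.shear_score,
                "field_score": r.field_score,
                "best_scale": r.best_scale,
                "best_scaled_fraction": r.best_scaled_fraction,
                "passed": r.passed,
                "tau_csv": tau_csv.name,
                "e_csv": e_csv.name,
            }
        )
    payload = {
        "hypotheses": entries,
        "selected": design_report.selected,
        "rationale": design_report.rationale,
        "target": {
            "shear_windows_Pa": [list(w) for w in design_report.target.shear_windows],
            "field_window_V_per_m": list(design_report.target.field_window),
            "required_fraction": design_report.target.required_fraction,
        },
    }
    report_path = out / "design_report.json"
    with open(report_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return report_path


def export_stl(path, grid: LabeledVoxelGrid, label: str = "scaffold") -> None:
    """Export the surface of one label as STL (marching cubes + trimesh)."""
    from skimage import measure
    import trimesh

    mask = grid.mask(label)
    if not mask.any():
        raise ValueError(f"no cells with label {label!r}")
    vol = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(vol, level=0.5)
    verts = (verts - 1 + 0.5) * grid.spacing + grid.origin  # cell centers
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.export(path)
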