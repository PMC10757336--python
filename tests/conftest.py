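"""Shared fixtures.

The chamber-scale solves are expensive, so every result consumed by more
than one test (the four scaffold/holder flow solves, the electric-field
solves) is computed once per session and cached.
"""

from __future__ import annotations

import numpy as np
import pytest

from stimtwin.flow import shear_stress
from stimtwin.geometry import honeycomb_scaffold, orthogonal_scaffold
from stimtwin.materials import default_registry
from stimtwin.submodel import solve_em_chamber, solve_flow_chamber

# resolutions used for chamber-scale checks: coarse global grid /
# scaffold-resolving submodel grid (meters)
FLOW_RES = (500e-6, 150e-6)
EM_RES = (400e-6, 100e-6)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def _flow_case(kind: str, holder: str):
    spec = orthogonal_scaffold() if kind == "orthogonal" else honeycomb_scaffold()
    res = solve_flow_chamber(spec, holder, coarse_h=FLOW_RES[0], fine_h=FLOW_RES[1])
    tau = shear_stress(res.fine)
    med = res.fine.grid.mask("medium")
    vals = tau[res.roi_mask & med]
    return {
        "tau_values": vals[np.isfinite(vals)],
        "info": dict(res.fine.info),
    }


@pytest.fixture(scope="session")
def chamber_flow_results():
    """Shear-stress ROI samples for all four scaffold x holder combinations."""
    out = {}
    for kind in ("orthogonal", "honeycomb"):
        for holder in ("horizontal", "vertical"):
            out[f"{holder}+{kind}"] = _flow_case(kind, holder)
    return out


def _em_case(kind: str, holder: str, coarse_h: float, fine_h: float):
    spec = orthogonal_scaffold() if kind == "orthogonal" else honeycomb_scaffold()
    res = solve_em_chamber(spec, holder, coarse_h=coarse_h, fine_h=fine_h)
    med = res.fine.grid.mask("medium")
    vals = res.fine.e_mag[res.roi_mask & med]
    return {
        "e_values": vals[np.isfinite(vals)],
        "i_active": res.coarse.i_active,
        "i_ground": res.coarse.i_ground,
    }


@pytest.fixture(scope="session")
def chamber_em_results():
    """ROI |E| samples for the two scaffolds on the horizontal holder."""
    return {
        f"horizontal+{kind}": _em_case(kind, "horizontal", *EM_RES)
        for kind in ("orthogonal", "honeycomb")
    }


@pytest.fixture(scope="session")
def chamber_em_reference():
    """The scaled-down reference solve for the printed ROI-average field."""
    return _em_case("orthogonal", "horizontal", 300e-6, 100e-6)
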