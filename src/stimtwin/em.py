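"""Quasistatic frequency-domain electric-field solver.

Capacitively-coupled stimulation is modeled by current conservation with
complex admittivity, ``div(sigma*(x) grad V) = 0`` with
``sigma* = sigma + i 2 pi f eps0 eps_r``, driven by Dirichlet potentials on
the two electrode conductors.  This is the quasistatic phasor regime
(chamber much smaller than the wavelength; induction neglected).

Discretization: cell-centered finite volumes on the labeled voxel grid with
harmonic-mean face admittances.  The thin PET film of the electrodes
(175 um, far below chamber-scale voxels) is lumped as a face (contact)
impedance ``Z = d / sigma*_PET`` on the electrode surface by default;
resolving it explicitly is supported for fine grids and cross-checked
against the 1D layered oracle.

Cells whose admittivity magnitude is negligible next to the medium
(insulating scaffold, printed parts) are excluded from the unknown set and
treated as internal no-flux boundaries unless ``resolve_insulators`` is set
(small grids only; also yields the field inside the solids).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse import linalg as spla

from ._numerics import dct_poisson_solve, neumann_laplacian_eigs
from .grid import LabeledVoxelGrid
from .materials import (
    MaterialRegistry,
    MaterialSpec,
    complex_conductivity,
    default_registry,
)

__all__ = [
    "EMBC",
    "EMSolution",
    "solve_em",
    "layered_1d_oracle",
    "LayeredOracleResult",
    "apply_series_resistor",
    "field_from_measured_current",
]


@dataclass(frozen=True)
class EMBC:
    """Electrode drive: potential amplitude (V) and frequency (Hz).

    ``v_amp`` is the zero-to-peak amplitude at the active electrode (5 V for
    a 10 V peak-to-peak sine); the other electrode is ground.
    """

    v_amp: float
    f: float

    def __post_init__(self) -> None:
        if self.v_amp < 0:
            raise ValueError("v_amp must be >= 0 (real amplitude)")
        if self.f < 0:
            raise ValueError("frequency must be >= 0")


@dataclass
class EMSolution:
    """Solved complex potential and derived fields on the grid.

    ``potential`` is NaN outside the solved domain; ``e_field`` holds three
    complex cell-centered components and ``e_mag`` the phasor magnitude
    sqrt(|Ex|^2 + |Ey|^2 + |Ez|^2), V/m.  Terminal currents are surface
    integrals of J.n over each electrode (A, complex); for a series pair
    they agree in magnitude.
    """

    grid: LabeledVoxelGrid
    bc: EMBC
    potential: np.ndarray
    e_field: tuple[np.ndarray, np.ndarray, np.ndarray]
    e_mag: np.ndarray
    domain_mask: np.ndarray
    i_active: complex
    i_ground: complex
    info: dict = field(default_factory=dict)

    def scaled(self, factor: complex) -> "EMSolution":
        """Linearly rescaled copy (the quasistatic model is linear in V)."""
        return EMSolution(
            grid=self.grid,
            bc=self.bc,
            potential=self.potential * factor,
            e_field=tuple(c * factor for c in self.e_field),  # type: ignore[arg-type]
            e_mag=self.e_mag * abs(factor),
            domain_mask=self.domain_mask,
            i_active=self.i_active * factor,
            i_ground=self.i_ground * factor,
            info=dict(self.info),
        )


_ACTIVE = "electrode_active"
_GROUND = "electrode_ground"


def _cell_admittivity(grid, registry, f):
    """Per-cell sigma* and mask of cells mapped to any material."""
    n_labels = len(grid.label_names)
    sig_by_label = np.zeros(n_labels, dtype=complex)
    has_mat = np.zeros(n_labels, dtype=bool)
    for lid, name in enumerate(grid.label_names):
        mat_name = grid.material_map.get(name)
        if mat_name is None:
            continue
        has_mat[lid] = True
        sig_by_label[lid] = complex_conductivity(registry[mat_name], f)
    return sig_by_label[grid.labels], has_mat[grid.labels]


def _axis_slices(ax):
    sl1 = [slice(None)] * 3
    sl2 = [slice(None)] * 3
    sl1[ax] = slice(None, -1)
    sl2[ax] = slice(1, None)
    return tuple(sl1), tuple(sl2)


def solve_em(
    grid: LabeledVoxelGrid,
    bc: EMBC,
    registry: MaterialRegistry | None = None,
    *,
    resolve_insulators: bool = False,
    exclude_ratio: float = 1e-3,
    method: str = "auto",
    tol: float = 1e-8,
    direct_limit: int = 30_000,
    maxiter: int = 6000,
    dirichlet_boundary: np.ndarray | None = None,
) -> EMSolution:
    """Solve the quasistatic current-conservation problem on a labeled grid.

    Electrode conductors (labels ``electrode_active`` / ``electrode_ground``)
    are imposed as equipotential Dirichlet regions at ``bc.v_amp`` and 0 V —
    justified by the >= 12 orders of magnitude conductivity contrast of ITO
    over everything else.  Alternatively a complex ``dirichlet_boundary``
    array (grid shape, NaN = free) fixes potentials on the outermost cell
    layer; that is how fine submodel solves inherit a coarse parent
    solution.

    ``method`` is ``direct`` (sparse LU), ``iterative`` (LGMRES with an FFT
    Poisson preconditioner) or ``auto``.
    """
    registry = registry or default_registry()
    h = grid.spacing
    sig, has_mat = _cell_admittivity(grid, registry, bc.f)

    active = grid.mask(_ACTIVE)
    ground = grid.mask(_GROUND)
    if dirichlet_boundary is None and (not active.any() or not ground.any()):
        raise ValueError("both electrode conductor regions must be present")

    for ax in range(3):
        sl1, sl2 = _axis_slices(ax)
        if (active[sl1] & ground[sl2]).any() or (ground[sl1] & active[sl2]).any():
            raise ValueError("electrodes touch: short-circuit geometry")

    electrode = active | ground
    candidate = has_mat & ~electrode
    if resolve_insulators:
        domain = candidate.copy()
    else:
        ref = np.abs(sig[candidate]).max() if candidate.any() else 0.0
        domain = candidate & (np.abs(sig) >= exclude_ratio * ref)
    if not domain.any():
        raise ValueError("no conducting cells to solve on")

    dir_mask = electrode.copy()
    dir_val = np.zeros(grid.shape, dtype=complex)
    dir_val[active] = bc.v_amp
    if dirichlet_boundary is not None:
        shell = np.zeros(grid.shape, dtype=bool)
        shell[[0, -1], :, :] = True
        shell[:, [0, -1], :] = True
        shell[:, :, [0, -1]] = True
        fixed = shell & domain & ~np.isnan(dirichlet_boundary.real)
        dir_mask |= fixed
        dir_val[fixed] = dirichlet_boundary[fixed]
        domain &= ~fixed

    # conducting pockets with no path to a Dirichlet surface float at an
    # undetermined potential (singular Neumann blocks); exclude them.
    from scipy import ndimage

    comp, n_comp = ndimage.label(domain)
    if n_comp > 1:
        near_dir = ndimage.binary_dilation(dir_mask)
        driven = np.zeros(n_comp + 1, dtype=bool)
        driven[np.unique(comp[domain & near_dir])] = True
        driven[0] = False
        domain &= driven[comp]
        if not domain.any():
            raise ValueError("no conducting region is coupled to an electrode")

    idx = -np.ones(grid.shape, dtype=np.int64)
    n = int(domain.sum())
    idx[domain] = np.arange(n)

    pet = grid.metadata.get("pet_face_impedance")
    z_pet = 0.0 + 0.0j
    if pet is not None and pet.get("thickness", 0) > 0:
        sig_pet = complex_conductivity(registry[pet["material"]], bc.f)
        z_pet = pet["thickness"] / sig_pet  # ohm m^2, per unit area

    rows, cols, vals = [], [], []
    diag = np.zeros(n, dtype=complex)
    rhs = np.zeros(n, dtype=complex)
    # per-unknown coupling to each electrode for terminal-current integrals
    g_act = np.zeros(n, dtype=complex)
    g_gnd = np.zeros(n, dtype=complex)
    g_dir_total = 0.0
    participates = domain | dir_mask
    face_g = []  # per-axis face conductances, reused for the E field
    face_active = []  # per-axis masks of faces that carry current

    for ax in range(3):
        sl1, sl2 = _axis_slices(ax)
        p1, p2 = participates[sl1], participates[sl2]
        s1, s2 = sig[sl1], sig[sl2]
        d1, d2 = dir_mask[sl1], dir_mask[sl2]
        face_ok = p1 & p2 & ~(d1 & d2)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = h * 2.0 * s1 * s2 / (s1 + s2)
        g = np.where(face_ok & np.isfinite(g), g, 0.0)
        el1, el2 = electrode[sl1], electrode[sl2]
        lump = face_ok & (el1 ^ el2)
        if z_pet != 0 and lump.any():
            s_free = np.where(el1, s2, s1)
            with np.errstate(divide="ignore", invalid="ignore"):
                g_l = (h * h) / (z_pet + h / (2.0 * s_free))
            g = np.where(lump, g_l, g)
        face_g.append(g)
        face_active.append(face_ok)

        i1, i2 = idx[sl1], idx[sl2]
        both = face_ok & ~d1 & ~d2
        if both.any():
            a, b, gv = i1[both], i2[both], g[both]
            rows.extend((a, b))
            cols.extend((b, a))
            vals.extend((-gv, -gv))
            np.add.at(diag, a, gv)
            np.add.at(diag, b, gv)

        for dm, io, vd_side, act_side, gnd_side in (
            (face_ok & d1 & ~d2, i2, dir_val[sl1], active[sl1], ground[sl1]),
            (face_ok & d2 & ~d1, i1, dir_val[sl2], active[sl2], ground[sl2]),
        ):
            if not dm.any():
                continue
            iu, gv, vd = io[dm], g[dm], vd_side[dm]
            np.add.at(diag, iu, gv)
            np.add.at(rhs, iu, gv * vd)
            g_dir_total += float(np.abs(gv).sum())
            am, gm = act_side[dm], gnd_side[dm]
            if am.any():
                np.add.at(g_act, iu[am], gv[am])
            if gm.any():
                np.add.at(g_gnd, iu[gm], gv[gm])

    # isolated cells (no conducting neighbor): pin to 0 V
    iso = np.abs(diag) == 0
    if iso.any():
        diag[iso] = 1.0
        rhs[iso] = 0.0
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    del rows, cols, vals

    if method == "auto":
        method = "direct" if n <= direct_limit else "iterative"
    info: dict = {"n_unknowns": n, "method": method}

    if method == "direct":
        v = spla.spsolve(A.tocsc(), rhs)
        info["residual"] = float(np.linalg.norm(A @ v - rhs) / max(np.linalg.norm(rhs), 1e-300))
    elif method == "iterative":
        lam = neumann_laplacian_eigs(grid.shape)
        sigma_scale = float(np.median(np.abs(sig[domain])))
        shift_hat = max(g_dir_total / max(n, 1), 1e-30) / (sigma_scale * h)
        scale = sigma_scale * h

        def precond(r):
            z = np.zeros(grid.shape, dtype=complex)
            z[domain] = r
            z = dct_poisson_solve(z, lam, shift_hat) / scale
            return z[domain]

        M = spla.LinearOperator((n, n), matvec=precond, dtype=complex)
        nb = np.linalg.norm(rhs)
        v, code = spla.lgmres(A, rhs, M=M, rtol=tol, atol=tol * nb, maxiter=maxiter)
        res = float(np.linalg.norm(A @ v - rhs) / max(nb, 1e-300))
        info["residual"] = res
        if code != 0 or res > 100 * tol:
            raise RuntimeError(
                f"EM iterative solve did not converge (code={code}, residual={res:.2e})"
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    V = np.full(grid.shape, np.nan + 0j, dtype=complex)
    V[domain] = v
    V[dir_mask] = dir_val[dir_mask]

    # Face currents J = -g dV / h^2, averaged to cell centers and divided by
    # the local admittivity: E = J / sigma*.  This keeps the reported field
    # consistent across lumped-PET electrode faces (where -dV/h would smear
    # the film drop over a whole voxel) and across material interfaces.
    e_field = []
    for ax in range(3):
        sl1, sl2 = _axis_slices(ax)
        shp = list(grid.shape)
        shp[ax] -= 1
        face_j = np.zeros(tuple(shp), dtype=complex)
        ok = face_active[ax]
        dv = V[sl2] - V[sl1]
        face_j[ok] = -face_g[ax][ok] * dv[ok] / (h * h)
        comp = np.zeros(grid.shape, dtype=complex)
        cnt = np.zeros(grid.shape)
        comp[sl1] += face_j
        cnt[sl1] += ok
        comp[sl2] += face_j
        cnt[sl2] += ok
        with np.errstate(divide="ignore", invalid="ignore"):
            comp = comp / np.maximum(cnt, 1) / sig
        comp[~(domain | dir_mask)] = 0.0
        comp[~np.isfinite(comp)] = 0.0
        e_field.append(comp)

    e_mag = np.sqrt(sum(np.abs(c) ** 2 for c in e_field))
    e_mag[~domain] = np.nan

    i_active = complex(np.sum(g_act * (bc.v_amp - v)))
    i_ground = complex(np.sum(g_gnd * (v - 0.0)))
    info["current_mismatch"] = (
        abs(abs(i_active) - abs(i_ground)) / abs(i_active) if i_active != 0 else 0.0
    )

    return EMSolution(
        grid=grid,
        bc=bc,
        potential=V,
        e_field=tuple(e_field),  # type: ignore[arg-type]
        e_mag=e_mag,
        domain_mask=domain,
        i_active=i_active,
        i_ground=i_ground,
        info=info,
    )


# ---------------------------------------------------------------------------
# 1D layered oracle and lumped-circuit arithmetic
# ---------------------------------------------------------------------------


@dataclass
class LayeredOracleResult:
    """Per-layer complex fields of the 1D series (plate-capacitor) model."""

    layers: list[tuple[float, MaterialSpec]]
    e_layers: list[complex]  # V/m, complex amplitude per layer
    z_total: complex  # ohm m^2 (area-normalized series impedance)
    j: complex  # A/m^2 through the stack

    def e_mag(self, index: int) -> float:
        return abs(self.e_layers[index])

    def e_in(self, material_name: str) -> float:
        """|E| in the first layer made of the named material."""
        for (d, mat), e in zip(self.layers, self.e_layers):
            if mat.name == material_name:
                return abs(e)
        raise KeyError(f"no layer of material {material_name!r}")


def layered_1d_oracle(
    layers: Sequence[tuple[float, MaterialSpec]],
    v_amp: float,
    f: float,
) -> LayeredOracleResult:
    """Series layered-media solution for parallel-plate geometry.

    Each layer contributes an area-normalized impedance
    ``Z_k = d_k / sigma*_k``; the common current density is
    ``J = V / sum(Z)`` and the field in layer k is ``E_k = J / sigma*_k`` —
    independent of plate area by construction.  Zero-thickness layers are
    dropped with a warning.
    """
    kept = []
    for d, mat in layers:
        if d < 0:
            raise ValueError("layer thickness must be >= 0")
        if d == 0:
            warnings.warn(f"dropping zero-thickness layer {mat.name!r}", stacklevel=2)
            continue
        kept.append((float(d), mat))
    if not kept:
        raise ValueError("need at least one layer of positive thickness")
    z = [d / complex_conductivity(mat, f) for d, mat in kept]
    z_total = sum(z)
    j = v_amp / z_total
    e_layers = [j / complex_conductivity(mat, f) for _, mat in kept]
    return LayeredOracleResult(layers=kept, e_layers=e_layers, z_total=z_total, j=j)


def apply_series_resistor(
    v_amp: float,
    i_base: complex,
    r_s: float,
) -> tuple[float, float]:
    """Correct a predicted terminal current for a series measurement resistor.

    The un-modeled setup impedance is inferred as ``Z = v_amp / i_base``;
    when ``i_base`` is given as a plain magnitude its phase is taken as
    purely reactive (capacitive), which is the regime of a PET-blocked
    electrode pair.  Returns ``(|I|, field_scale)`` where all solved fields
    scale by ``field_scale = |I| / |i_base|`` (linearity).
    """
    if r_s < 0:
        raise ValueError("series resistance must be >= 0")
    if not (abs(i_base) > 0):
        raise ValueError("i_base must be nonzero")
    if isinstance(i_base, complex) and i_base.imag != 0:
        z = v_amp / i_base
    else:
        z = -1j * v_amp / abs(i_base)  # purely reactive
    i_new = v_amp / abs(z + r_s)
    return i_new, i_new / abs(i_base)


def field_from_measured_current(e_pred: float, i_pred: float, i_meas: float) -> float:
    """Rescale a predicted field to a measured terminal current (linearity)."""
    if not (i_pred > 0):
        raise ValueError("i_pred must be > 0")
    return e_pred * i_meas / i_pred
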