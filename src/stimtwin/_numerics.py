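"""Shared numerical kernels: FFT Poisson preconditioners and interpolation.

Both solvers discretize on regular voxel grids, so uniform-coefficient
Laplacians on the bounding box diagonalize in cosine (Neumann) or sine
(Dirichlet) bases.  These exact inverses of the *uniform* operator serve as
preconditioners for the variable-coefficient / perforated systems, which
keeps Krylov iteration counts nearly resolution-independent.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

__all__ = [
    "neumann_laplacian_eigs",
    "dct_poisson_solve",
    "dst_poisson_solve",
    "trilinear_sampler",
    "fill_nan_by_diffusion",
]


def neumann_laplacian_eigs(shape: tuple[int, ...]) -> np.ndarray:
    """Eigenvalues of the unit-coefficient 7-point Neumann Laplacian.

    Returned with shape ``shape`` in DCT-II ordering; entries are
    ``sum_a 2 - 2 cos(pi m_a / n_a)`` (non-negative, first entry 0).
    """
    lam = np.zeros(shape)
    for a, n in enumerate(shape):
        k = 2.0 - 2.0 * np.cos(np.pi * np.arange(n) / n)
        sh = [1] * len(shape)
        sh[a] = n
        lam = lam + k.reshape(sh)
    return lam


def dct_poisson_solve(rhs: np.ndarray, lam: np.ndarray, shift: float) -> np.ndarray:
    """Solve (L_neumann + shift I) x = rhs for the uniform unit Laplacian.

    ``lam`` must come from :func:`neumann_laplacian_eigs` for ``rhs.shape``.
    Works for real or complex ``rhs`` (complex handled per part).
    """
    if np.iscomplexobj(rhs):
        return (dct_poisson_solve(rhs.real, lam, shift)
                + 1j * dct_poisson_solve(rhs.imag, lam, shift))
    x = sfft.dctn(rhs, type=2, norm="ortho")
    x /= lam + shift
    return sfft.idctn(x, type=2, norm="ortho")


def dirichlet_laplacian_eigs(shape: tuple[int, ...]) -> np.ndarray:
    """Eigenvalues of the unit 7-point Laplacian with zero-Dirichlet layer.

    Matches a cell-centered grid whose outermost cells are held fixed: the
    interior operator has sine eigenvectors (DST-I) with eigenvalues
    ``sum_a 2 - 2 cos(pi m_a / (n_a + 1))``, m_a = 1..n_a.
    """
    lam = np.zeros(shape)
    for a, n in enumerate(shape):
        k = 2.0 - 2.0 * np.cos(np.pi * np.arange(1, n + 1) / (n + 1))
        sh = [1] * len(shape)
        sh[a] = n
        lam = lam + k.reshape(sh)
    return lam


def dst_poisson_solve(rhs: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Solve L_dirichlet x = rhs via DST-I (unit coefficient)."""
    if np.iscomplexobj(rhs):
        return (dst_poisson_solve(rhs.real, lam)
                + 1j * dst_poisson_solve(rhs.imag, lam))
    x = sfft.dstn(rhs, type=1, norm="ortho")
    x /= lam
    return sfft.idstn(x, type=1, norm="ortho")


def trilinear_sampler(
    axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    values: np.ndarray,
):
    """Trilinear interpolant of a 3D field sampled on a tensor grid.

    ``axes`` are the (strictly increasing) sample coordinates per axis.
    Evaluation clamps to the grid (constant extrapolation), which is the
    right behavior when sampling a coarse parent solution near its edge.
    Returns a callable f(points[n, 3]) -> values[n].
    """
    from scipy.interpolate import RegularGridInterpolator

    rgi = RegularGridInterpolator(axes, values, method="linear",
                                  bounds_error=False, fill_value=None)

    def f(points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, float)
        clipped = pts.copy()
        for a in range(3):
            clipped[:, a] = np.clip(pts[:, a], axes[a][0], axes[a][-1])
        return rgi(clipped)

    return f


def fill_nan_by_diffusion(field: np.ndarray, iterations: int = 60) -> np.ndarray:
    """Replace NaNs by iterative neighbor averaging (Jacobi inpainting).

    Used before interpolating a parent solution whose excluded (solid)
    cells carry NaN: the filled values only matter as interpolation support
    next to material boundaries.
    """
    out = field.copy()
    nan = np.isnan(out)
    if not nan.any():
        return out
    # start from the mean of defined values
    fill0 = np.nanmean(out) if not np.isnan(np.nanmean(out)) else 0.0
    out[nan] = fill0
    for _ in range(iterations):
        acc = np.zeros_like(out)
        cnt = np.zeros(out.shape)
        for axis in range(3):
            for shift in (1, -1):
                acc += np.roll(out, shift, axis=axis)
                cnt += 1
        out[nan] = (acc[nan] / cnt[nan])
    return out
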