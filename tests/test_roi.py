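import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stimtwin.geometry import generate_scaffold, honeycomb_scaffold, orthogonal_scaffold
from stimtwin.roi import (
    MicroenvironmentTarget,
    extract_roi,
    histogram,
    rescale_histogram,
    score_against_target,
)

MM = 1e-3

_COARSE_GRID = generate_scaffold(orthogonal_scaffold(), 250e-6 / 2)


@pytest.fixture(scope="module")
def scaffold_grid():
    return _COARSE_GRID


class TestExtractROI:
    def test_orthogonal_envelope_box(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        nx, ny, nz = scaffold_grid.shape
        counts = [roi.any(axis=tuple(a for a in range(3) if a != ax)).sum()
                  for ax in range(3)]
        h = scaffold_grid.spacing
        assert counts[0] * h == pytest.approx(10.0 * MM, abs=h)
        assert counts[1] * h == pytest.approx(10.0 * MM, abs=h)
        assert counts[2] * h == pytest.approx(2.75 * MM, abs=h)

    def test_honeycomb_envelope_box(self):
        grid = generate_scaffold(honeycomb_scaffold(), 100e-6)
        roi = extract_roi(grid)
        h = grid.spacing
        n_z = roi.any(axis=(0, 1)).sum()
        assert n_z * h == pytest.approx(3.0 * MM, abs=h)

    def test_grid_without_scaffold_rejected(self, scaffold_grid):
        empty = generate_scaffold(honeycomb_scaffold(filament_or_truss=0.0), 100e-6)
        with pytest.raises(ValueError, match="no scaffold"):
            extract_roi(empty)


class TestHistogram:
    def test_uniform_field_is_single_bin_with_mean(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        field = np.full(scaffold_grid.shape, 0.01)
        hist = histogram(field, scaffold_grid, roi, bins=np.array([0, 0.005, 0.0101]))
        assert hist.mean == pytest.approx(0.01)
        assert hist.normalized[-1] == 1.0 and hist.volume[0] == 0.0

    def test_linear_ramp_is_flat_within_discretization(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        xs = scaffold_grid.cell_centers(0)
        field = np.broadcast_to(xs[:, None, None] - xs[0],
                                scaffold_grid.shape).copy()
        hist = histogram(field, scaffold_grid, roi, bins=8)
        inner = hist.volume[1:-1]
        # the ramp distributes volume evenly over bins, up to the lattice
        # structure sampled per slab
        assert inner.std() / inner.mean() < 0.15

    def test_mean_equals_independent_summation(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        rng = np.random.default_rng(1)
        field = rng.random(scaffold_grid.shape)
        hist = histogram(field, scaffold_grid, roi)
        med = scaffold_grid.mask("medium")
        manual = field[roi & med].mean()
        assert hist.mean == pytest.approx(manual, rel=1e-12)

    def test_mass_conservation(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        rng = np.random.default_rng(2)
        field = rng.random(scaffold_grid.shape)
        hist = histogram(field, scaffold_grid, roi)
        assert hist.volume.sum() == pytest.approx(hist.roi_volume, rel=1e-12)
        med = scaffold_grid.mask("medium")
        assert hist.roi_volume == pytest.approx(
            (roi & med).sum() * scaffold_grid.cell_volume, rel=1e-12)

    def test_solid_cells_excluded_by_default(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        field = np.zeros(scaffold_grid.shape)
        field[scaffold_grid.mask("scaffold")] = 100.0
        hist = histogram(field, scaffold_grid, roi)
        assert hist.max == 0.0
        incl = histogram(field, scaffold_grid, roi, include_solids=True)
        assert incl.max == 100.0


class TestScoring:
    def test_uniform_tau_inside_window_passes(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        hist = histogram(np.full(scaffold_grid.shape, 0.01), scaffold_grid, roi,
                         units="Pa")
        score = score_against_target(hist, MicroenvironmentTarget(), "shear")
        assert score["best_fraction"] == 1.0 and score["passed"]

    def test_uniform_tau_outside_window_fails(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        hist = histogram(np.full(scaffold_grid.shape, 0.5), scaffold_grid, roi,
                         units="Pa")
        score = score_against_target(hist, MicroenvironmentTarget(), "shear")
        assert score["best_fraction"] == 0.0 and not score["passed"]

    def test_bimodal_field_scores_half(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        med = scaffold_grid.mask("medium")
        n_roi = (roi & med).sum()
        field = np.full(scaffold_grid.shape, 0.5)
        idx = np.argwhere(roi & med)
        half = idx[: n_roi // 2]
        field[tuple(half.T)] = 0.01
        hist = histogram(field, scaffold_grid, roi, units="Pa")
        score = score_against_target(hist, MicroenvironmentTarget(), "shear")
        one_cell = 1.0 / n_roi
        assert score["best_fraction"] == pytest.approx(0.5, abs=one_cell)

    def test_unit_mismatch_rejected(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        hist = histogram(np.ones(scaffold_grid.shape), scaffold_grid, roi,
                         units="V/m")
        with pytest.raises(ValueError, match="unit"):
            score_against_target(hist, MicroenvironmentTarget(), "shear")


class TestProtocolRescaling:
    def test_identity_scale(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        hist = histogram(np.random.default_rng(3).random(scaffold_grid.shape),
                         scaffold_grid, roi)
        same = rescale_histogram(hist, 1.0)
        assert np.array_equal(same.edges, hist.edges)
        assert same.mean == hist.mean

    @settings(max_examples=20, deadline=None)
    @given(factor=st.floats(0.01, 10.0))
    def test_window_fraction_change_of_variables(self, factor):
        grid = _COARSE_GRID
        roi = extract_roi(grid)
        field = np.random.default_rng(4).random(grid.shape) * 0.05
        hist = histogram(field, grid, roi, units="Pa")
        scaled = rescale_histogram(hist, factor)
        lo, hi = 1.47e-3, 24e-3
        assert scaled.in_window_fraction(lo, hi) == pytest.approx(
            hist.in_window_fraction(lo / factor, hi / factor), abs=1e-12)

    def test_negative_factor_rejected(self, scaffold_grid):
        roi = extract_roi(scaffold_grid)
        hist = histogram(np.ones(scaffold_grid.shape), scaffold_grid, roi)
        with pytest.raises(ValueError):
            rescale_histogram(hist, -1.0)

    def test_rescale_equals_rescaled_solve(self):
        """Scaling the drive and re-solving equals scaling the fields."""
        from stimtwin.flow import FlowBC, solve_flow
        from stimtwin.grid import Scene

        sc = Scene(background=("wall", "C8"))
        sc.add("medium", "medium", lambda x, y, z: x * x + y * y <= (0.5e-3) ** 2)
        h = 1e-3 / 16
        grid = sc.voxelize((-0.7e-3, -0.7e-3, 0), (0.7e-3, 0.7e-3, 1.5e-3), h)
        s1 = solve_flow(grid, FlowBC(boundary_pressures={"z_min": 0.05, "z_max": 0}),
                        method="minres", tol=1e-10)
        s2 = solve_flow(grid, FlowBC(boundary_pressures={"z_min": 0.0005, "z_max": 0}),
                        method="minres", tol=1e-10)
        m = np.abs(s1.u_faces[2]) > 1e-6 * np.abs(s1.u_faces[2]).max()
        assert np.allclose(s1.u_faces[2][m] * 0.01, s2.u_faces[2][m], rtol=1e-6)
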