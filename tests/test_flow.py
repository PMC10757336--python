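import numpy as np
import pytest

from stimtwin.flow import FlowBC, reynolds, shear_stress, solve_flow
from stimtwin.grid import Scene
from stimtwin.materials import default_registry

MU = 6.89e-4  # culture medium dynamic viscosity, Pa s


def planar_channel(n_across=32, height=1e-3, length=2e-3):
    """2D plane-Poiseuille setup: walls in y, symmetry sides in z."""
    h = height / n_across
    sc = Scene(background=("wall", "C8"))
    sc.add("medium", "medium", lambda x, y, z: (y > 0) & (y < height))
    grid = sc.voxelize((0, -2 * h, 0), (length, height + 2 * h, 6 * h), h)
    bc = FlowBC(
        boundary_pressures={"x_min": 0.05, "x_max": 0.0},
        boundary_types={"z_min": "symmetry", "z_max": "symmetry"},
    )
    return grid, bc


def circular_duct(n_across=24, diameter=1e-3, length=2e-3, dp=0.05):
    h = diameter / n_across
    pad = 2 * h
    r = diameter / 2
    sc = Scene(background=("wall", "C8"))
    sc.add("medium", "medium", lambda x, y, z: x * x + y * y <= r * r)
    grid = sc.voxelize((-r - pad, -r - pad, 0), (r + pad, r + pad, length), h)
    bc = FlowBC(boundary_pressures={"z_min": dp, "z_max": 0.0})
    return grid, bc


class TestPoiseuilleBenchmarks:
    def test_circular_duct_max_over_mean_is_two(self):
        grid, bc = circular_duct()
        sol = solve_flow(grid, bc, method="minres")
        uz = sol.velocity_cell[2]
        vals = uz[sol.fluid_mask]
        assert np.nanmax(vals) / vals.mean() == pytest.approx(2.0, rel=0.02)

    def test_planar_wall_shear_is_six_mu_u_over_h(self):
        grid, bc = planar_channel()
        sol = solve_flow(grid, bc, method="minres")
        ux = sol.velocity_cell[0]
        i, k = grid.shape[0] // 2, grid.shape[2] // 2
        profile = ux[i, :, k]
        u_mean = profile[2:-2].mean()
        tau = shear_stress(sol, MU)
        tau_wall = tau[i, 2, k]  # first fluid cell at the lower wall
        assert tau_wall == pytest.approx(6 * MU * u_mean / 1e-3, rel=0.03)
        # parabolic profile: centerline / mean = 3/2
        assert profile.max() / u_mean == pytest.approx(1.5, rel=0.02)

    def test_printed_shear_magnitude(self):
        # mu = 6.89e-4 Pa s, U = 1 mm/s, h = 1 mm -> 4.134e-3 Pa
        assert 6 * MU * 1e-3 / 1e-3 == pytest.approx(4.134e-3, rel=1e-3)


class TestStokesStructure:
    def test_zero_driving_gives_zero_flow(self):
        grid, _ = circular_duct()
        sol = solve_flow(grid, FlowBC(), method="minres")
        assert all(np.abs(u).max() == 0.0 for u in sol.u_faces)

    def test_linearity_in_the_drive(self):
        grid, bc1 = circular_duct(dp=0.05)
        _, bc2 = circular_duct(dp=0.10)
        s1 = solve_flow(grid, bc1, method="minres", tol=1e-10)
        s2 = solve_flow(grid, bc2, method="minres", tol=1e-10)
        m = np.abs(s1.u_faces[2]) > 1e-3 * np.abs(s1.u_faces[2]).max()
        ratio = s2.u_faces[2][m] / s1.u_faces[2][m]
        assert np.abs(ratio / 2.0 - 1.0).max() < 1e-6

    def test_divergence_free_and_mass_balance(self):
        grid, bc = circular_duct()
        sol = solve_flow(grid, bc, method="minres", tol=1e-10)
        assert sol.info["div_max_rel"] < 1e-6
        # net volumetric flux through the two open ends cancels
        h2 = grid.spacing**2
        q_in = sol.u_faces[2][:, :, 0].sum() * h2
        q_out = sol.u_faces[2][:, :, -1].sum() * h2
        assert abs(q_out - q_in) <= 1e-6 * abs(q_out)

    def test_velocity_vanishes_inside_solids(self):
        grid, bc = circular_duct()
        sol = solve_flow(grid, bc, method="minres")
        for comp in sol.velocity_cell:
            assert np.all(comp[~sol.fluid_mask] == 0.0)

    def test_scaled_solution_equals_rescaled_fields(self):
        grid, bc = circular_duct()
        sol = solve_flow(grid, bc, method="minres")
        doubled = sol.scaled(2.0)
        assert np.allclose(doubled.u_faces[2], 2 * sol.u_faces[2])
        tau = shear_stress(sol, MU)
        assert np.allclose(shear_stress(doubled, MU), 2 * tau)


class TestDerivedFields:
    def test_uniform_translation_has_zero_shear(self):
        # all-Dirichlet box moving at constant velocity: gamma-dot == 0
        sc = Scene(background=("medium", "medium"))
        grid = sc.voxelize((0, 0, 0), (1e-3, 1e-3, 1e-3), 1e-4)
        dirichlet = []
        for ax in range(3):
            shp = list(grid.shape)
            shp[ax] += 1
            arr = np.full(tuple(shp), np.nan)
            sel = [slice(None)] * 3
            sel[ax] = 0
            arr[tuple(sel)] = 1e-3 if ax == 0 else 0.0
            sel[ax] = shp[ax] - 1
            arr[tuple(sel)] = 1e-3 if ax == 0 else 0.0
            dirichlet.append(arr)
        sol = solve_flow(grid, FlowBC(), method="minres",
                         dirichlet_faces=tuple(dirichlet))
        tau = shear_stress(sol, MU)
        assert np.abs(tau[sol.fluid_mask]).max() < 1e-9 * MU * 1e-3 / 1e-4

    def test_reynolds_formula_and_scaling(self):
        grid, bc = circular_duct()
        sol = solve_flow(grid, bc, method="minres")
        reg = default_registry()
        re1 = reynolds(sol, reg["medium"], l_char=500e-6)
        re2 = reynolds(sol, reg["medium"], l_char=1000e-6)
        assert np.allclose(re2, 2 * re1)
        # rho=994, |u|=1 mm/s, L=500 um, mu=6.89e-4 -> Re = 0.721
        assert 994 * 1e-3 * 500e-6 / MU == pytest.approx(0.721, abs=5e-4)
        assert np.all(re1[~sol.fluid_mask] == 0)
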