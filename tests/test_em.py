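import numpy as np
import pytest

from stimtwin.em import (
    EMBC,
    apply_series_resistor,
    field_from_measured_current,
    layered_1d_oracle,
    solve_em,
)
from stimtwin.geometry import build_validation_cell
from stimtwin.materials import default_registry

MM = 1e-3
UM = 1e-6


@pytest.fixture(scope="module")
def registry():
    return default_registry()


@pytest.fixture(scope="module")
def bench_stack(registry):
    """PET 175 um | medium 10 mm | PET 175 um, the bench validation cell."""
    return [(175 * UM, registry["PET"]), (10 * MM, registry["medium"]),
            (175 * UM, registry["PET"])]


class TestLayeredOracle:
    def test_bench_cell_field_is_0095(self, bench_stack):
        o = layered_1d_oracle(bench_stack, 5.0, 60e3)
        assert o.e_in("medium") == pytest.approx(0.095, abs=5e-4)
        # hand check: J = 5 V / 34.95 ohm m^2, E = J / 1.5
        assert abs(o.z_total) == pytest.approx(34.95, rel=1e-3)
        assert abs(o.j) == pytest.approx(0.1431, rel=1e-3)

    def test_single_layer_dc_is_v_over_d(self, registry):
        o = layered_1d_oracle([(10 * MM, registry["medium"])], 5.0, 0.0)
        assert o.e_in("medium") == pytest.approx(5.0 / 10e-3, rel=1e-12)

    def test_gap_22mm_leaves_field_unchanged(self, registry, bench_stack):
        wide = [bench_stack[0], (22 * MM, registry["medium"]), bench_stack[2]]
        e10 = layered_1d_oracle(bench_stack, 5.0, 60e3).e_in("medium")
        e22 = layered_1d_oracle(wide, 5.0, 60e3).e_in("medium")
        assert round(e22, 3) == round(e10, 3)  # PET impedance dominates

    def test_zero_thickness_layer_dropped_with_warning(self, registry):
        with pytest.warns(UserWarning, match="zero-thickness"):
            o = layered_1d_oracle(
                [(0.0, registry["PET"]), (1 * MM, registry["medium"])], 1.0, 1e3)
        assert len(o.layers) == 1


class TestSolveEM:
    def test_validation_cell_uniform_and_matches_oracle(self, bench_stack):
        grid = build_validation_cell(resolution=500 * UM)
        sol = solve_em(grid, EMBC(5.0, 60e3))
        med = grid.mask("medium")
        xs = grid.cell_centers(0)
        core = med & (np.abs(xs)[:, None, None] <= 0.8 * 5 * MM)
        vals = sol.e_mag[core]
        oracle = layered_1d_oracle(bench_stack, 5.0, 60e3).e_in("medium")
        assert vals.mean() == pytest.approx(oracle, rel=0.05)
        assert (vals.max() - vals.min()) / vals.mean() < 0.05  # uniform core

    def test_resolved_pet_matches_oracle(self, registry):
        # thin cell fully resolving the 175 um film (10 cells across it)
        gap = 1.05 * MM
        grid = build_validation_cell(
            gap=gap, plate_size=(0.56 * MM, 0.56 * MM), resolution=17.5 * UM,
            pet_resolved=True, enclosure_material=None)
        sol = solve_em(grid, EMBC(5.0, 60e3), resolve_insulators=True,
                       method="iterative")
        stack = [(175 * UM, registry["PET"]), (gap, registry["medium"]),
                 (175 * UM, registry["PET"])]
        oracle = layered_1d_oracle(stack, 5.0, 60e3)
        med = grid.mask("medium")
        assert sol.e_mag[med].mean() == pytest.approx(oracle.e_in("medium"), rel=0.05)
        # the film interior field follows the same series model
        pet = grid.mask("PET")
        assert sol.e_mag[pet].mean() == pytest.approx(oracle.e_in("PET"), rel=0.05)

    def test_zero_amplitude_gives_zero_field_and_current(self):
        grid = build_validation_cell(resolution=500 * UM)
        sol = solve_em(grid, EMBC(0.0, 60e3))
        assert np.nanmax(sol.e_mag) == 0.0
        assert sol.i_active == 0.0

    def test_dc_plate_capacitor_limit(self):
        # bare plates in medium, fringing suppressed: E = V/d, I = sigma V A / d
        grid = build_validation_cell(gap=10 * MM, plate_size=(5 * MM, 5 * MM),
                                     pet_thickness=0.0, resolution=500 * UM)
        sol = solve_em(grid, EMBC(5.0, 0.0), method="direct")
        med = grid.mask("medium")
        assert sol.e_mag[med].mean() == pytest.approx(500.0, rel=0.02)
        i_exact = 1.5 * 5.0 * (5 * MM) ** 2 / (10 * MM)
        assert abs(sol.i_active) == pytest.approx(i_exact, rel=0.02)

    def test_terminal_currents_balance(self):
        grid = build_validation_cell(resolution=500 * UM)
        sol = solve_em(grid, EMBC(5.0, 60e3))
        assert abs(abs(sol.i_active) - abs(sol.i_ground)) <= 1e-6 * abs(sol.i_active)

    def test_linearity_in_amplitude(self):
        grid = build_validation_cell(resolution=500 * UM)
        s1 = solve_em(grid, EMBC(5.0, 60e3))
        s2 = solve_em(grid, EMBC(10.0, 60e3))
        med = grid.mask("medium")
        assert np.allclose(s2.e_mag[med], 2 * s1.e_mag[med], rtol=1e-6)
        assert abs(s2.i_active) == pytest.approx(2 * abs(s1.i_active), rel=1e-6)

    def test_missing_electrode_rejected(self):
        grid = build_validation_cell(resolution=500 * UM)
        grid.labels[grid.mask("electrode_ground")] = grid.label_id("enclosure")
        with pytest.raises(ValueError, match="electrode"):
            solve_em(grid, EMBC(5.0, 60e3))


class TestCircuitArithmetic:
    def test_series_resistor_correction(self):
        # inferred reactive source impedance + 21.89 kOhm measurement resistor
        i_new, scale = apply_series_resistor(5.0, 3.21e-5, 21.89e3)
        assert i_new == pytest.approx(31.8e-6, abs=0.05e-6)
        assert 0.095 * scale == pytest.approx(0.094, abs=5e-4)

    def test_zero_resistor_is_identity(self):
        i_new, scale = apply_series_resistor(5.0, 3.21e-5, 0.0)
        assert i_new == pytest.approx(3.21e-5, rel=1e-12)
        assert scale == pytest.approx(1.0, rel=1e-12)

    def test_negative_resistor_rejected(self):
        with pytest.raises(ValueError):
            apply_series_resistor(5.0, 1e-5, -1.0)

    def test_field_from_measured_current(self):
        assert field_from_measured_current(0.095, 3.21e-5, 2.43e-5) == pytest.approx(
            0.072, abs=5e-4)
        assert field_from_measured_current(0.095, 3.21e-5, 3.21e-5) == 0.095
        half = field_from_measured_current(0.095, 3.21e-5, 3.21e-5 / 2)
        assert half == pytest.approx(0.095 / 2, rel=1e-12)
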