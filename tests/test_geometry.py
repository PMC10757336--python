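import math

import numpy as np
import pytest

from stimtwin.geometry import (
    ElectrodeAssembly,
    ScaffoldSpec,
    assemble_chamber,
    build_validation_cell,
    generate_scaffold,
    honeycomb_scaffold,
    orthogonal_scaffold,
    scaffold_predicate,
    synthetic_dye_recording,
)

MM = 1e-3
UM = 1e-6


def mc_orthogonal_fraction(spec: ScaffoldSpec, n: int = 2_000_000, seed: int = 0) -> float:
    """Brute-force point-sampling oracle over the explicit cylinder list."""
    Lx, Ly, Lz = spec.envelope
    d = spec.filament_or_truss
    r = d / 2
    pin = d + spec.pore
    pz = d * (1 - spec.superposition_frac)
    n_layers = int(math.floor((Lz - d) / pz + 1e-9)) + 1
    z_first = -0.5 * (n_layers - 1) * pz
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-0.5, 0.5, size=(n, 3)) * np.array([Lx, Ly, Lz])
    inside = np.zeros(n, dtype=bool)
    for m in range(n_layers):
        zc = z_first + m * pz
        along_x = m % 2 == 0
        L_t = Ly if along_x else Lx
        n_cyl = int(math.floor((L_t - d) / pin + 1e-9)) + 1
        t = pts[:, 1] if along_x else pts[:, 0]
        for k in range(n_cyl):
            tc = (k - (n_cyl - 1) / 2) * pin
            inside |= (t - tc) ** 2 + (pts[:, 2] - zc) ** 2 <= r * r
    return float(inside.mean())


class TestScaffoldGeneration:
    def test_orthogonal_fraction_matches_mc_oracle(self):
        spec = orthogonal_scaffold()
        grid = generate_scaffold(spec, 50 * UM)
        mc = mc_orthogonal_fraction(spec)
        assert grid.volume_fraction("scaffold") == pytest.approx(mc, rel=0.02)

    def test_single_filament_limit_is_analytic(self):
        # pore -> infinity leaves one filament per layer; a one-layer
        # envelope then holds exactly one cylinder
        spec = orthogonal_scaffold(
            pore=1.0, superposition_frac=0.0, envelope=(10 * MM, 10 * MM, 0.5 * MM)
        )
        grid = generate_scaffold(spec, 25 * UM)
        exact = math.pi * (0.25 * MM) ** 2 * 10 * MM / (10 * MM * 10 * MM * 0.5 * MM)
        assert grid.volume_fraction("scaffold") == pytest.approx(exact, rel=0.02)

    def test_zero_truss_honeycomb_is_all_medium(self):
        spec = honeycomb_scaffold(filament_or_truss=0.0)
        grid = generate_scaffold(spec, 100 * UM)
        assert grid.count("scaffold") == 0

    def test_too_coarse_resolution_refused_with_minimum(self):
        spec = orthogonal_scaffold()
        with pytest.raises(ValueError, match="3 cells per pore"):
            generate_scaffold(spec, spec.pore)

    def test_voxelization_refines_consistently(self):
        # prismatic walls voxelize cleanly, so halving the cell size may
        # move the solid fraction only by O(h)
        spec = honeycomb_scaffold()
        f = {h: generate_scaffold(spec, h).volume_fraction("scaffold")
             for h in (100 * UM, 50 * UM)}
        assert abs(f[100 * UM] - f[50 * UM]) < 0.01

    @pytest.mark.parametrize("bad", [
        dict(kind="spiral"),
        dict(superposition_frac=0.5),
        dict(envelope=(0.0, 1e-2, 1e-2)),
    ])
    def test_invalid_specs_rejected(self, bad):
        base = dict(kind="orthogonal", envelope=(1e-2, 1e-2, 3e-3),
                    filament_or_truss=5e-4, pore=5e-4)
        base.update(bad)
        with pytest.raises(ValueError):
            ScaffoldSpec(**base)


class TestChamberAssembly:
    def test_horizontal_holder_has_exactly_one_exit_patch(self):
        grid = assemble_chamber(None, "horizontal", resolution=500 * UM)
        bottom = grid.labels[:, :, 0]
        medium = bottom == grid.label_id("medium")
        from scipy import ndimage

        _, n = ndimage.label(medium)
        assert n == 1

    def test_electrode_separation_is_22mm(self):
        grid = assemble_chamber(orthogonal_scaffold(), "horizontal",
                                ElectrodeAssembly(), resolution=500 * UM)
        act = grid.mask("electrode_active")
        gnd = grid.mask("electrode_ground")
        xs = grid.cell_centers(0)
        x_act = xs[np.where(act.any(axis=(1, 2)))[0]].min()
        x_gnd = xs[np.where(gnd.any(axis=(1, 2)))[0]].max()
        inner = (x_act - grid.spacing / 2) - (x_gnd + grid.spacing / 2)
        assert inner == pytest.approx(22 * MM, abs=grid.spacing)

    def test_scaffold_voxel_count_invariant_to_holder(self):
        spec = orthogonal_scaffold()
        a = assemble_chamber(spec, "horizontal", resolution=250 * UM, supersample=2)
        b = assemble_chamber(spec, "vertical", resolution=250 * UM, supersample=2)
        assert a.count("scaffold") == b.count("scaffold") > 0

    def test_mirror_symmetry_about_scaffold_midplanes(self):
        grid = assemble_chamber(orthogonal_scaffold(), "horizontal",
                                resolution=500 * UM)
        lab = grid.labels
        assert np.array_equal(lab, lab[:, ::-1, :])
        assert np.array_equal(lab, lab[::-1, :, :])

    def test_labels_partition_every_cell(self):
        grid = assemble_chamber(orthogonal_scaffold(), "vertical",
                                resolution=500 * UM)
        assert grid.labels.max() < len(grid.label_names)
        for name in grid.label_names:
            assert name in grid.material_map

    def test_electrodes_intersecting_scaffold_rejected(self):
        with pytest.raises(ValueError, match="intersect"):
            assemble_chamber(orthogonal_scaffold(), "horizontal",
                             ElectrodeAssembly(gap=8 * MM), resolution=500 * UM)


class TestValidationCell:
    @pytest.mark.parametrize("gap", [10 * MM, 22 * MM])
    def test_medium_slab_thickness_equals_gap(self, gap):
        grid = build_validation_cell(gap=gap, resolution=500 * UM)
        med = grid.mask("medium")
        nx = med.any(axis=(1, 2)).sum()
        assert nx * grid.spacing == pytest.approx(gap, abs=grid.spacing)

    def test_zero_pet_gives_bare_conductors(self):
        grid = build_validation_cell(pet_thickness=0.0, resolution=500 * UM)
        assert "pet_face_impedance" not in grid.metadata
        assert grid.count("PET") == 0

    def test_resolved_pet_layer_thickness(self):
        grid = build_validation_cell(gap=1.75 * MM, plate_size=(0.7 * MM, 0.7 * MM),
                                     resolution=17.5 * UM, pet_resolved=True)
        pet = grid.mask("PET")
        nx = pet.any(axis=(1, 2)).sum()
        assert nx == 2 * 10  # 175 um on each side at 17.5 um cells


class TestDyeRecording:
    def test_noise_free_front_covers_7mm_in_2963ms(self):
        v = 7 * MM / 2.963  # the bench-measured mean front speed
        rec = synthetic_dye_recording(v, 7 * MM, frame_rate=1000.0)
        assert rec[-1, 0] - rec[0, 0] == pytest.approx(2.963, abs=2e-3)
        assert rec[-1, 1] == pytest.approx(7 * MM, abs=v * 1.1e-3)

    def test_zero_velocity_is_constant(self):
        rec = synthetic_dye_recording(0.0, 7 * MM, frame_rate=30.0)
        assert np.all(rec[:, 1] == 0)

    def test_seeded_noise_is_deterministic(self):
        a = synthetic_dye_recording(1e-3, 5 * MM, 30.0, noise_sd=1e-4, seed=7)
        b = synthetic_dye_recording(1e-3, 5 * MM, 30.0, noise_sd=1e-4, seed=7)
        c = synthetic_dye_recording(1e-3, 5 * MM, 30.0, noise_sd=1e-4, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


def test_upright_predicate_is_rotated_flat_predicate():
    spec = orthogonal_scaffold()
    flat = scaffold_predicate(spec, orientation="flat")
    up = scaffold_predicate(spec, orientation="upright")
    rng = np.random.default_rng(3)
    pts = rng.uniform(-6e-3, 6e-3, size=(5000, 3))
    # world (x, y, z) of the upright scaffold = rotation of local coords
    assert np.array_equal(
        up(pts[:, 0], pts[:, 1], pts[:, 2]),
        flat(-pts[:, 2], pts[:, 1], pts[:, 0]),
    )
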