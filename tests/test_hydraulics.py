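import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stimtwin.hydraulics import (
    PERISTALTIC_CONNECTOR_AREA,
    Branch,
    ChannelNetworkSpec,
    default_manifold,
    hydraulic_resistance,
    solve_split,
    velocity_from_flow,
)

Q_MAX = 50e-6 / 60.0  # 50 mL/min


class TestVelocityFromFlow:
    def test_pump_maximum_gives_printed_outlet_velocity(self):
        v = velocity_from_flow(Q_MAX, PERISTALTIC_CONNECTOR_AREA)
        assert v == pytest.approx(0.328, abs=5e-4)

    def test_zero_flow(self):
        assert velocity_from_flow(0.0, 1e-6) == 0.0

    def test_velocity_preserved_under_area_conservation(self):
        # a quarter of the flow through a quarter of the area
        v_root = velocity_from_flow(Q_MAX, PERISTALTIC_CONNECTOR_AREA)
        v_leaf = velocity_from_flow(Q_MAX / 4, PERISTALTIC_CONNECTOR_AREA / 4)
        assert v_leaf == pytest.approx(v_root, rel=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            velocity_from_flow(1e-6, 0.0)


class TestManifold:
    def test_default_tree_obeys_area_rule(self):
        net = default_manifold()
        assert net.check_area_rule() == []
        assert net.is_symmetric()
        assert len(net.leaves()) == 4

    def test_symmetric_split_is_exact_quarter(self):
        net = default_manifold()
        res = solve_split(net, Q_MAX)
        for leaf in net.leaves():
            assert res[leaf.name]["q"] == pytest.approx(Q_MAX / 4, rel=1e-14)
            assert res[leaf.name]["v"] == pytest.approx(0.328, abs=5e-4)

    def test_rule_violation_names_the_split(self):
        root = Branch("root", area=1e-6, length=0.1,
                      children=[Branch("a", 0.4e-6, 0.1), Branch("b", 0.4e-6, 0.1)])
        net = ChannelNetworkSpec(root)
        assert net.check_area_rule() == ["root"]
        with pytest.raises(ValueError, match="root"):
            solve_split(net, Q_MAX)

    def test_blocked_leaf_reroutes_flow(self):
        root = Branch("root", area=1e-6, length=0.1, children=[
            Branch("a", 0.5e-6, 0.1),
            Branch("b", 0.0, 0.1),  # blocked
        ])
        net = ChannelNetworkSpec(root)
        res = solve_split(net, Q_MAX, check_rule=False)
        assert res["b"]["q"] == 0.0
        assert res["a"]["q"] == pytest.approx(Q_MAX, rel=1e-12)

    def test_asymmetric_without_lengths_is_an_error(self):
        root = Branch("root", area=1e-6, children=[
            Branch("a", 0.7e-6), Branch("b", 0.3e-6)])
        with pytest.raises(ValueError, match="length"):
            solve_split(ChannelNetworkSpec(root), Q_MAX, check_rule=False)

    @settings(max_examples=25, deadline=None)
    @given(
        a_frac=st.floats(0.2, 0.8),
        l1=st.floats(0.01, 0.5),
        l2=st.floats(0.01, 0.5),
        q=st.floats(1e-8, 1e-5),
    )
    def test_kirchhoff_conservation_on_asymmetric_trees(self, a_frac, l1, l2, q):
        area = 2e-6
        root = Branch("root", area=area, length=0.05, children=[
            Branch("a", a_frac * area, l1),
            Branch("b", (1 - a_frac) * area, l2),
        ])
        res = solve_split(ChannelNetworkSpec(root), q)
        assert res["a"]["q"] + res["b"]["q"] == pytest.approx(q, rel=1e-9)
        assert res["a"]["q"] >= 0 and res["b"]["q"] >= 0


class TestCrossValidationAgainstStokes:
    """Lumped Poiseuille split vs the voxel Stokes solver, two-branch net."""

    def test_two_branch_split_matches_voxel_solver(self):
        from stimtwin.grid import Scene
        from stimtwin.flow import FlowBC, solve_flow

        # two parallel square channels of equal length, sides w1 > w2,
        # joined to common pressure reservoirs at both ends
        w1, w2, L = 1.0e-3, 0.7e-3, 4.0e-3
        h = 50e-6
        sc = Scene(background=("wall", "C8"))
        sc.add("medium", "medium",
               lambda x, y, z: (np.abs(y - 1e-3) < w1 / 2) & (np.abs(z) < w1 / 2))
        sc.add("medium", "medium",
               lambda x, y, z: (np.abs(y + 1e-3) < w2 / 2) & (np.abs(z) < w2 / 2))
        grid = sc.voxelize((0, -1.8e-3, -0.8e-3), (L, 1.8e-3, 0.8e-3), h)
        sol = solve_flow(grid, FlowBC(boundary_pressures={"x_min": 0.2, "x_max": 0.0}),
                         method="minres", tol=1e-9)
        ux = sol.u_faces[0]
        mid = ux.shape[0] // 2
        ys = grid.cell_centers(1)
        q1 = ux[mid][ys > 0, :].sum() * h * h
        q2 = ux[mid][ys < 0, :].sum() * h * h

        mu = 6.89e-4
        r1 = hydraulic_resistance(L, w1 * w1, mu, "square")
        r2 = hydraulic_resistance(L, w2 * w2, mu, "square")
        expected_ratio = r2 / r1  # q1/q2 under a common pressure drop
        assert q1 / q2 == pytest.approx(expected_ratio, rel=0.15)
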