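"""Stokes solver: analytic Poiseuille benchmark, conservation, linearity,
symmetry, and the channel-flow summaries."""

import numpy as np
import pytest

from macropore.geometry import DeviceGeometry, build_device_geometry
from macropore.meshing import generate_mesh, rectangle_mesh
from macropore.stokes import (
    StokesError,
    channel_flux,
    channel_mean_velocity,
    fluid_collection_efficiency,
    solve_stokes,
)

U_REF = 115e-6


@pytest.fixture(scope="module")
def duct_flow():
    """Plane duct, 4 mm x 1 mm; the profile far from the inlet is the
    plane-Poiseuille parabola."""
    mesh = rectangle_mesh(4e-3, 1e-3, 60, 24)
    return mesh, solve_stokes(mesh, U_REF)


def test_zero_velocity_gives_null_field():
    mesh = rectangle_mesh(2e-3, 1e-3, 10, 6)
    flow = solve_stokes(mesh, 0.0)
    assert np.all(flow.u == 0)
    assert np.ptp(flow.p) == 0


def test_poiseuille_profile_matches_closed_form(duct_flow):
    mesh, flow = duct_flow
    W = 1e-3
    y = np.linspace(0, W, 101)[1:-1]
    pts = np.column_stack([np.full_like(y, 3.2e-3), y])
    ux = flow.interpolate_velocity(pts)[:, 0]
    exact = 6.0 * U_REF * y * (W - y) / W**2
    assert np.max(np.abs(ux - exact)) < 0.03 * exact.max()
    # mean = (2/3) max for the parabola
    assert ux.mean() == pytest.approx((2.0 / 3.0) * ux.max(), rel=0.02)


def test_duct_flux_equals_U_times_width(duct_flow):
    mesh, flow = duct_flow
    for x in (1e-3, 2e-3, 3.5e-3):
        q = -flow.flux_across_segment((x, 0.0), (x, 1e-3))
        assert q == pytest.approx(U_REF * 1e-3, rel=0.01)


def test_no_slip_on_duct_walls(duct_flow):
    mesh, flow = duct_flow
    wall = mesh.nodes_with_tag("chamber_wall")
    assert np.max(np.abs(flow.u[wall])) < 1e-12 * U_REF + 1e-18


@pytest.fixture()
def device_flow(runner):
    spec = runner.device(600.0, 0.0)
    return spec, runner.mesh(600.0, 0.0), runner.flow(600.0, 0.0, 1150.0)


class TestDevice:
    def test_cross_section_flux_matches_imposed_velocity(self, device_flow):
        _, mesh, flow = device_flow
        for x in (-6e-3, 0.0, 6e-3):
            assert flow.flux_across_x(x) == pytest.approx(
                flow.bulk_velocity * 5e-3, rel=0.01
            )

    def test_inlet_and_outlet_fluxes_balance(self, device_flow):
        _, _, flow = device_flow
        qin = flow.flux_across_x(-7.5e-3)
        qout = flow.flux_across_x(7.5e-3)
        assert qin == pytest.approx(qout, rel=0.005)

    def test_divergence_residual_is_small(self, device_flow):
        _, _, flow = device_flow
        assert flow.continuity_residual() < 0.08

    def test_linearity_in_bulk_velocity(self, runner):
        mesh = runner.mesh(600.0, 0.0)
        f1 = runner.flow(600.0, 0.0, 1150.0)
        f2 = solve_stokes(mesh, 2 * 1150e-6)
        scale = np.max(np.abs(f1.u))
        assert np.max(np.abs(f2.u - 2 * f1.u)) < 1e-8 * scale

    def test_collection_efficiency_independent_of_velocity(self, runner):
        spec = runner.device(600.0, 0.0)
        e_lo = fluid_collection_efficiency(runner.flow(600.0, 0.0, 11.5), spec)
        e_hi = fluid_collection_efficiency(runner.flow(600.0, 0.0, 1150.0), spec)
        assert e_lo == pytest.approx(e_hi, rel=0.01)

    def test_perpendicular_channel_carries_no_net_flow(self, runner):
        spec = runner.device(400.0, 90.0)
        flow = runner.flow(400.0, 90.0, 115.0)
        v = channel_mean_velocity(flow, spec)
        assert v < 1e-2 * flow.bulk_velocity

    def test_mirror_symmetry_at_90_degrees(self, runner):
        flow = runner.flow(400.0, 90.0, 115.0)
        pts = np.column_stack(
            [np.linspace(-3.5e-3, 3.5e-3, 41), np.full(41, 1.1e-3)]
        )
        up = flow.interpolate_velocity(pts)
        um = flow.interpolate_velocity(pts * np.array([1.0, -1.0]))
        scale = np.abs(up).max()
        assert np.max(np.abs(up[:, 0] - um[:, 0])) < 0.05 * scale
        assert np.max(np.abs(up[:, 1] + um[:, 1])) < 0.05 * scale

    def test_channel_velocity_decreases_with_angle(self):
        # coarse meshes suffice for the monotone trend
        vals = []
        for angle in (0.0, 30.0, 60.0, 90.0):
            spec = DeviceGeometry(channel_width=400e-6, channel_angle=angle)
            mesh = generate_mesh(build_device_geometry(spec), 60e-6, 1e-3)
            flow = solve_stokes(mesh, U_REF)
            vals.append(channel_mean_velocity(flow, spec))
        assert all(a >= b for a, b in zip(vals, vals[1:]))


def test_missing_outlet_is_diagnosed_by_tag_name():
    mesh = rectangle_mesh(
        2e-3, 1e-3, 8, 4, edge_tags={"right": "chamber_wall"}
    )
    with pytest.raises(StokesError, match="outlet"):
        solve_stokes(mesh, U_REF)


def test_channel_summaries_reject_degenerate_inputs(runner):
    solid = runner.device(0.0, 0.0)
    flow = runner.flow(600.0, 0.0, 1150.0)
    with pytest.raises(ValueError):
        channel_mean_velocity(flow, solid)
    assert fluid_collection_efficiency(flow, solid) == 0.0
    with pytest.raises(ValueError):
        fluid_collection_efficiency(solve_stokes(runner.mesh(0.0, 0.0), 0.0), solid)
    with pytest.raises(StokesError):
        solve_stokes(runner.mesh(0.0, 0.0), -1.0)
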