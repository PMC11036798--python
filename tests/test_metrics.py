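"""Derived metrics: dimensionless numbers, surface fractions, and the
field-based metrics on manufactured states."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macropore.geometry import DISC, TAG_ARC, TAG_CHANNEL, DeviceGeometry
from macropore.growth import GrowthParams, SimulationState
from macropore.meshing import rectangle_mesh
from macropore.metrics import (
    anoxic_area_fraction,
    channel_flux_contribution,
    channel_surface_fraction,
    delineation_curve,
    pe_binned_oxic_fractions,
    peclet,
    penetration_depth,
    relative_biomass_increase,
    sherwood_flux_ratio,
)


def make_state(mesh, C, B, U=115e-6, flux=None):
    """Manufactured simulation state for metric unit tests."""
    return SimulationState(
        mesh=mesh,
        params=GrowthParams(),
        bulk_velocity=U,
        t=86400.0,
        C=np.asarray(C, dtype=float),
        B=np.asarray(B, dtype=float),
        history=pd.DataFrame(),
        interface_flux=flux or {TAG_CHANNEL: 0.0, TAG_ARC: 0.0},
        interface_flux_integrated=flux or {TAG_CHANNEL: 0.0, TAG_ARC: 0.0},
        balance={},
        clamp_events=0,
    )


class TestPeclet:
    def test_pore_scale_example_gives_unity(self):
        # 50 um pore radius (100 um diameter), 10 um/s, D = 1e-9 m^2/s
        assert peclet(100e-6, 10e-6, 1e-9) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert peclet(300e-6, 50e-6, 1e-9) == pytest.approx(15.0)

    def test_zero_velocity(self):
        assert peclet(1e-4, 0.0, 1e-9) == 0.0

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            peclet(0.0, 1e-6, 1e-9)
        with pytest.raises(ValueError):
            peclet(1e-4, 1e-6, 0.0)
        with pytest.raises(ValueError):
            peclet(1e-4, -1e-6, 1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        L=st.floats(1e-7, 1e-2),
        v=st.floats(0, 1e-2),
        D=st.floats(1e-11, 1e-8),
        k=st.floats(0.1, 10),
    )
    def test_linearity_and_delineation_identity(self, L, v, D, k):
        assert peclet(L, k * v, D) == pytest.approx(k * peclet(L, v, D), rel=1e-12)
        assert peclet(k * L, v, D) == pytest.approx(k * peclet(L, v, D), rel=1e-12)
        # v(L) * L / D = 1 identically on the Pe = 1 curve
        assert delineation_curve(D, L) * L / D == pytest.approx(1.0, rel=1e-12)


class TestDelineation:
    def test_oxygen_at_100um_pore(self):
        assert delineation_curve(1e-9, 100e-6) == pytest.approx(10e-6)

    def test_sucrose_diffusivity(self):
        assert delineation_curve(4.8e-10, 100e-6) == pytest.approx(4.8e-6)

    def test_halving_D_halves_the_curve(self):
        L = np.geomspace(1e-6, 1e-3, 20)
        assert np.allclose(delineation_curve(5e-10, L), 0.5 * delineation_curve(1e-9, L))


class TestSurfaceFraction:
    def test_axial_length_convention_is_39_percent(self):
        assert channel_surface_fraction(DeviceGeometry(), "axial_length") == pytest.approx(
            38.9, abs=0.05
        )

    def test_chord_mode_600um(self):
        spec = DeviceGeometry(channel_width=600e-6)
        assert channel_surface_fraction(spec, "chord") == pytest.approx(41.7, abs=0.05)

    def test_chord_mode_solid_disc_is_zero(self):
        assert channel_surface_fraction(DeviceGeometry(), "chord") == 0.0


@pytest.fixture(scope="module")
def disc_box():
    return rectangle_mesh(1e-3, 1e-3, 8, 8, region=DISC)


class TestFieldMetrics:
    def test_anoxic_fraction_extremes(self, disc_box):
        n = disc_box.n_nodes
        sat = make_state(disc_box, np.full(n, 0.258), np.zeros(n))
        dead = make_state(disc_box, np.zeros(n), np.zeros(n))
        assert anoxic_area_fraction(sat) == 0.0
        assert anoxic_area_fraction(dead) == 100.0
        assert anoxic_area_fraction(sat) + (100 - anoxic_area_fraction(sat)) == 100.0

    def test_relative_biomass_identity_and_manufactured_doubling(self, disc_box):
        n = disc_box.n_nodes
        B = np.full(n, 1e15)
        a = make_state(disc_box, np.zeros(n), B)
        assert relative_biomass_increase(a, a) == 0.0
        # doubling B at the nodes with x < 0.5 mm doubles the lumped mass
        # they carry: on the structured 8x8 grid the nodal control volumes
        # of those columns cover (0.5 mm - h/2) of the length (h = 1/8 mm),
        # i.e. a hand-computed 43.75% increase (-> 50% as h -> 0)
        B2 = B.copy()
        B2[disc_box.points[:, 0] < 0.5e-3 - 1e-9] *= 2
        b = make_state(disc_box, np.zeros(n), B2)
        assert relative_biomass_increase(b, a) == pytest.approx(43.75, rel=1e-9)

    def test_mismatched_velocity_rejected(self, disc_box):
        n = disc_box.n_nodes
        a = make_state(disc_box, np.zeros(n), np.full(n, 1e15), U=115e-6)
        b = make_state(disc_box, np.zeros(n), np.full(n, 1e15), U=11.5e-6)
        with pytest.raises(ValueError):
            relative_biomass_increase(a, b)

    def test_channel_flux_contribution_symmetric_fixture(self, disc_box):
        n = disc_box.n_nodes
        st_ = make_state(
            disc_box,
            np.zeros(n),
            np.zeros(n),
            flux={TAG_CHANNEL: 2.5e-10, TAG_ARC: 2.5e-10},
        )
        spec = DeviceGeometry(channel_width=400e-6)
        assert channel_flux_contribution(st_, spec) == pytest.approx(50.0)
        with pytest.raises(ValueError):
            channel_flux_contribution(st_, DeviceGeometry())

    def test_sherwood_identity_and_errors(self, disc_box):
        n = disc_box.n_nodes
        ref = make_state(
            disc_box, np.zeros(n), np.zeros(n), U=0.0, flux={TAG_CHANNEL: 0.0, TAG_ARC: 1e-10}
        )
        assert sherwood_flux_ratio(ref, ref) == pytest.approx(1.0)
        moving = make_state(
            disc_box, np.zeros(n), np.zeros(n), U=1e-4, flux={TAG_CHANNEL: 0.0, TAG_ARC: 1e-10}
        )
        with pytest.raises(ValueError):
            sherwood_flux_ratio(ref, moving)  # reference must be no-flow
        dead = make_state(
            disc_box, np.zeros(n), np.zeros(n), U=0.0, flux={TAG_CHANNEL: 0.0, TAG_ARC: 0.0}
        )
        with pytest.raises(ValueError):
            sherwood_flux_ratio(ref, dead)


class TestPenetrationDepth:
    def test_saturated_channel_reports_full(self, runner):
        spec = runner.device(400.0, 30.0)
        mesh = runner.mesh(400.0, 30.0)
        n = mesh.n_nodes
        sat = make_state(mesh, np.full(n, 0.258), np.zeros(n))
        assert math.isinf(penetration_depth(sat, spec))

    def test_threshold_crossing_is_interpolated(self, runner):
        spec = runner.device(400.0, 30.0)
        mesh = runner.mesh(400.0, 30.0)
        ent = spec.windward_entrance()
        axis = spec.channel_axis
        s = (mesh.points - ent) @ axis
        # linear decay crossing 1 umol/L at 1 mm from the entrance
        C = 0.258 * np.maximum(1.0 - s / 1.00388e-3, 0.0)
        state = make_state(mesh, C, np.zeros(mesh.n_nodes))
        assert penetration_depth(state, spec) == pytest.approx(1e-3, rel=0.02)

    def test_solid_disc_rejected(self, runner):
        mesh = runner.mesh(0.0, 0.0)
        state = make_state(mesh, np.zeros(mesh.n_nodes), np.zeros(mesh.n_nodes))
        with pytest.raises(ValueError):
            penetration_depth(state, runner.device(0.0, 0.0))


def test_pe_binned_means():
    lo, hi = pe_binned_oxic_fractions([0.1, 0.5, 10.0, 20.0], [96.0, 94.0, 90.0, 86.0])
    assert lo == pytest.approx(5.0)
    assert hi == pytest.approx(12.0)
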