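"""Cached end-to-end case runner: geometry -> mesh -> Stokes -> 24 h growth.

A :class:`CaseRunner` memoises meshes, flow fields and simulation states
per (width, angle, velocity) so that sweeps, tests and the acceptance
script can share the expensive 24 h integrations.  Two resolution scales
are provided:

``full``  h_boundary 20 um, h_max 1 mm, dt 2.4 s  (reference twin)
``test``  h_boundary 40 um, h_max 1 mm, dt 12 s   (documented scaled-down
          configuration; every reported number holds there)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import DeviceGeometry, Domain, build_device_geometry
from .growth import GrowthParams, SimulationState, reference_params, simulate_growth
from .meshing import Mesh, generate_mesh
from .metrics import (
    anoxic_area_fraction,
    channel_flux_contribution,
    peclet,
    penetration_depth,
    relative_biomass_increase,
    sherwood_flux_ratio,
)
from .stokes import (
    FlowField,
    channel_mean_velocity,
    fluid_collection_efficiency,
    solve_stokes,
)

SCALES = {
    "full": {"h_boundary": 20e-6, "h_max": 1e-3, "dt": 2.4},
    "test": {"h_boundary": 40e-6, "h_max": 1e-3, "dt": 12.0},
}

#: the three bulk velocities of the study, m/s
BULK_VELOCITIES = (11.5e-6, 115e-6, 1150e-6)


@dataclass(frozen=True)
class CaseKey:
    width_um: float
    angle_deg: float
    U_um_s: float


class CaseRunner:
    """Memoising pipeline driver at a fixed resolution scale."""

    def __init__(
        self,
        scale: str = "test",
        params: GrowthParams | None = None,
        t_end: float = 86400.0,
        geometry_overrides: dict | None = None,
    ):
        if scale not in SCALES:
            raise ValueError(f"unknown scale {scale!r}; pick from {sorted(SCALES)}")
        self.scale = scale
        self.resolution = SCALES[scale]
        self.params = params or reference_params()
        self.t_end = t_end
        self.geometry_overrides = geometry_overrides or {}
        self._domains: dict = {}
        self._meshes: dict = {}
        self._flows: dict = {}
        self._states: dict = {}

    # -- pipeline stages -------------------------------------------------
    def device(self, width_um: float, angle_deg: float) -> DeviceGeometry:
        return DeviceGeometry(
            channel_width=width_um * 1e-6,
            channel_angle=angle_deg,
            **self.geometry_overrides,
        )

    def domain(self, width_um: float, angle_deg: float) -> Domain:
        key = (width_um, angle_deg)
        if key not in self._domains:
            self._domains[key] = build_device_geometry(self.device(*key))
        return self._domains[key]

    def mesh(self, width_um: float, angle_deg: float) -> Mesh:
        key = (width_um, angle_deg)
        if key not in self._meshes:
            self._meshes[key] = generate_mesh(
                self.domain(*key),
                self.resolution["h_boundary"],
                self.resolution["h_max"],
            )
        return self._meshes[key]

    def flow(self, width_um: float, angle_deg: float, U_um_s: float) -> FlowField:
        key = (width_um, angle_deg, U_um_s)
        if key not in self._flows:
            self._flows[key] = solve_stokes(
                self.mesh(width_um, angle_deg), U_um_s * 1e-6
            )
        return self._flows[key]

    def state(
        self, width_um: float, angle_deg: float, U_um_s: float
    ) -> SimulationState:
        key = (width_um, angle_deg, U_um_s)
        if key not in self._states:
            flow = self.flow(*key) if U_um_s > 0 else None
            self._states[key] = simulate_growth(
                self.mesh(width_um, angle_deg),
                flow,
                params=self.params,
                t_end=self.t_end,
                dt=self.resolution["dt"],
            )
        return self._states[key]

    # -- metric helpers --------------------------------------------------
    def channel_peclet(self, width_um: float, angle_deg: float, U_um_s: float) -> float:
        """Channel Peclet number: width x mean channel velocity / D_ox."""
        if width_um <= 0:
            return 0.0
        spec = self.device(width_um, angle_deg)
        v = channel_mean_velocity(self.flow(width_um, angle_deg, U_um_s), spec)
        return peclet(spec.channel_width, v, self.params.D_ox)

    def sherwood(self, U_um_s: float) -> float:
        """Solid-disc Sherwood number at a bulk velocity (flux ratio
        against the no-flow reference)."""
        return sherwood_flux_ratio(self.state(0.0, 0.0, U_um_s), self.state(0.0, 0.0, 0.0))

    def metrics_row(
        self, width_um: float, angle_deg: float, U_um_s: float, sherwood: bool = False
    ) -> dict:
        """One sweep-results row with every reported metric."""
        spec = self.device(width_um, angle_deg)
        state = self.state(width_um, angle_deg, U_um_s)
        row: dict = {
            "angle_deg": angle_deg,
            "width_um": width_um,
            "U_um_s": U_um_s,
        }
        if spec.has_channel:
            flow = self.flow(width_um, angle_deg, U_um_s)
            v = channel_mean_velocity(flow, spec)
            row["channel_v_um_s"] = v * 1e6
            row["Pe_channel"] = peclet(spec.channel_width, v, self.params.D_ox)
            row["collection_eff_pct"] = fluid_collection_efficiency(flow, spec)
            depth = penetration_depth(state, spec)
            row["penetration_full"] = not math.isfinite(depth)
            row["penetration_um"] = (
                spec.channel_length() * 1e6 if not math.isfinite(depth) else depth * 1e6
            )
            row["channel_flux_pct"] = channel_flux_contribution(state, spec)
        else:
            row.update(
                channel_v_um_s=0.0,
                Pe_channel=0.0,
                collection_eff_pct=0.0,
                penetration_full=False,
                penetration_um=float("nan"),
                channel_flux_pct=float("nan"),
            )
        row["anoxic_pct"] = anoxic_area_fraction(state)
        row["total_biomass"] = state.total_biomass()
        control = self._states.get((0.0, 0.0, U_um_s))
        row["rel_biomass_pct"] = (
            relative_biomass_increase(state, control) if control is not None else float("nan")
        )
        row["Sh"] = self.sherwood(U_um_s) if sherwood and U_um_s > 0 else float("nan")
        return row
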