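"""Derived transport and growth metrics of the disc-in-flow system.

All quantities the analysis reports are computed here from geometry,
flow and simulation state: Peclet numbers, the advection/diffusion
delineation curve, oxygen penetration depth along the channel, anoxic
area fraction, relative biomass increase against a solid-disc control,
the channel's share of the oxygen supply, geometric surface fractions,
and the Sherwood number as a with-flow/no-flow flux ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import matplotlib.tri as mtri
import numpy as np

from .geometry import DISC, TAG_ARC, TAG_CHANNEL, DeviceGeometry
from .growth import SimulationState

#: anoxia threshold, 1 umol/L in mol/m^3
ANOXIA_THRESHOLD = 1e-3


@dataclass(frozen=True)
class TransportRegime:
    """A (length, velocity, diffusivity) triple and its dimensionless
    transport numbers."""

    L: float
    v: float
    D: float
    Sh: float | None = None

    @property
    def Pe(self) -> float:
        return peclet(self.L, self.v, self.D)


def peclet(L: float, v: float, D: float) -> float:
    """Peclet number L*v/D: ratio of advective to diffusive transport."""
    if L <= 0 or D <= 0:
        raise ValueError("length scale and diffusivity must be positive")
    if v < 0:
        raise ValueError("velocity must be nonnegative")
    return L * v / D


def delineation_curve(D: float, L) -> np.ndarray:
    """Velocity v(L) = D/L at which Pe = 1, delineating diffusion- from
    advection-dominated supply for an entity of diffusivity D."""
    if D <= 0:
        raise ValueError("diffusivity must be positive")
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("pore sizes must be positive")
    return D / L


def channel_oxygen_profile(
    state: SimulationState, spec: DeviceGeometry, n_samples: int = 1201
):
    """Oxygen concentration along the channel centreline, measured from
    the windward entrance (arc length s, concentration C(s))."""
    if not spec.has_channel:
        raise ValueError("solid disc has no channel centreline")
    ent = spec.windward_entrance()
    axis = spec.channel_axis
    s = np.linspace(0.0, spec.channel_length(), n_samples)
    pts = ent + s[:, None] * axis
    mesh = state.mesh
    tri = mtri.Triangulation(mesh.points[:, 0], mesh.points[:, 1], mesh.triangles)
    C = mtri.LinearTriInterpolator(tri, state.C)(pts[:, 0], pts[:, 1])
    return s, C.filled(np.nan)


def penetration_depth(
    state: SimulationState,
    spec: DeviceGeometry,
    threshold: float = ANOXIA_THRESHOLD,
) -> float:
    """Distance from the windward channel entrance at which centreline
    oxygen first falls below ``threshold`` (m).

    Returns ``math.inf`` ("full penetration") when oxygen never crosses
    the threshold along the whole channel.  The first crossing is located
    by linear interpolation between centreline samples."""
    s, C = channel_oxygen_profile(state, spec)
    ok = np.isfinite(C)
    s, C = s[ok], C[ok]
    below = np.flatnonzero(C < threshold)
    if len(below) == 0:
        return math.inf
    i = below[0]
    if i == 0:
        return float(s[0])
    f = (threshold - C[i - 1]) / (C[i] - C[i - 1])
    return float(s[i - 1] + f * (s[i] - s[i - 1]))


def anoxic_area_fraction(
    state: SimulationState, threshold: float = ANOXIA_THRESHOLD
) -> float:
    """Percentage of the disc area where oxygen is below ``threshold``
    (element-mean concentration, area-weighted)."""
    mesh = state.mesh
    sel = mesh.region == DISC
    c_el = state.C[mesh.triangles[sel]].mean(axis=1)
    areas = mesh.triangle_areas[sel]
    return float(100.0 * areas[c_el < threshold].sum() / areas.sum())


def relative_biomass_increase(
    run: SimulationState, solid_control: SimulationState
) -> float:
    """Percentage increase of disc-integrated biomass over a solid-disc
    control grown under the same bulk velocity."""
    if not math.isclose(
        run.bulk_velocity, solid_control.bulk_velocity, rel_tol=1e-9, abs_tol=1e-15
    ):
        raise ValueError(
            "control was grown at a different bulk velocity "
            f"({solid_control.bulk_velocity} vs {run.bulk_velocity})"
        )
    ref = solid_control.total_biomass()
    return float(100.0 * (run.total_biomass() - ref) / ref)


def channel_flux_contribution(
    state: SimulationState, spec: DeviceGeometry, time_integrated: bool = False
) -> float:
    """Channel walls' share (%) of the total diffusive oxygen supply into
    the disc (channel walls + disc arcs).

    Instantaneous fluxes at the final simulated time by default;
    ``time_integrated=True`` uses the time integrals instead."""
    if not spec.has_channel:
        raise ValueError("channel flux contribution undefined for a solid disc")
    flux = state.interface_flux_integrated if time_integrated else state.interface_flux
    ch = flux[TAG_CHANNEL]
    arc = flux[TAG_ARC]
    total = ch + arc
    if total <= 0:
        raise ValueError("no net oxygen influx into the disc")
    return float(np.clip(100.0 * ch / total, 0.0, 100.0))


def channel_surface_fraction(spec: DeviceGeometry, mode: str = "axial_length") -> float:
    """Channel walls' share (%) of the disc surface.

    ``axial_length``: both channel walls counted at the disc diameter
    against the full circle perimeter, 100 * 2d / (2d + pi d) -- the
    geometric convention that yields 39% for any disc.  ``chord``: exact
    chord lengths against the remaining arcs."""
    if mode == "axial_length":
        return 100.0 * 2.0 / (2.0 + math.pi)
    if mode == "chord":
        if not spec.has_channel:
            return 0.0
        ch = 2.0 * spec.chord_length()
        arc = spec.arc_length_total()
        return 100.0 * ch / (ch + arc)
    raise ValueError(f"unknown mode {mode!r}")


def sherwood_flux_ratio(
    run: SimulationState,
    no_flow_run: SimulationState,
    time_integrated: bool = True,
) -> float:
    """Sherwood number of the disc as the ratio of the time-integrated
    oxygen flux across the disc arc with flow to the same quantity
    without flow (instantaneous final-time fluxes on request).

    Both runs must be solid discs differing only in bulk velocity (the
    reference at U = 0)."""
    if no_flow_run.bulk_velocity != 0:
        raise ValueError("reference run must have zero bulk velocity")
    fw = (
        run.interface_flux_integrated if time_integrated else run.interface_flux
    )[TAG_ARC]
    f0 = (
        no_flow_run.interface_flux_integrated
        if time_integrated
        else no_flow_run.interface_flux
    )[TAG_ARC]
    if f0 <= 0:
        raise ValueError("vanishing no-flow reference flux")
    return float(fw / f0)


def pe_binned_oxic_fractions(pe, anoxic_pct):
    """Mean oxic area percentage for diffusion- (Pe < 1) and advection-
    dominated (Pe > 1) sweep rows.  Returns ``(oxic_low_pe, oxic_high_pe)``
    with NaN for an empty bin."""
    pe = np.asarray(pe, dtype=float)
    oxic = 100.0 - np.asarray(anoxic_pct, dtype=float)
    lo = oxic[pe < 1.0]
    hi = oxic[pe > 1.0]
    return (
        float(lo.mean()) if len(lo) else float("nan"),
        float(hi.mean()) if len(hi) else float("nan"),
    )
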