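"""Parametric 2D geometry of the millifluidic device.

The device is a plan-view (2D) model of one chamber unit: a circular flow
chamber (default 8 mm diameter) with an inlet and an outlet connector
(default 5 mm wide) on the bulk-flow axis, containing a hydrogel disc
(default 3 mm diameter) centred in the chamber.  The disc is optionally
bisected by a straight channel of width ``w`` whose axis passes through the
disc centre at an angle ``theta`` (degrees) from the bulk-flow (+x) axis,
leaving two semi-disc obstacles.

Boundary tags partition the full boundary:

``inlet``         left face of the inlet connector (Dirichlet velocity)
``outlet``        right face of the outlet connector (do-nothing)
``chamber_wall``  remaining outer walls (no-slip, oxygen-saturated)
``disc_arc``      circular arcs of the two semi-discs (no-slip)
``channel_wall``  the two flat chord faces bounding the channel (no-slip)

All lengths are SI metres; angles are degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

FLUID = 0
DISC = 1

TAG_INLET = "inlet"
TAG_OUTLET = "outlet"
TAG_CHAMBER = "chamber_wall"
TAG_ARC = "disc_arc"
TAG_CHANNEL = "channel_wall"

ALL_TAGS = (TAG_INLET, TAG_OUTLET, TAG_CHAMBER, TAG_ARC, TAG_CHANNEL)


class GeometryError(ValueError):
    """Raised for infeasible device specifications."""


@dataclass(frozen=True)
class DeviceGeometry:
    """Dimensions of one chamber unit with a (possibly solid) disc.

    ``channel_width = 0`` describes a solid disc.  ``channel_angle`` is the
    angle between the channel axis and the bulk-flow (+x) axis, in degrees,
    restricted to [0, 90] (the geometry is mirror-symmetric beyond that).
    """

    chamber_diameter: float = 8e-3
    connector_width: float = 5e-3
    connector_length: float = 5e-3
    disc_diameter: float = 3e-3
    channel_width: float = 0.0
    channel_angle: float = 0.0
    disc_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.channel_width < 0 or self.channel_width >= self.disc_diameter:
            raise GeometryError(
                f"channel width {self.channel_width} must satisfy "
                f"0 <= w < disc diameter {self.disc_diameter}"
            )
        if not 0.0 <= self.channel_angle <= 90.0:
            raise GeometryError(
                f"channel angle {self.channel_angle} outside [0, 90] degrees"
            )
        if self.disc_diameter >= self.chamber_diameter:
            raise GeometryError("disc does not fit inside the chamber")
        if self.connector_width > self.chamber_diameter:
            raise GeometryError("connector wider than the chamber")
        if self.connector_length <= 0:
            raise GeometryError("connector length must be positive")

    # -- derived scalars -------------------------------------------------
    @property
    def disc_radius(self) -> float:
        return 0.5 * self.disc_diameter

    @property
    def has_channel(self) -> bool:
        return self.channel_width > 0.0

    @property
    def channel_axis(self) -> np.ndarray:
        """Unit vector along the channel axis (undefined direction sign
        resolved towards +x, i.e. pointing leeward)."""
        th = math.radians(self.channel_angle)
        return np.array([math.cos(th), math.sin(th)])

    @property
    def channel_normal(self) -> np.ndarray:
        th = math.radians(self.channel_angle)
        return np.array([-math.sin(th), math.cos(th)])

    def chord_length(self) -> float:
        """Length of each flat chord face bounding the channel."""
        if not self.has_channel:
            return 0.0
        r, hw = self.disc_radius, 0.5 * self.channel_width
        return 2.0 * math.sqrt(r * r - hw * hw)

    def channel_length(self) -> float:
        """Centreline length of the channel between its two mouth planes
        (the planes through the chord-face corners); equals the chord
        length and approaches the disc diameter for narrow channels."""
        return self.chord_length()

    def disc_region_area(self) -> float:
        """Analytic area of the two semi-discs (circle minus slab)."""
        r = self.disc_radius
        if not self.has_channel:
            return math.pi * r * r
        h = 0.5 * self.channel_width
        seg = r * r * math.acos(h / r) - h * math.sqrt(r * r - h * h)
        return 2.0 * seg

    def arc_length_total(self) -> float:
        """Total circular-arc length of the semi-disc boundaries."""
        r = self.disc_radius
        if not self.has_channel:
            return 2.0 * math.pi * r
        alpha = math.asin(0.5 * self.channel_width / r)
        return 2.0 * r * (math.pi - 2.0 * alpha)

    def windward_entrance(self) -> np.ndarray | None:
        """Centreline point of the channel mouth facing the inlet (None
        for solid discs).

        The mouth plane passes through the windward chord-face corners,
        half a chord length from the disc centre along the axis.  The
        channel axis points leeward (positive x-component), so the
        windward mouth is upstream; at 90 degrees this degenerates to the
        lower mouth, a deterministic convention."""
        if not self.has_channel:
            return None
        return (
            np.asarray(self.disc_center)
            - 0.5 * self.chord_length() * self.channel_axis
        )


@dataclass(frozen=True)
class Segment:
    """One analytic boundary piece: a line or a circular arc."""

    kind: str  # "line" | "arc"
    tag: str
    # line: (x0, y0, x1, y1); arc: (cx, cy, radius, angle0, angle1) CCW
    data: tuple

    def length(self) -> float:
        if self.kind == "line":
            x0, y0, x1, y1 = self.data
            return math.hypot(x1 - x0, y1 - y0)
        _, _, r, a0, a1 = self.data
        return r * (a1 - a0)

    def sample(self, h: float) -> np.ndarray:
        """Points along the segment at spacing <= h, excluding the final
        endpoint (loops are closed by concatenation)."""
        n = max(1, int(math.ceil(self.length() / h)))
        t = np.linspace(0.0, 1.0, n + 1)[:-1]
        if self.kind == "line":
            x0, y0, x1, y1 = self.data
            return np.column_stack([x0 + t * (x1 - x0), y0 + t * (y1 - y0)])
        cx, cy, r, a0, a1 = self.data
        ang = a0 + t * (a1 - a0)
        return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


@dataclass
class Domain:
    """Labelled planar domain: one outer fluid loop plus disc loops.

    Loops are counter-clockwise lists of :class:`Segment`.  ``disc_loops``
    holds one loop per semi-disc (one full circle for a solid disc).
    """

    spec: DeviceGeometry
    outer_loop: list[Segment] = field(default_factory=list)
    disc_loops: list[list[Segment]] = field(default_factory=list)

    @property
    def windward_entrance(self) -> np.ndarray | None:
        return self.spec.windward_entrance()

    def channel_wall_length(self) -> float:
        return sum(
            s.length() for loop in self.disc_loops for s in loop if s.tag == TAG_CHANNEL
        )

    def boundary_tags_present(self) -> set[str]:
        tags = {s.tag for s in self.outer_loop}
        tags |= {s.tag for loop in self.disc_loops for s in loop}
        return tags

    def sample_loop(self, loop: list[Segment], h: float):
        """Sample a closed loop; returns (points, edge_tags) where edge i
        connects point i to point (i+1) % n."""
        pts, tags = [], []
        for seg in loop:
            p = seg.sample(h)
            pts.append(p)
            tags.extend([seg.tag] * len(p))
        return np.vstack(pts), np.array(tags)


def _rot(theta_deg: float) -> np.ndarray:
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, -s], [s, c]])


def build_device_geometry(spec: DeviceGeometry) -> Domain:
    """Construct the labelled boundary loops for a device specification.

    The outer loop runs counter-clockwise: inlet-connector floor, lower
    chamber arc, outlet-connector floor, outlet face, outlet-connector
    ceiling, upper chamber arc, inlet-connector ceiling, inlet face.  Disc
    loops are counter-clockwise so the disc region lies to their left.
    """
    rc = 0.5 * spec.chamber_diameter
    hw = 0.5 * spec.connector_width
    if hw >= rc:
        raise GeometryError("connector half-width must be below chamber radius")
    cx, cy = spec.disc_center
    # junction abscissa where connector walls meet the chamber circle
    xj = math.sqrt(rc * rc - hw * hw)
    aj = math.atan2(hw, xj)  # half-opening angle of the connector mouth
    x_in = -(xj + spec.connector_length)
    x_out = xj + spec.connector_length

    outer = [
        Segment("line", TAG_CHAMBER, (x_in, -hw, -xj, -hw)),
        Segment("arc", TAG_CHAMBER, (0.0, 0.0, rc, math.pi + aj, 2 * math.pi - aj)),
        Segment("line", TAG_CHAMBER, (xj, -hw, x_out, -hw)),
        Segment("line", TAG_OUTLET, (x_out, -hw, x_out, hw)),
        Segment("line", TAG_CHAMBER, (x_out, hw, xj, hw)),
        Segment("arc", TAG_CHAMBER, (0.0, 0.0, rc, aj, math.pi - aj)),
        Segment("line", TAG_CHAMBER, (-xj, hw, x_in, hw)),
        Segment("line", TAG_INLET, (x_in, hw, x_in, -hw)),
    ]

    r = spec.disc_radius
    loops: list[list[Segment]] = []
    if not spec.has_channel:
        loops.append([Segment("arc", TAG_ARC, (cx, cy, r, 0.0, 2 * math.pi))])
    else:
        whalf = 0.5 * spec.channel_width
        alpha = math.asin(whalf / r)
        xc = math.sqrt(r * r - whalf * whalf)
        R = _rot(spec.channel_angle)

        def tr(p):
            q = R @ np.asarray(p)
            return (q[0] + cx, q[1] + cy)

        th0 = math.radians(spec.channel_angle)
        # upper semi-disc (local y' >= w/2): chord west->east, arc CCW
        p0, p1 = tr((-xc, whalf)), tr((xc, whalf))
        loops.append(
            [
                Segment("line", TAG_CHANNEL, (*p0, *p1)),
                Segment("arc", TAG_ARC, (cx, cy, r, th0 + alpha, th0 + math.pi - alpha)),
            ]
        )
        # lower semi-disc (local y' <= -w/2): chord east->west, arc CCW
        q0, q1 = tr((xc, -whalf)), tr((-xc, -whalf))
        loops.append(
            [
                Segment("line", TAG_CHANNEL, (*q0, *q1)),
                Segment(
                    "arc",
                    TAG_ARC,
                    (cx, cy, r, th0 + math.pi + alpha, th0 + 2 * math.pi - alpha),
                ),
            ]
        )
    return Domain(spec=spec, outer_loop=outer, disc_loops=loops)
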