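"""Synthetic brightfield-like micrographs of colony-bearing hydrogel discs.

The generator emulates 16-bit tile scans of a 3 mm disc: bright colonies
(smooth super-Gaussian blobs) on a darker gel disc against the chamber
background, with additive Gaussian background noise and signal-dependent
shot noise.  Colony mean area decays exponentially with distance from the
nearest oxygen-exposed boundary (the disc arc, plus the channel walls),
optionally skewed towards the windward channel entrance to emulate
advective oxygen supply, and "anomalous" oversized colonies of known
excess area can be implanted near the channel -- the ground truth every
imaging-pipeline test is scored against.

The default pixel size (2.6 um/px) is a 4x binning of the microscope's
0.65 um/px so a full disc fits in a ~1300 px frame; the native scale is
available through the ``pixel_size_um`` field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DeviceGeometry


class PackingError(ValueError):
    """Colony density infeasible without overlap."""


@dataclass(frozen=True)
class SyntheticImageSpec:
    disc_diameter_um: float = 3000.0
    channel_width_um: float = 0.0  # 0 = solid disc
    channel_angle_deg: float = 0.0
    pixel_size_um: float = 2.6
    colony_density_per_mm2: float = 40.0
    base_area_um2: float = 2000.0  # mean colony area at an exposed boundary
    decay_length_um: float = 300.0  # radial decay of the mean area
    area_sigma: float = 0.25  # lognormal scatter of areas
    entrance_skew: float = 0.0  # extra size towards the windward entrance
    skew_length_um: float = 600.0
    #: implanted anomalous colonies: (distance from entrance along the
    #: channel axis, um; lateral offset into the gel, um; excess area, um2)
    anomalous: tuple = ()
    #: whether the channel walls count as nutrient-exposed boundaries in
    #: the size model; None = automatic (True when the emulated angle
    #: supports through-flow, i.e. below 90 degrees)
    channel_walls_exposed: bool | None = None
    background: float = 3000.0
    disc_level: float = 6000.0  # gel appears brighter than background
    amplitude: float = 30000.0  # peak colony signal above the gel
    noise_sigma: float = 60.0
    shot_scale: float = 0.3
    seed: int = 0

    def device(self) -> DeviceGeometry:
        return DeviceGeometry(
            disc_diameter=self.disc_diameter_um * 1e-6,
            channel_width=self.channel_width_um * 1e-6,
            channel_angle=self.channel_angle_deg,
        )


@dataclass
class ChannelTruth:
    angle_deg: float
    width_um: float
    length_um: float
    entrance_xy_um: tuple[float, float]


def _disc_mask(spec: SyntheticImageSpec, shape, origin_um, px):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = xx * px + origin_um[0]
    y = yy * px + origin_um[1]
    r = np.hypot(x, y)
    mask = r <= spec.disc_diameter_um / 2
    if spec.channel_width_um > 0:
        th = math.radians(spec.channel_angle_deg)
        n = -x * math.sin(th) + y * math.cos(th)  # signed distance to axis
        mask &= np.abs(n) >= spec.channel_width_um / 2
    return mask, x, y


def _boundary_distance_um(spec: SyntheticImageSpec, x, y):
    """Distance to the nearest oxygen-exposed boundary (arc or channel
    wall) for points inside the disc."""
    r = np.hypot(x, y)
    d_arc = spec.disc_diameter_um / 2 - r
    exposed = (
        spec.channel_walls_exposed
        if spec.channel_walls_exposed is not None
        else spec.channel_angle_deg < 90.0
    )
    if spec.channel_width_um <= 0 or not exposed:
        return d_arc
    th = math.radians(spec.channel_angle_deg)
    n = np.abs(-x * math.sin(th) + y * math.cos(th)) - spec.channel_width_um / 2
    return np.minimum(d_arc, n)


def _entrance_distance_um(spec: SyntheticImageSpec, x, y):
    if spec.channel_width_um <= 0:
        return np.full_like(np.asarray(x, dtype=float), np.nan)
    th = math.radians(spec.channel_angle_deg)
    ex = -math.cos(th) * spec.disc_diameter_um / 2
    ey = -math.sin(th) * spec.disc_diameter_um / 2
    return np.hypot(x - ex, y - ey)


def mean_area_model(spec: SyntheticImageSpec, x, y):
    """Mean colony area (um^2) at a position: exponential decay from the
    nearest exposed boundary, skewed towards the windward entrance."""
    d = _boundary_distance_um(spec, x, y)
    area = spec.base_area_um2 * np.exp(-np.maximum(d, 0.0) / spec.decay_length_um)
    if spec.entrance_skew > 0 and spec.channel_width_um > 0:
        de = _entrance_distance_um(spec, x, y)
        area = area * (1.0 + spec.entrance_skew * np.exp(-de / spec.skew_length_um))
    return area


def generate_micrograph(spec: SyntheticImageSpec):
    """Render one micrograph.

    Returns ``(image uint16, truth table, channel truth or None)``.  The
    truth table holds one row per colony: position (um, disc-centred
    coordinates), area (um^2), distances to the disc edge and windward
    entrance, and the anomalous flag.  Identical specs (same seed) yield
    byte-identical images."""
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    half = 0.6 * spec.disc_diameter_um
    npx = int(round(2 * half / px))
    origin = (-half, -half)
    mask, X, Y = _disc_mask(spec, (npx, npx), origin, px)

    disc_area_mm2 = mask.sum() * (px / 1000.0) ** 2
    n_target = rng.poisson(spec.colony_density_per_mm2 * disc_area_mm2)

    inside = np.flatnonzero(mask.ravel())
    xs, ys, areas, flags = [], [], [], []

    def _try_place(x, y, area, max_misses_ok=True):
        r = math.sqrt(area / math.pi)
        for xo, yo, ao in zip(xs, ys, areas):
            if math.hypot(x - xo, y - yo) < 1.15 * (r + math.sqrt(ao / math.pi)):
                return False
        xs.append(x)
        ys.append(y)
        areas.append(area)
        return True

    # anomalous colonies first (fixed positions near the channel)
    th = math.radians(spec.channel_angle_deg)
    ax, ay = math.cos(th), math.sin(th)
    nx, ny = -math.sin(th), math.cos(th)
    for s_um, off_um, excess in spec.anomalous:
        ex = -ax * spec.disc_diameter_um / 2
        ey = -ay * spec.disc_diameter_um / 2
        x = ex + ax * s_um + nx * (spec.channel_width_um / 2 + off_um)
        y = ey + ay * s_um + ny * (spec.channel_width_um / 2 + off_um)
        area = float(mean_area_model(spec, x, y)) + excess
        if not _try_place(x, y, area):
            raise PackingError("anomalous colonies overlap")
        flags.append(True)

    misses = 0
    while len(xs) < n_target + len(spec.anomalous) and misses < 200:
        i = rng.integers(0, len(inside))
        iy, ix = np.unravel_index(inside[i], mask.shape)
        x = X[iy, ix] + rng.uniform(-px / 2, px / 2)
        y = Y[iy, ix] + rng.uniform(-px / 2, px / 2)
        mu = float(mean_area_model(spec, x, y))
        area = mu * rng.lognormal(0.0, spec.area_sigma)
        if _try_place(x, y, area):
            flags.append(False)
            misses = 0
        else:
            misses += 1
    if len(xs) < 0.8 * (n_target + len(spec.anomalous)):
        raise PackingError(
            f"placed only {len(xs)} of {n_target} colonies; density infeasible"
        )

    # render: gel disc + super-Gaussian colony blobs
    img = np.full((npx, npx), spec.background, dtype=float)
    img[mask] = spec.disc_level
    # steep super-Gaussian edge: the radius is threshold-insensitive, so
    # the rendered area is the truth area for any reasonable segmentation
    EDGE_POWER = 16
    for x, y, area in zip(xs, ys, areas):
        r_half = math.sqrt(area / math.pi)
        r_e = r_half / math.log(2.0) ** (1.0 / EDGE_POWER)
        w = int(math.ceil(2.0 * r_half / px)) + 3
        cx = int(round((x - origin[0]) / px))
        cy = int(round((y - origin[1]) / px))
        x0, x1 = max(cx - w, 0), min(cx + w + 1, npx)
        y0, y1 = max(cy - w, 0), min(cy + w + 1, npx)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = origin[0] + np.arange(x0, x1) * px
        gy = origin[1] + np.arange(y0, y1) * px
        rho = np.hypot(gx[None, :] - x, gy[:, None] - y)
        img[y0:y1, x0:x1] += spec.amplitude * np.exp(-((rho / r_e) ** EDGE_POWER))

    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img += rng.normal(0.0, 1.0, img.shape) * spec.shot_scale * np.sqrt(
        np.maximum(img, 0.0)
    )
    img = np.clip(img, 0, 65535).astype(np.uint16)

    xs = np.array(xs)
    ys = np.array(ys)
    truth = pd.DataFrame(
        {
            "x_um": xs,
            "y_um": ys,
            "area_um2": np.array(areas),
            "dist_edge_um": _boundary_distance_um(spec, xs, ys),
            "dist_entrance_um": _entrance_distance_um(spec, xs, ys),
            "anomalous": np.array(flags, dtype=bool),
        }
    )

    channel = None
    if spec.channel_width_um > 0:
        channel = ChannelTruth(
            angle_deg=spec.channel_angle_deg,
            width_um=spec.channel_width_um,
            length_um=spec.disc_diameter_um,
            entrance_xy_um=(
                -ax * spec.disc_diameter_um / 2,
                -ay * spec.disc_diameter_um / 2,
            ),
        )
    return img, truth, channel


def generate_baseline_set(spec: SyntheticImageSpec, n_discs: int, seed: int = 0):
    """Solid-disc control replicates sharing the radial size model and
    differing only by seed-derived placement and noise."""
    if n_discs < 1:
        raise ValueError("need at least one disc")
    out = []
    for i in range(n_discs):
        s = SyntheticImageSpec(
            **{
                **spec.__dict__,
                "channel_width_um": 0.0,
                "entrance_skew": 0.0,
                "anomalous": (),
                "seed": seed + 1000 * i,
            }
        )
        img, truth, _ = generate_micrograph(s)
        out.append((img, truth))
    return out
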