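"""Micrograph quantification: disc classification, channel extraction,
colony segmentation, spatial profiles and the image-based biomass
estimator.

The workflow mirrors routine brightfield analysis of colonised hydrogel
discs:

1. classify each frame as a solid disc, a channel-bearing pair of
   semi-discs, or invalid (moved/merged discs), from circularity and the
   elongation shape factor of the disc foreground;
2. for semi-discs, isolate the channel gap with a morphological
   closing-residue (black-hat) after an opening-residue (white-hat)
   clean-up and measure its angle, width and length;
3. segment colonies (background removal, global Otsu threshold,
   connected components with optional watershed splitting);
4. relate colony sizes to distances from the oxygen-exposed boundaries,
   and estimate the advection-driven biomass increase by flagging
   colonies that exceed the solid-disc size-versus-depth envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

SOLID = "solid"
SEMI_DISC = "semi_disc"
INVALID = "invalid"


@dataclass
class DiscClassification:
    label: str
    circularity: float
    elongation: float
    mask: np.ndarray | None = None  # filled disc footprint (closed union)
    components: int = 0
    reason: str = ""


@dataclass
class ChannelMeasurement:
    mask: np.ndarray
    angle_deg: float
    width_um: float
    length_um: float
    entrance_xy_um: tuple[float, float]


class ChannelExtractionError(RuntimeError):
    def __init__(self, msg: str, fragments: int = 0):
        super().__init__(msg)
        self.fragments = fragments


def _drop_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    lbl, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = np.bincount(lbl.ravel())
    keep = np.flatnonzero(sizes >= min_px)
    keep = keep[keep > 0]
    return np.isin(lbl, keep)


def _binary_closing_edt(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Binary closing with a Euclidean disk via distance transforms
    (large structuring elements stay cheap this way)."""
    r = int(radius_px)
    padded = np.pad(mask, r + 1, constant_values=False)
    dil = ndimage.distance_transform_edt(~padded) <= r
    closed = ndimage.distance_transform_edt(dil) > r - 0.5
    return closed[r + 1 : -(r + 1), r + 1 : -(r + 1)]


def _shape_factors(mask: np.ndarray) -> tuple[float, float]:
    """Circularity 4 pi A / P^2 and the elongation shape factor (square
    root of the ratio of the second moments about the principal axes)."""
    lbl = measure.label(mask)
    props = measure.regionprops(lbl)
    p = max(props, key=lambda q: q.area)
    circ = 4.0 * math.pi * p.area / max(p.perimeter_crofton, 1e-9) ** 2
    l1, l2 = p.inertia_tensor_eigvals
    elong = math.sqrt(max(l1, l2) / max(min(l1, l2), 1e-12))
    return min(circ, 1.0), elong


def _foreground(image: np.ndarray) -> np.ndarray:
    """Disc footprint: everything brighter than the chamber background.

    The histogram has three modes (background, gel, colonies); the lower
    multi-Otsu threshold separates the disc from the background."""
    sm = filters.gaussian(image.astype(float), sigma=2, preserve_range=True)
    try:
        thr = filters.threshold_multiotsu(sm, classes=3)[0]
    except ValueError:  # degenerate histogram (e.g. blank frame)
        thr = filters.threshold_otsu(sm)
    fg = sm > thr
    fg = ndimage.binary_fill_holes(fg)
    return _drop_small(fg, max(64, fg.size // 5000))


def classify_disc(
    image: np.ndarray,
    pixel_size_um: float,
    circularity_min: float = 0.93,
    elongation_max: float = 1.10,
    close_radius_um: float = 400.0,
) -> DiscClassification:
    """Classify a frame as solid disc / semi-discs / invalid.

    A solid disc is a single near-circular object; a channel-bearing disc
    is two components whose morphological closure is near-circular.  The
    thresholds on circularity and the elongation shape factor are
    configurable (they are calibrated on the synthetic fixtures)."""
    fg = _foreground(image)
    n = int(measure.label(fg).max())
    if n == 0:
        return DiscClassification(INVALID, 0.0, 0.0, None, 0, "no object found")
    if n == 1:
        circ, elong = _shape_factors(fg)
        if circ >= circularity_min and elong <= elongation_max:
            return DiscClassification(SOLID, circ, elong, fg, 1)
        return DiscClassification(
            INVALID, circ, elong, fg, 1, "single non-circular object"
        )
    if n == 2:
        r_px = max(1, int(round(close_radius_um / pixel_size_um)))
        closed = _binary_closing_edt(fg, r_px)
        closed = ndimage.binary_fill_holes(closed)
        circ, elong = _shape_factors(closed)
        if circ >= circularity_min and elong <= elongation_max:
            return DiscClassification(SEMI_DISC, circ, elong, closed, 2)
        return DiscClassification(
            INVALID, circ, elong, closed, 2, "semi-discs shifted or merged"
        )
    return DiscClassification(INVALID, 0.0, 0.0, fg, n, f"{n} objects found")


def extract_channel(
    image: np.ndarray,
    classification: DiscClassification,
    pixel_size_um: float,
    se_radius_um: float = 350.0,
) -> ChannelMeasurement:
    """Isolate and measure the channel between the two semi-discs.

    The channel mask is the black-hat residue (closing minus image) of the
    white-hat-cleaned disc foreground, restricted to the closed disc
    footprint; the structuring element must be larger than the channel
    half-width.  The angle is the principal-axis orientation folded into
    [0, 90] degrees; width = area / length."""
    if classification.label != SEMI_DISC:
        raise ChannelExtractionError(
            f"channel extraction requires semi-discs, got {classification.label!r}"
        )
    # white-hat (opening residue) suppression of bright colony speckle is
    # implicit in the smoothed foreground; the black-hat residue of the
    # closed footprint (closing minus image support) is the channel gap
    fg = _foreground(image)
    r_px = max(1, int(round(se_radius_um / pixel_size_um)))
    closed = _binary_closing_edt(fg, r_px) if classification.mask is None else (
        classification.mask
    )
    chan = closed & ~fg
    chan = _drop_small(chan, 64)
    lbl = measure.label(chan)
    nfrag = int(lbl.max())
    if nfrag == 0:
        raise ChannelExtractionError("no channel found", fragments=0)
    if nfrag > 1:
        sizes = np.bincount(lbl.ravel())[1:]
        if sizes.max() < 0.8 * sizes.sum():
            raise ChannelExtractionError(
                f"channel mask fragmented into {nfrag} pieces", fragments=nfrag
            )
        chan = lbl == (1 + int(np.argmax(sizes)))

    ys, xs = np.nonzero(chan)
    pts = np.column_stack([xs, ys]).astype(float) * pixel_size_um
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    ang = math.degrees(math.atan2(axis[1], axis[0])) % 180.0
    folded = 180.0 - ang if ang > 90.0 else ang

    proj = (pts - c) @ axis
    length = float(proj.max() - proj.min())
    area_um2 = chan.sum() * pixel_size_um**2
    width = area_um2 / max(length, 1e-9)

    lo, hi = pts[int(np.argmin(proj))], pts[int(np.argmax(proj))]
    # windward = the end facing the oncoming (-x) flow; at 90 degrees fall
    # back to the lower-y mouth
    if abs(lo[0] - hi[0]) > 1e-6:
        ent = lo if lo[0] < hi[0] else hi
    else:
        ent = lo if lo[1] < hi[1] else hi
    return ChannelMeasurement(
        mask=chan,
        angle_deg=float(folded),
        width_um=float(width),
        length_um=length,
        entrance_xy_um=(float(ent[0]), float(ent[1])),
    )


def segment_colonies(
    image: np.ndarray,
    disc_mask: np.ndarray,
    pixel_size_um: float,
    background_radius_um: float = 120.0,
    min_area_px: int = 5,
    split_touching: bool = True,
) -> pd.DataFrame:
    """Segment bright colonies inside the disc footprint.

    Rolling-ball-style background removal (morphological white top-hat
    with a structuring element larger than any colony), global Otsu
    threshold, connected components, and optional watershed splitting of
    touching colonies.  Returns one row per colony with area (um^2),
    centroid (um, image coordinates) and distance to the disc edge (um).
    The result is invariant to a global intensity rescaling."""
    if disc_mask is None or not disc_mask.any():
        return pd.DataFrame(
            columns=["x_um", "y_um", "area_um2", "dist_edge_um"]
        )
    img = image.astype(float)
    # rolling-ball-style background: grayscale opening with a separable
    # square window (cheap even for large background radii); the outside
    # of the disc is filled with the median gel level first so the dark
    # chamber background cannot forge a bright rim in the residue
    fill = float(np.median(img[disc_mask]))
    img_f = np.where(disc_mask, img, fill)
    n = 2 * max(2, int(round(background_radius_um / pixel_size_um))) + 1
    background = ndimage.maximum_filter(
        ndimage.minimum_filter(img_f, size=n), size=n
    )
    top = img_f - background
    # keep clear of the smoothed gel-to-background transition ring
    det_mask = ndimage.binary_erosion(disc_mask, iterations=4)
    vals = top[det_mask]
    thr = filters.threshold_otsu(vals)
    # a threshold buried in the noise floor means there is nothing to
    # segment (Otsu always splits something, even pure noise)
    noise = 1.4826 * float(np.median(np.abs(vals - np.median(vals))))
    if thr < 6.0 * noise:
        return pd.DataFrame(columns=["x_um", "y_um", "area_um2", "dist_edge_um"])
    mask = (top > thr) & det_mask
    mask = _drop_small(mask, min_area_px)
    if not mask.any():
        return pd.DataFrame(columns=["x_um", "y_um", "area_um2", "dist_edge_um"])

    if split_touching:
        dist = ndimage.distance_transform_edt(mask)
        peaks = morphology.h_maxima(dist, 1.0)
        markers = measure.label(peaks)
        if markers.max() > 0:
            lbl = segmentation.watershed(-dist, markers, mask=mask)
        else:
            lbl = measure.label(mask)
    else:
        lbl = measure.label(mask)

    edge_dist = ndimage.distance_transform_edt(disc_mask) * pixel_size_um
    props = measure.regionprops(lbl)
    rows = []
    for p in props:
        if p.area < min_area_px:
            continue
        cy, cx = p.centroid
        rows.append(
            {
                "x_um": cx * pixel_size_um,
                "y_um": cy * pixel_size_um,
                "area_um2": p.area * pixel_size_um**2,
                "dist_edge_um": float(edge_dist[int(round(cy)), int(round(cx))]),
            }
        )
    return pd.DataFrame(rows)


def add_entrance_distance(
    colonies: pd.DataFrame, channel: ChannelMeasurement
) -> pd.DataFrame:
    """Append the distance from each colony to the windward channel
    entrance (um)."""
    out = colonies.copy()
    ex, ey = channel.entrance_xy_um
    out["dist_entrance_um"] = np.hypot(out["x_um"] - ex, out["y_um"] - ey)
    return out


def colony_size_profile(
    colonies: pd.DataFrame, bin_width_um: float = 250.0
) -> pd.DataFrame:
    """Binned mean +/- std of colony area versus distance from the
    windward channel entrance."""
    if colonies.empty or "dist_entrance_um" not in colonies:
        return pd.DataFrame(columns=["dist_um", "mean_area_um2", "std_area_um2", "n"])
    d = colonies["dist_entrance_um"].to_numpy()
    a = colonies["area_um2"].to_numpy()
    edges = np.arange(0.0, d.max() + bin_width_um, bin_width_um)
    idx = np.digitize(d, edges) - 1
    rows = []
    for k in range(len(edges) - 1):
        sel = idx == k
        if not sel.any():
            continue
        rows.append(
            {
                "dist_um": 0.5 * (edges[k] + edges[k + 1]),
                "mean_area_um2": float(a[sel].mean()),
                "std_area_um2": float(a[sel].std()),
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class BiomassIncreaseResult:
    percent: float
    colonies: pd.DataFrame  # semi-disc table with anomalous flags & excess
    baseline_trend: pd.DataFrame


def _depth_trend(
    tables: list[pd.DataFrame], bin_width_um: float, quantile: float
) -> pd.DataFrame:
    pooled = pd.concat(tables, ignore_index=True)
    d = pooled["dist_edge_um"].to_numpy()
    a = pooled["area_um2"].to_numpy()
    edges = np.arange(0.0, d.max() + bin_width_um, bin_width_um)
    idx = np.digitize(d, edges) - 1
    rows = []
    for k in range(len(edges) - 1):
        sel = idx == k
        if sel.sum() < 3:
            continue
        rows.append(
            {
                "dist_um": 0.5 * (edges[k] + edges[k + 1]),
                "mean_area_um2": float(a[sel].mean()),
                "envelope_um2": float(np.quantile(a[sel], quantile)),
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def biomass_increase_from_images(
    semi: pd.DataFrame,
    solid_baselines: list[pd.DataFrame],
    bin_width_um: float = 150.0,
    envelope_quantile: float = 0.995,
    envelope_margin: float = 1.15,
    min_baseline_colonies: int = 30,
) -> BiomassIncreaseResult:
    """Estimate the advection-driven biomass increase from colony tables.

    The solid-disc baselines define the size-versus-depth trend and its
    upper envelope (a per-depth quantile stretched by ``envelope_margin``
    so that ordinary size scatter is almost never flagged).  Colonies in
    the semi-disc exceeding the envelope at their depth are flagged
    anomalous and their excess area over the trend is attributed to
    advective supply:

        increase % = 100 * total / (total - excess) - 100
    """
    n_base = sum(len(t) for t in solid_baselines)
    if n_base < min_baseline_colonies:
        raise ValueError(
            f"only {n_base} baseline colonies; need >= {min_baseline_colonies}"
        )
    trend = _depth_trend(solid_baselines, bin_width_um, envelope_quantile)
    if trend.empty:
        raise ValueError("baseline trend could not be established")

    out = semi.copy()
    mean_i = np.interp(
        out["dist_edge_um"], trend["dist_um"], trend["mean_area_um2"]
    )
    env_i = envelope_margin * np.interp(
        out["dist_edge_um"], trend["dist_um"], trend["envelope_um2"]
    )
    out["anomalous"] = out["area_um2"].to_numpy() > env_i
    out["excess_um2"] = np.where(
        out["anomalous"], np.maximum(out["area_um2"] - mean_i, 0.0), 0.0
    )
    total = float(out["area_um2"].sum())
    excess = float(out["excess_um2"].sum())
    pct = 100.0 * total / max(total - excess, 1e-12) - 100.0
    return BiomassIncreaseResult(percent=pct, colonies=out, baseline_trend=trend)


def biomass_increase_multi_depth(
    semi_slices: list[pd.DataFrame],
    baseline_slices: list[list[pd.DataFrame]],
    **kwargs,
) -> float:
    """Average the per-slice biomass increase over imaging depths."""
    vals = [
        biomass_increase_from_images(s, b, **kwargs).percent
        for s, b in zip(semi_slices, baseline_slices)
    ]
    return float(np.mean(vals))
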