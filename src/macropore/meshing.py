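"""Graded triangular meshing of the labelled device domain.

The mesher builds a boundary-refined unstructured triangulation without an
external mesh generator:

1. every boundary loop is sampled at the target boundary spacing
   ``h_boundary`` (~20 um in the reference configuration);
2. interior points are laid out on deterministic hexagonal grids, one per
   size band, where the local target edge length grades linearly from
   ``h_boundary`` at any tagged boundary up to ``h_max`` in the far field;
3. a Delaunay triangulation of the combined point set is filtered to the
   device domain and triangles are classified as ``fluid`` or ``disc`` by
   centroid membership in the sampled semi-disc polygons.

The disc region is meshed conformally with the fluid (shared interface
nodes), which the transport solver relies on for concentration continuity
across the gel surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.spatial import Delaunay, cKDTree

from .geometry import (
    DISC,
    FLUID,
    TAG_ARC,
    TAG_CHANNEL,
    Domain,
)

#: linear grading rate of the target edge length away from boundaries
GRADING = 0.55
#: geometric ratio between successive interior size bands
BAND_RATIO = 1.5


class MeshError(RuntimeError):
    """Raised when the domain cannot be meshed at the requested sizes."""


@dataclass
class Mesh:
    """2D triangulated device domain with region and boundary labels."""

    points: np.ndarray  # (n, 2) node coordinates, metres
    triangles: np.ndarray  # (m, 3) CCW node triples
    region: np.ndarray  # (m,) FLUID or DISC per triangle
    boundary_edges: np.ndarray  # (k, 2) node pairs on the outer boundary
    boundary_tags: np.ndarray  # (k,) tag strings for boundary_edges
    interface_edges: np.ndarray  # (j, 2) fluid/disc interface node pairs
    interface_tags: np.ndarray  # (j,) disc_arc or channel_wall
    h_boundary: float
    h_max: float
    domain: Domain | None = field(default=None, repr=False)

    # -- derived --------------------------------------------------------
    @cached_property
    def triangle_areas(self) -> np.ndarray:
        p = self.points
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        u, v = b - a, c - a
        return 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])

    @cached_property
    def n_nodes(self) -> int:
        return len(self.points)

    def nodes_with_tag(self, *tags: str) -> np.ndarray:
        """Node indices lying on boundary or interface edges with any of
        the given tags."""
        out: set[int] = set()
        for edges, etags in (
            (self.boundary_edges, self.boundary_tags),
            (self.interface_edges, self.interface_tags),
        ):
            if len(edges) == 0:
                continue
            sel = np.isin(etags, tags)
            out.update(np.unique(edges[sel]).tolist())
        return np.array(sorted(out), dtype=int)

    @cached_property
    def disc_nodes(self) -> np.ndarray:
        """Nodes belonging to at least one disc-region triangle."""
        tris = self.triangles[self.region == DISC]
        return np.unique(tris)

    def region_area(self, region: int) -> float:
        return float(self.triangle_areas[self.region == region].sum())

    def edge_lengths(self, edges: np.ndarray) -> np.ndarray:
        d = self.points[edges[:, 0]] - self.points[edges[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])


def _hex_grid(bbox, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Deterministically jittered hexagonal grid covering a bounding box."""
    (x0, y0), (x1, y1) = bbox
    dy = spacing * math.sqrt(3.0) / 2.0
    ys = np.arange(y0 + 0.5 * dy, y1, dy)
    rows = []
    for i, y in enumerate(ys):
        off = 0.5 * spacing if i % 2 else 0.0
        xs = np.arange(x0 + 0.5 * spacing + off, x1, spacing)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
    if not rows:
        return np.empty((0, 2))
    pts = np.vstack(rows)
    # small deterministic jitter breaks Delaunay degeneracy of the lattice
    pts += (rng.random(pts.shape) - 0.5) * (0.12 * spacing)
    return pts


def _interior_points(
    bpts: np.ndarray, outer_path: MplPath, h_boundary: float, h_max: float
) -> np.ndarray:
    rng = np.random.default_rng(9176)
    tree = cKDTree(bpts)
    bbox = (bpts.min(axis=0), bpts.max(axis=0))

    bands = [h_boundary]
    while bands[-1] * BAND_RATIO < h_max:
        bands.append(bands[-1] * BAND_RATIO)
    bands.append(h_max)

    kept = []
    for k, s in enumerate(bands):
        cand = _hex_grid(bbox, s, rng)
        if len(cand) == 0:
            continue
        inside = outer_path.contains_points(cand)
        cand = cand[inside]
        if len(cand) == 0:
            continue
        d, _ = tree.query(cand, workers=-1)
        h_loc = np.minimum(h_max, h_boundary + GRADING * d)
        lo = s
        hi = bands[k + 1] if k + 1 < len(bands) else np.inf
        sel = (h_loc >= lo) & (h_loc < hi) & (d >= 0.75 * s)
        kept.append(cand[sel])
    if not kept:
        return np.empty((0, 2))
    pts = np.vstack(kept)

    # prune close pairs across band seams (keep the earlier/finer point)
    ptree = cKDTree(pts)
    d_b, _ = tree.query(pts, workers=-1)
    h_loc = np.minimum(h_max, h_boundary + GRADING * d_b)
    pairs = ptree.query_pairs(r=0.8 * h_max, output_type="ndarray")
    if len(pairs):
        dist = np.hypot(*(pts[pairs[:, 0]] - pts[pairs[:, 1]]).T)
        hmin = np.minimum(h_loc[pairs[:, 0]], h_loc[pairs[:, 1]])
        bad = pairs[dist < 0.72 * hmin]
        drop = np.zeros(len(pts), dtype=bool)
        for i, j in bad:
            if not drop[i] and not drop[j]:
                drop[max(i, j)] = True
        pts = pts[~drop]
    return pts


def rectangle_mesh(
    length: float,
    width: float,
    nx: int,
    ny: int,
    region: int = FLUID,
    edge_tags: dict | None = None,
) -> Mesh:
    """Structured triangular mesh of ``[0, length] x [0, width]``.

    Useful as an analytic benchmark domain (plane-Poiseuille ducts,
    sealed well-mixed boxes).  ``edge_tags`` maps the sides
    {'left','right','bottom','top'} to boundary tag names; defaults to a
    flow-through duct (left=inlet, right=outlet, walls=chamber_wall)."""
    tags = {
        "left": "inlet",
        "right": "outlet",
        "bottom": "chamber_wall",
        "top": "chamber_wall",
    }
    tags.update(edge_tags or {})
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, width, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b, c, d = nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)
            tris.append((a, b, c))
            tris.append((a, c, d))
    tris = np.array(tris, dtype=int)

    bedges, btags = [], []
    for j in range(ny):
        bedges.append((nid(0, j), nid(0, j + 1)))
        btags.append(tags["left"])
        bedges.append((nid(nx, j), nid(nx, j + 1)))
        btags.append(tags["right"])
    for i in range(nx):
        bedges.append((nid(i, 0), nid(i + 1, 0)))
        btags.append(tags["bottom"])
        bedges.append((nid(i, ny), nid(i + 1, ny)))
        btags.append(tags["top"])

    return Mesh(
        points=pts,
        triangles=tris,
        region=np.full(len(tris), region, dtype=int),
        boundary_edges=np.array(bedges, dtype=int),
        boundary_tags=np.array(btags),
        interface_edges=np.empty((0, 2), dtype=int),
        interface_tags=np.array([], dtype=object),
        h_boundary=min(length / nx, width / ny),
        h_max=max(length / nx, width / ny),
        domain=None,
    )


def generate_mesh(domain: Domain, h_boundary: float, h_max: float) -> Mesh:
    """Generate a graded, conforming fluid+disc triangulation.

    Raises :class:`MeshError` when the sizes are infeasible or the
    triangulation degenerates (e.g. sliver triangles at a very acute
    chord/arc intersection)."""
    if not 0 < h_boundary <= h_max:
        raise MeshError("need 0 < h_boundary <= h_max")

    outer_pts, outer_tags = domain.sample_loop(domain.outer_loop, h_boundary)
    disc_samples = [
        domain.sample_loop(loop, h_boundary) for loop in domain.disc_loops
    ]

    all_bpts = [outer_pts] + [p for p, _ in disc_samples]
    bpts = np.vstack(all_bpts)

    outer_path = MplPath(outer_pts, closed=False)
    disc_paths = [MplPath(p, closed=False) for p, _ in disc_samples]

    interior = _interior_points(bpts, outer_path, h_boundary, h_max)
    points = np.vstack([bpts, interior]) if len(interior) else bpts

    tri = Delaunay(points)
    cent = points[tri.simplices].mean(axis=1)
    keep = outer_path.contains_points(cent)
    simplices = tri.simplices[keep]
    cent = cent[keep]

    region = np.full(len(simplices), FLUID, dtype=int)
    for path in disc_paths:
        region[path.contains_points(cent)] = DISC

    # drop unused nodes and renumber
    used, inv = np.unique(simplices, return_inverse=True)
    points = points[used]
    simplices = inv.reshape(simplices.shape)

    # enforce CCW orientation
    a, b, c = (points[simplices[:, i]] for i in range(3))
    u, v = b - a, c - a
    signed = 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    flip = signed < 0
    simplices[flip] = simplices[flip][:, [0, 2, 1]]
    areas = np.abs(signed)
    if np.any(areas <= 0):
        bad = cent[np.argmin(areas)]
        raise MeshError(
            f"degenerate (zero-area) triangle near ({bad[0]:.6g}, {bad[1]:.6g}); "
            "geometry too acute for the requested h_boundary"
        )

    # edge -> adjacent triangle regions
    edges = np.vstack(
        [simplices[:, [0, 1]], simplices[:, [1, 2]], simplices[:, [2, 0]]]
    )
    edge_region = np.concatenate([region] * 3)
    key = np.sort(edges, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key, edges, edge_region = key[order], edges[order], edge_region[order]
    uniq, start, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )

    boundary = uniq[counts == 1]
    dual = start[counts == 2]
    r1 = edge_region[dual]
    r2 = edge_region[dual + 1]
    interface = uniq[counts == 2][r1 != r2]

    # tag lookup trees from the sampled analytic loops
    def _edge_midtags(samples):
        mids, tags = [], []
        for p, t in samples:
            nxt = np.roll(p, -1, axis=0)
            mids.append(0.5 * (p + nxt))
            tags.append(t)
        return np.vstack(mids), np.concatenate(tags)

    omids, otags = _edge_midtags([(outer_pts, outer_tags)])
    otree = cKDTree(omids)
    bmids = 0.5 * (points[boundary[:, 0]] + points[boundary[:, 1]])
    _, idx = otree.query(bmids, workers=-1)
    boundary_tags = otags[idx]

    if disc_samples:
        dmids, dtags = _edge_midtags(disc_samples)
        dtree = cKDTree(dmids)
        imids = 0.5 * (points[interface[:, 0]] + points[interface[:, 1]])
        if len(imids):
            _, idx = dtree.query(imids, workers=-1)
            interface_tags = dtags[idx]
        else:
            interface_tags = np.array([], dtype=otags.dtype)
    else:
        interface = np.empty((0, 2), dtype=int)
        interface_tags = np.array([], dtype=otags.dtype)

    mesh = Mesh(
        points=points,
        triangles=simplices,
        region=region,
        boundary_edges=boundary,
        boundary_tags=boundary_tags,
        interface_edges=interface,
        interface_tags=interface_tags,
        h_boundary=h_boundary,
        h_max=h_max,
        domain=domain,
    )

    # sanity: the disc region must exist and tile the sampled semi-discs
    if domain.disc_loops and mesh.region_area(DISC) <= 0:
        raise MeshError("disc region vanished during meshing")
    if domain.spec.has_channel and TAG_CHANNEL not in set(interface_tags):
        raise MeshError("channel walls were not resolved; reduce h_boundary")
    if TAG_ARC not in set(interface_tags):
        raise MeshError("disc arc was not resolved; reduce h_boundary")
    return mesh
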