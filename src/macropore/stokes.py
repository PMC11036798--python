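"""Steady incompressible Stokes flow in the fluid region.

The flow chamber operates deep in the creeping-flow regime (Re ~ 1e-3 at
the highest bulk velocity), so inertia is dropped entirely and the steady
Stokes equations are discretised with the inf-sup-stable Taylor-Hood pair
(P2 velocity on vertices + edge midpoints, P1 pressure):

    mu (grad u, grad v) - (p, div v) = 0
    (div u, q) = 0

Boundary conditions: imposed mean (plug) velocity U on the inlet face,
natural (do-nothing) traction on the outlet -- which also gauges the
pressure -- and no-slip on every wall including the semi-disc surfaces
(the gel discs are impermeable to flow; matrix permeation contributes a
~1e-7 % collection efficiency and is neglected).

Because Stokes flow is linear in the driving velocity, all normalised
channel summaries (collection efficiency, flux fractions) are invariant
under changes of U.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import matplotlib.tri as mtri
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (
    FLUID,
    TAG_ARC,
    TAG_CHAMBER,
    TAG_CHANNEL,
    TAG_INLET,
    TAG_OUTLET,
    DeviceGeometry,
)
from .meshing import Mesh
from . import fem

#: dynamic viscosity of water at room temperature, Pa s (the velocity
#: field of a velocity-driven Stokes problem does not depend on it)
MU_WATER = 1.0e-3

# edge i of a triangle is opposite local vertex i
_EDGE_LOCAL = ((1, 2), (2, 0), (0, 1))
# barycentric coordinates of the 3 edge-midpoint quadrature points
_QPTS = np.array([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]])


class StokesError(RuntimeError):
    pass


def _edge_map(triangles: np.ndarray):
    """Unique undirected edges and the (m, 3) local-edge -> edge-id map."""
    raw = np.sort(
        np.stack(
            [triangles[:, [1, 2]], triangles[:, [2, 0]], triangles[:, [0, 1]]],
            axis=1,
        ),
        axis=2,
    )  # (m, 3, 2)
    flat = raw.reshape(-1, 2)
    edges, inv = np.unique(flat, axis=0, return_inverse=True)
    return edges, inv.reshape(len(triangles), 3)


def _p2_basis_at(lam: np.ndarray, grads: np.ndarray):
    """Values and gradients of the 6 P2 basis functions at one barycentric
    point for every triangle.

    ``lam``: (3,) barycentric point; ``grads``: (m, 3, 2) gradients of the
    barycentric coordinates.  Returns (vals (6,), gvals (m, 6, 2))."""
    vals = np.empty(6)
    for i in range(3):
        vals[i] = lam[i] * (2.0 * lam[i] - 1.0)
    for k, (i, j) in enumerate(_EDGE_LOCAL):
        vals[3 + k] = 4.0 * lam[i] * lam[j]
    m = grads.shape[0]
    g = np.empty((m, 6, 2))
    for i in range(3):
        g[:, i, :] = (4.0 * lam[i] - 1.0) * grads[:, i, :]
    for k, (i, j) in enumerate(_EDGE_LOCAL):
        g[:, 3 + k, :] = 4.0 * (lam[i] * grads[:, j, :] + lam[j] * grads[:, i, :])
    return vals, g


@dataclass
class FlowField:
    """Taylor-Hood Stokes solution on a device mesh.

    ``u`` holds vertex velocities; ``u_edge`` the edge-midpoint velocities
    of the quadratic field (both zero on and inside the impermeable disc).
    ``p`` is the nodal pressure, gauged by the outlet traction condition.
    """

    mesh: Mesh
    u: np.ndarray  # (n, 2)
    p: np.ndarray  # (n,)
    bulk_velocity: float
    edges: np.ndarray | None = None  # (e, 2) unique edges
    u_edge: np.ndarray | None = None  # (e, 2)
    tri_edges: np.ndarray | None = None  # (m, 3) edge ids per triangle

    @cached_property
    def _triangulation(self) -> mtri.Triangulation:
        return mtri.Triangulation(
            self.mesh.points[:, 0], self.mesh.points[:, 1], self.mesh.triangles
        )

    @cached_property
    def _trifinder(self):
        return self._triangulation.get_trifinder()

    def element_velocity(self) -> np.ndarray:
        """Centroid velocity per triangle of the quadratic field."""
        tris = self.mesh.triangles
        u_v = self.u[tris].sum(axis=1)  # (m, 2)
        if self.u_edge is None:
            return u_v / 3.0
        u_e = self.u_edge[self.tri_edges].sum(axis=1)
        # P2 at the centroid: vertex weight -1/9, edge weight 4/9
        return -u_v / 9.0 + 4.0 * u_e / 9.0

    def interpolate_velocity(self, pts: np.ndarray) -> np.ndarray:
        """Evaluate the quadratic velocity at arbitrary points; zero
        outside the mesh (walls / disc interior)."""
        pts = np.asarray(pts, dtype=float)
        t = self._trifinder(pts[:, 0], pts[:, 1])
        out = np.zeros((len(pts), 2))
        ok = t >= 0
        if not np.any(ok):
            return out
        ti = t[ok]
        tri_pts = self.mesh.points[self.mesh.triangles[ti]]  # (k, 3, 2)
        v0 = tri_pts[:, 1] - tri_pts[:, 0]
        v1 = tri_pts[:, 2] - tri_pts[:, 0]
        det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
        d = pts[ok] - tri_pts[:, 0]
        l1 = (d[:, 0] * v1[:, 1] - d[:, 1] * v1[:, 0]) / det
        l2 = (v0[:, 0] * d[:, 1] - v0[:, 1] * d[:, 0]) / det
        lam = np.stack([1.0 - l1 - l2, l1, l2], axis=1)  # (k, 3)
        vals = self.u[self.mesh.triangles[ti]]  # (k, 3, 2)
        if self.u_edge is None:
            out[ok] = np.einsum("ki,kid->kd", lam, vals)
            return out
        phi_v = lam * (2.0 * lam - 1.0)  # (k, 3)
        res = np.einsum("ki,kid->kd", phi_v, vals)
        e_vals = self.u_edge[self.tri_edges[ti]]  # (k, 3, 2)
        for k, (i, j) in enumerate(_EDGE_LOCAL):
            res += (4.0 * lam[:, i] * lam[:, j])[:, None] * e_vals[:, k, :]
        out[ok] = res
        return out

    def flux_across_segment(self, p0, p1, n_samples: int = 600) -> float:
        """Signed volumetric flux (per unit depth, m^2/s) across segment
        p0 -> p1, positive along the left normal of the direction p0->p1."""
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        t = (np.arange(n_samples) + 0.5) / n_samples
        pts = p0 + t[:, None] * (p1 - p0)
        seg = p1 - p0
        length = float(np.hypot(*seg))
        normal = np.array([-seg[1], seg[0]]) / length
        u = self.interpolate_velocity(pts)
        return float((u @ normal).mean() * length)

    def flux_across_x(self, x: float) -> float:
        """Net +x volumetric flux through the full vertical cross-section
        of the device at abscissa x."""
        spec = self.mesh.domain.spec
        rc = 0.5 * spec.chamber_diameter
        hw = 0.5 * spec.connector_width
        ylim = max(hw, np.sqrt(max(rc * rc - x * x, 0.0)))
        return -self.flux_across_segment((x, -ylim), (x, ylim))

    def continuity_residual(self) -> float:
        """Area-weighted relative L2 norm of div(u) over fluid elements
        (against the velocity-gradient norm); O(h^2) for Taylor-Hood."""
        mesh = self.mesh
        fl = np.flatnonzero(mesh.region == FLUID)
        tris = mesh.triangles[fl]
        areas, grads = fem.tri_geometry(mesh.points, tris)
        num = 0.0
        den = 0.0
        for q in range(3):
            _, g = _p2_basis_at(_QPTS[q], grads)
            dofs_u = np.concatenate(
                [self.u[tris], self.u_edge[self.tri_edges[fl]]], axis=1
            )  # (k, 6, 2)
            J = np.einsum("kad,kae->kde", g, dofs_u)  # (k, 2, 2) grad u
            div = J[:, 0, 0] + J[:, 1, 1]
            num += (areas / 3.0 * div**2).sum()
            den += (areas / 3.0 * (J**2).sum(axis=(1, 2))).sum()
        return float(np.sqrt(num / den)) if den > 0 else 0.0


def solve_stokes(mesh: Mesh, bulk_velocity: float) -> FlowField:
    """Solve steady Stokes flow on the fluid region of a device mesh.

    Raises :class:`StokesError` if the inlet or outlet tags are missing
    (an unreachable boundary makes the system singular)."""
    if bulk_velocity < 0:
        raise StokesError("bulk velocity must be nonnegative")
    n = mesh.n_nodes
    edges, tri_edges = _edge_map(mesh.triangles)
    ne = len(edges)

    if bulk_velocity == 0.0:
        return FlowField(
            mesh,
            np.zeros((n, 2)),
            np.zeros(n),
            0.0,
            edges=edges,
            u_edge=np.zeros((ne, 2)),
            tri_edges=tri_edges,
        )

    present = set(np.unique(mesh.boundary_tags))
    missing = {TAG_INLET, TAG_OUTLET} - present
    if missing:
        raise StokesError(f"boundary tags unreachable in mesh: {sorted(missing)}")

    fl = np.flatnonzero(mesh.region == FLUID)
    tris = mesh.triangles[fl]
    te = tri_edges[fl]
    areas, grads = fem.tri_geometry(mesh.points, tris)
    ndof = n + ne
    dofs = np.concatenate([tris, n + te], axis=1)  # (m, 6)

    # quadrature at edge midpoints (exact for the quadratic integrands)
    K_loc = np.zeros((len(tris), 6, 6))
    Bx_loc = np.zeros((len(tris), 3, 6))
    By_loc = np.zeros((len(tris), 3, 6))
    for q in range(3):
        lam = _QPTS[q]
        _, g = _p2_basis_at(lam, grads)
        w = areas / 3.0
        K_loc += np.einsum("kad,kbd->kab", g, g) * w[:, None, None]
        for i_p in range(3):
            Bx_loc[:, i_p, :] += lam[i_p] * g[:, :, 0] * w[:, None]
            By_loc[:, i_p, :] += lam[i_p] * g[:, :, 1] * w[:, None]
    K_loc *= MU_WATER

    rows = np.repeat(dofs, 6, axis=1)
    cols = np.tile(dofs, (1, 6))
    K = sp.coo_matrix(
        (K_loc.reshape(len(tris), 36).ravel(), (rows.ravel(), cols.ravel())),
        shape=(ndof, ndof),
    ).tocsr()
    prow = np.repeat(tris, 6, axis=1)
    pcol = np.tile(dofs, (1, 3))
    Bx = sp.coo_matrix(
        (Bx_loc.reshape(len(tris), 18).ravel(), (prow.ravel(), pcol.ravel())),
        shape=(n, ndof),
    ).tocsr()
    By = sp.coo_matrix(
        (By_loc.reshape(len(tris), 18).ravel(), (prow.ravel(), pcol.ravel())),
        shape=(n, ndof),
    ).tocsr()

    # --- Dirichlet sets -------------------------------------------------
    wall_nodes = mesh.nodes_with_tag(TAG_CHAMBER, TAG_ARC, TAG_CHANNEL)
    inlet_nodes = np.setdiff1d(mesh.nodes_with_tag(TAG_INLET), wall_nodes)
    fluid_vnodes = np.unique(tris)
    orphan_nodes = np.setdiff1d(np.arange(n), fluid_vnodes)

    edge_key = {tuple(e): i for i, e in enumerate(np.sort(edges, axis=1).tolist())}

    def _edge_ids(edge_list, tag_list, tags):
        ids = []
        for e, t in zip(edge_list, tag_list):
            if t in tags:
                ids.append(edge_key[tuple(sorted(e.tolist()))])
        return np.array(ids, dtype=int)

    wall_edges = np.concatenate(
        [
            _edge_ids(mesh.boundary_edges, mesh.boundary_tags, {TAG_CHAMBER}),
            _edge_ids(mesh.interface_edges, mesh.interface_tags, {TAG_ARC, TAG_CHANNEL}),
        ]
    )
    inlet_edges = _edge_ids(mesh.boundary_edges, mesh.boundary_tags, {TAG_INLET})
    fluid_edges = np.unique(te)
    orphan_edges = np.setdiff1d(np.arange(ne), fluid_edges)

    # plug values, rescaled so the discrete inlet influx of the quadratic
    # field is exactly U times the inlet width (the no-slip corners would
    # otherwise shave off U*W/72 per corner edge)
    wall_set = set(wall_nodes.tolist())
    q_flux = 0.0
    width = 0.0
    inlet_edge_rows = [
        e for e, t in zip(mesh.boundary_edges, mesh.boundary_tags) if t == TAG_INLET
    ]
    for a, b in inlet_edge_rows:
        length = float(np.hypot(*(mesh.points[b] - mesh.points[a])))
        va = 0.0 if a in wall_set else 1.0
        vb = 0.0 if b in wall_set else 1.0
        q_flux += length * (va + vb + 4.0) / 6.0
        width += length
    scale = width / q_flux if q_flux > 0 else 1.0

    fix_u = np.concatenate(
        [wall_nodes, inlet_nodes, orphan_nodes, n + wall_edges, n + inlet_edges, n + orphan_edges]
    )
    val_ux = np.concatenate(
        [
            np.zeros(len(wall_nodes)),
            np.full(len(inlet_nodes), scale * bulk_velocity),
            np.zeros(len(orphan_nodes)),
            np.zeros(len(wall_edges)),
            np.full(len(inlet_edges), scale * bulk_velocity),
            np.zeros(len(orphan_edges)),
        ]
    )

    A = sp.bmat(
        [[K, None, -Bx.T], [None, K, -By.T], [-Bx, -By, None]], format="csr"
    )
    x0 = np.zeros(2 * ndof + n)
    x0[fix_u] = val_ux  # ux block; uy stays zero
    p_fix = 2 * ndof + orphan_nodes
    fix = np.concatenate([fix_u, ndof + fix_u, p_fix])
    b = -A @ x0
    keep = np.setdiff1d(np.arange(2 * ndof + n), fix)
    try:
        sol = spla.spsolve(A[keep][:, keep].tocsc(), b[keep])
    except Exception as exc:  # pragma: no cover - backend specific
        raise StokesError(f"singular Stokes system: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise StokesError("Stokes solve produced non-finite values")
    x = x0.copy()
    x[keep] = sol

    u = np.column_stack([x[:n], x[ndof : ndof + n]])
    u_edge = np.column_stack([x[n:ndof], x[ndof + n : 2 * ndof]])
    p = x[2 * ndof :]
    return FlowField(
        mesh=mesh,
        u=u,
        p=p,
        bulk_velocity=bulk_velocity,
        edges=edges,
        u_edge=u_edge,
        tri_edges=tri_edges,
    )


# --- channel summaries ----------------------------------------------------


def channel_midsection(spec: DeviceGeometry):
    """Endpoints of the mid-chord cross-section (through the disc centre,
    perpendicular to the channel axis) -- farthest from entrance effects."""
    if not spec.has_channel:
        raise ValueError("solid disc has no channel cross-section")
    c = np.asarray(spec.disc_center, dtype=float)
    nrm = spec.channel_normal
    hw = 0.5 * spec.channel_width
    return c - hw * nrm, c + hw * nrm


def channel_flux(flow: FlowField, spec: DeviceGeometry) -> float:
    """Signed volumetric flux along the channel axis through the mid-chord
    cross-section (m^2/s per unit depth; positive leeward)."""
    p0, p1 = channel_midsection(spec)
    # the left normal of p0->p1 is -axis; flip to report along +axis
    return -flow.flux_across_segment(p0, p1)


def channel_mean_velocity(flow: FlowField, spec: DeviceGeometry) -> float:
    """Mean channel velocity |net flux| / width (m/s); monotone
    non-increasing in the channel angle at fixed U and width."""
    if not spec.has_channel:
        raise ValueError("channel mean velocity undefined for a solid disc")
    return abs(channel_flux(flow, spec)) / spec.channel_width


def channel_peak_velocity(
    flow: FlowField, spec: DeviceGeometry, n_samples: int = 201
) -> float:
    """Peak (centreline) axial velocity magnitude on the mid-chord
    cross-section (m/s).

    For the near-parabolic channel profile the peak is 3/2 of the mean;
    the channel Peclet numbers reported for this system are reproduced by
    the peak velocity (see the metrics module)."""
    if not spec.has_channel:
        raise ValueError("channel peak velocity undefined for a solid disc")
    p0, p1 = channel_midsection(spec)
    t = (np.arange(n_samples) + 0.5) / n_samples
    pts = p0 + t[:, None] * (np.asarray(p1) - np.asarray(p0))
    u = flow.interpolate_velocity(pts)
    return float(np.abs(u @ spec.channel_axis).max())


def fluid_collection_efficiency(flow: FlowField, spec: DeviceGeometry) -> float:
    """Percentage of the liquid approaching the disc's frontal width that
    passes through the channel: 100 |Q_channel| / (U d).  Independent of U
    by Stokes linearity."""
    if flow.bulk_velocity == 0:
        raise ValueError("collection efficiency undefined at zero bulk velocity")
    if not spec.has_channel:
        return 0.0
    return 100.0 * abs(channel_flux(flow, spec)) / (
        flow.bulk_velocity * spec.disc_diameter
    )
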