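"""Vectorised P1 (linear triangle) finite-element assembly.

Provides the few matrices the flow and transport solvers need: stiffness,
lumped mass, divergence/gradient coupling blocks, convection and a
streamline-upwind (SUPG-type) stabilisation term.  All assembly is done
with numpy scatter-adds into COO triplets; matrices are returned as CSR.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def tri_geometry(points: np.ndarray, tris: np.ndarray):
    """Areas and P1 basis gradients per triangle.

    Returns ``(areas, grads)`` with ``grads[t, i, :]`` the constant
    gradient of the basis function of local node ``i`` on triangle ``t``.
    """
    p = points[tris]  # (m, 3, 2)
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    areas = 0.5 * np.abs(det)
    # gradient of barycentric coordinates
    grads = np.empty((len(tris), 3, 2))
    inv_det = 1.0 / det
    grads[:, 1, 0] = v1[:, 1] * inv_det
    grads[:, 1, 1] = -v1[:, 0] * inv_det
    grads[:, 2, 0] = -v0[:, 1] * inv_det
    grads[:, 2, 1] = v0[:, 0] * inv_det
    grads[:, 0] = -grads[:, 1] - grads[:, 2]
    return areas, grads


def _assemble(rows, cols, vals, n):
    return sp.coo_matrix(
        (vals.ravel(), (rows.ravel(), cols.ravel())), shape=(n, n)
    ).tocsr()


def _pair_indices(tris):
    rows = np.repeat(tris, 3, axis=1)  # (m, 9)
    cols = np.tile(tris, (1, 3))
    return rows, cols


def stiffness(points, tris, n, coeff=1.0):
    """Assemble ``sum_T coeff_T int_T grad(phi_i) . grad(phi_j)``."""
    areas, grads = tri_geometry(points, tris)
    c = np.broadcast_to(np.asarray(coeff, dtype=float), areas.shape)
    local = np.einsum("tid,tjd->tij", grads, grads) * (c * areas)[:, None, None]
    rows, cols = _pair_indices(tris)
    return _assemble(rows, cols, local.reshape(len(tris), 9), n)


def lumped_mass(points, tris, n, coeff=1.0):
    """Diagonal (row-sum lumped) mass vector: node i gets sum A_T/3."""
    areas, _ = tri_geometry(points, tris)
    c = np.broadcast_to(np.asarray(coeff, dtype=float), areas.shape)
    m = np.zeros(n)
    w = (c * areas) / 3.0
    for i in range(3):
        np.add.at(m, tris[:, i], w)
    return m


def divergence_blocks(points, tris, n):
    """Divergence coupling blocks Bx, By with
    ``Bx[i, j] = int phi_i  d(phi_j)/dx`` (P1 pressure test x P1 velocity).
    """
    areas, grads = tri_geometry(points, tris)
    rows, cols = _pair_indices(tris)
    out = []
    for d in range(2):
        # int_T phi_i * dphi_j/dd = (A/3) * grad_j[d]  (gradient constant)
        local = np.repeat(grads[:, None, :, d], 3, axis=1) * (areas / 3.0)[
            :, None, None
        ]
        out.append(_assemble(rows, cols, local.reshape(len(tris), 9), n))
    return out[0], out[1]


def convection(points, tris, n, u_el):
    """Galerkin convection ``int phi_i (u . grad phi_j)`` with elementwise
    (centroid) velocities ``u_el`` of shape (m, 2)."""
    areas, grads = tri_geometry(points, tris)
    udotg = np.einsum("td,tjd->tj", u_el, grads)  # (m, 3)
    local = np.repeat(udotg[:, None, :], 3, axis=1) * (areas / 3.0)[:, None, None]
    rows, cols = _pair_indices(tris)
    return _assemble(rows, cols, local.reshape(len(tris), 9), n)


def supg_streamline_diffusion(points, tris, n, u_el, diffusivity):
    """Streamline diffusion ``sum_T tau_T int (u.grad phi_i)(u.grad phi_j)``
    with the optimal 1D upwind parameter
    ``tau = h/(2|u|) (coth(a) - 1/a)``, ``a = |u| h / (2 D)``."""
    areas, grads = tri_geometry(points, tris)
    speed = np.hypot(u_el[:, 0], u_el[:, 1])
    h = np.sqrt(4.0 * areas / np.sqrt(3.0))  # equilateral-equivalent size
    a = speed * h / (2.0 * diffusivity)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        xi = 1.0 / np.tanh(np.minimum(a, 50.0)) - 1.0 / a
    xi = np.where(a < 1e-8, a / 3.0, xi)  # series limit, avoids 0/0
    tau = np.where(speed > 0, h / (2.0 * np.maximum(speed, 1e-300)) * xi, 0.0)
    udotg = np.einsum("td,tjd->tj", u_el, grads)
    local = np.einsum("ti,tj->tij", udotg, udotg) * (tau * areas)[:, None, None]
    rows, cols = _pair_indices(tris)
    return _assemble(rows, cols, local.reshape(len(tris), 9), n)


def apply_dirichlet(A: sp.csr_matrix, b: np.ndarray, nodes: np.ndarray, values):
    """Row-replacement Dirichlet conditions (returns modified copies)."""
    A = A.tolil(copy=True)
    b = b.copy()
    A[nodes, :] = 0.0
    A[nodes, nodes] = 1.0
    b[nodes] = values
    return A.tocsr(), b
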