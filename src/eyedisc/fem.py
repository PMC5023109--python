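"""Vectorized P1 (linear triangle) finite-element assembly on numpy/scipy.

All operators act on nodal vectors; matrices are scipy CSR. Conventions:
`points` is (N, 2), `tris` is (M, 3) with positively oriented triangles.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numpy.typing import NDArray

__all__ = [
    "tri_geometry",
    "stiffness_matrix",
    "mass_matrix",
    "lumped_mass",
    "divergence_matrices",
    "divdiv_matrix",
    "boundary_edges",
    "edge_load",
    "element_gradients",
]


def tri_geometry(points: NDArray, tris: NDArray) -> tuple[NDArray, NDArray, NDArray]:
    """Signed areas (M,), and shape-function gradients gx, gy of shape (M, 3)."""
    p = points[tris]  # (M, 3, 2)
    x, y = p[..., 0], p[..., 1]
    # 2A = (x1-x0)(y2-y0) - (x2-x0)(y1-y0)
    twoA = (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (
        x[:, 2] - x[:, 0]
    ) * (y[:, 1] - y[:, 0])
    area = 0.5 * twoA
    # grad of barycentric lambda_i: b_i = (y_j - y_k)/2A, c_i = (x_k - x_j)/2A
    j = [1, 2, 0]
    k = [2, 0, 1]
    gx = (y[:, j] - y[:, k]) / twoA[:, None]
    gy = (x[:, k] - x[:, j]) / twoA[:, None]
    return area, gx, gy


def _assemble(rows, cols, vals, shape) -> sp.csr_matrix:
    return sp.coo_matrix(
        (np.ravel(vals), (np.ravel(rows), np.ravel(cols))), shape=shape
    ).tocsr()


def stiffness_matrix(
    points: NDArray, tris: NDArray, coeff: NDArray | float = 1.0
) -> sp.csr_matrix:
    """Assemble int coeff * grad(phi_i) . grad(phi_j); `coeff` per element."""
    n = len(points)
    area, gx, gy = tri_geometry(points, tris)
    c = np.broadcast_to(np.asarray(coeff, dtype=float), area.shape)
    # local 3x3: A * c * (gx_i gx_j + gy_i gy_j)
    ke = (c * area)[:, None, None] * (
        gx[:, :, None] * gx[:, None, :] + gy[:, :, None] * gy[:, None, :]
    )
    rows = np.repeat(tris[:, :, None], 3, axis=2)
    cols = np.repeat(tris[:, None, :], 3, axis=1)
    return _assemble(rows, cols, ke, (n, n))


def mass_matrix(points: NDArray, tris: NDArray) -> sp.csr_matrix:
    """Consistent mass matrix int phi_i phi_j."""
    n = len(points)
    area, _, _ = tri_geometry(points, tris)
    local = np.array([[2, 1, 1], [1, 2, 1], [1, 1, 2]], dtype=float) / 12.0
    me = area[:, None, None] * local[None, :, :]
    rows = np.repeat(tris[:, :, None], 3, axis=2)
    cols = np.repeat(tris[:, None, :], 3, axis=1)
    return _assemble(rows, cols, me, (n, n))


def lumped_mass(points: NDArray, tris: NDArray) -> NDArray:
    """Row-sum lumped mass vector (nodal areas)."""
    area, _, _ = tri_geometry(points, tris)
    m = np.zeros(len(points))
    np.add.at(m, tris.ravel(), np.repeat(area / 3.0, 3))
    return m


def divergence_matrices(points: NDArray, tris: NDArray) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Bx, By with (Bx u_x + By u_y)_i = int phi_i * div(u)."""
    n = len(points)
    area, gx, gy = tri_geometry(points, tris)
    # int phi_q * dphi_j/dx over element = (A/3) * gx_j  for each vertex q
    bx = (area[:, None, None] / 3.0) * np.broadcast_to(gx[:, None, :], (len(tris), 3, 3))
    by = (area[:, None, None] / 3.0) * np.broadcast_to(gy[:, None, :], (len(tris), 3, 3))
    rows = np.repeat(tris[:, :, None], 3, axis=2)
    cols = np.repeat(tris[:, None, :], 3, axis=1)
    return _assemble(rows, cols, bx, (n, n)), _assemble(rows, cols, by, (n, n))


def divdiv_matrix(points: NDArray, tris: NDArray) -> sp.csr_matrix:
    """Grad-div operator int (div u)(div v) on stacked [u_x; u_y] dofs (2N x 2N)."""
    n = len(points)
    area, gx, gy = tri_geometry(points, tris)
    g = np.concatenate([gx, gy], axis=1)  # (M, 6): d/dx of ux dofs, d/dy of uy dofs
    ge = area[:, None, None] * (g[:, :, None] * g[:, None, :])
    dofs = np.concatenate([tris, tris + n], axis=1)  # (M, 6)
    rows = np.repeat(dofs[:, :, None], 6, axis=2)
    cols = np.repeat(dofs[:, None, :], 6, axis=1)
    return _assemble(rows, cols, ge, (2 * n, 2 * n))


def boundary_edges(tris: NDArray) -> NDArray:
    """Boundary edges (E, 2), each oriented as in its (CCW) owner triangle.

    For positively oriented triangles this leaves the domain on the left of
    each edge, i.e. the outward normal is (dy, -dx)/|edge|.
    """
    edges = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return edges[idx[counts == 1]]


def edge_load(points: NDArray, edges: NDArray, g: NDArray) -> NDArray:
    """Assemble int_edges phi_i * g ds for nodal flux density g."""
    n = len(points)
    d = points[edges[:, 1]] - points[edges[:, 0]]
    length = np.hypot(d[:, 0], d[:, 1])
    g0, g1 = g[edges[:, 0]], g[edges[:, 1]]
    b = np.zeros(n)
    np.add.at(b, edges[:, 0], length * (2 * g0 + g1) / 6.0)
    np.add.at(b, edges[:, 1], length * (g0 + 2 * g1) / 6.0)
    return b


def element_gradients(points: NDArray, tris: NDArray, values: NDArray) -> NDArray:
    """Per-element gradient (M, 2) of a P1 nodal field."""
    _, gx, gy = tri_geometry(points, tris)
    v = values[tris]
    return np.stack([(v * gx).sum(axis=1), (v * gy).sum(axis=1)], axis=1)
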