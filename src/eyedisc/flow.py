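"""Tissue mechanics: proliferation source and velocity field.

The epithelium is treated as an incompressible Newtonian fluid whose local
volume production S models proliferation: div(u) = S with
S = Pi * k0 * exp(-delta_PL * PL). At tissue scales inertia is negligible
(Reynolds number << 1), so the default solver is the quasi-static Stokes
problem with prescribed divergence and a traction-free boundary; a
potential-flow fallback (u = grad(phi), laplace(phi) = S) is provided for
speed and cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numpy.typing import NDArray

from . import fem
from .errors import InvalidArgument, SolverFailure
from .mesh import GrowingMesh
from .params import ModelParameters

__all__ = ["VelocitySolution", "growth_source", "solve_velocity", "anisotropy"]


def growth_source(
    Pi: NDArray, PL: float, params: ModelParameters
) -> NDArray:
    """Proliferation source S = Pi * k0 * exp(-delta_PL * PL).

    ``PL`` is the tracked posterior length of the furrow (um), a surrogate of
    developmental time; growth is confined to the progenitor region (Pi > 0)
    and declines exponentially as the furrow advances. Before furrow
    initiation PL = 0 and S = Pi * k0.
    """
    if PL < 0:
        raise InvalidArgument("posterior length PL must be non-negative")
    return np.asarray(Pi, dtype=float) * params.k0 * np.exp(-params.delta_PL * PL)


@dataclass
class VelocitySolution:
    """Nodal velocity/pressure with a mass-balance diagnostic.

    ``div_residual`` is |∮ u.n ds - ∫ S dΩ| / max(|∫ S dΩ|, tiny): by the
    divergence theorem it vanishes for an exact solution.
    """

    u: NDArray          # (N, 2) um/s
    p: NDArray          # (N,) model units
    div_residual: float

    def boundary_flux(self, mesh: GrowingMesh) -> float:
        return _boundary_flux(mesh, self.u)


def _boundary_flux(mesh: GrowingMesh, u: NDArray) -> float:
    """∮ u.n ds over the boundary (outward normal from CCW edge orientation)."""
    e = mesh.boundary_edge_array
    d = mesh.points[e[:, 1]] - mesh.points[e[:, 0]]
    # domain lies left of the oriented edge -> outward normal (dy, -dx)
    nx, ny = d[:, 1], -d[:, 0]
    um = 0.5 * (u[e[:, 0]] + u[e[:, 1]])
    return float((um[:, 0] * nx + um[:, 1] * ny).sum())


def _source_integral(mesh: GrowingMesh, S: NDArray) -> float:
    return float(fem.lumped_mass(mesh.points, mesh.tris) @ S)


def solve_velocity(
    mesh: GrowingMesh,
    S: NDArray,
    params: ModelParameters,
    method: str = "stokes",
) -> VelocitySolution:
    """Velocity field with prescribed divergence S and free boundary.

    `stokes`: quasi-static Stokes (P1-P1, Brezzi-Pitkaranta stabilized) with
    zero pseudo-traction on the boundary; rigid-body translation/rotation
    removed with Lagrange multipliers so the domain centroid neither
    translates nor rotates.

    `potential`: u = grad(phi) with laplace(phi) = S and phi = 0 on the
    boundary; cheaper, exact for radially symmetric cases.
    """
    S = np.asarray(S, dtype=float)
    if S.shape != (mesh.n_nodes,):
        raise InvalidArgument("source field must be nodal")
    if method == "potential":
        return _solve_potential(mesh, S)
    if method != "stokes":
        raise InvalidArgument(f"unknown velocity solver '{method}'")
    return _solve_stokes(mesh, S, params)


def _solve_stokes(mesh: GrowingMesh, S: NDArray, params: ModelParameters) -> VelocitySolution:
    pts, tris = mesh.points, mesh.tris
    n = mesh.n_nodes
    mu = params.mu
    K = fem.stiffness_matrix(pts, tris)
    M = fem.mass_matrix(pts, tris)
    G = fem.divdiv_matrix(pts, tris)
    Bx, By = fem.divergence_matrices(pts, tris)
    B = sp.hstack([Bx, By]).tocsr()              # (n, 2n): int q div(u)
    A = (mu * sp.block_diag([K, K]) + (mu / 3.0) * G).tocsr()

    # Brezzi-Pitkaranta pressure stabilization, per-element h_T^2
    area, _, _ = fem.tri_geometry(pts, tris)
    hT2 = (4.0 / np.sqrt(3.0)) * area            # h^2 of equal-area equilateral
    C = fem.stiffness_matrix(pts, tris, coeff=0.1 * hT2 / mu)

    # momentum: A u - B^T p = 0 ; continuity: B u - C p = M S.
    # The traction-free problem is singular up to rigid motions; pin three
    # velocity dofs (an exact selection from the rigid-motion family, since
    # a rigid motion can always match three such values) and project the
    # result onto the zero-mean-translation / zero-rotation representative.
    sys = sp.bmat([[A, -B.T], [B, -C]], format="lil")
    rhs = np.concatenate([np.zeros(2 * n), M @ S])
    xc, yc = mesh.centroid
    # with the gradient-form momentum operator only translations are in the
    # discrete kernel (rotations feel the pseudo-traction), so two pins suffice
    i_a = int(np.argmin((pts[:, 0] - xc) ** 2 + (pts[:, 1] - yc) ** 2))
    for dof in (i_a, i_a + n):
        sys.rows[dof], sys.data[dof] = [dof], [1.0]
        rhs[dof] = 0.0
    try:
        sol = spla.spsolve(sys.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - singular systems
        raise SolverFailure(f"Stokes solve failed: {exc}") from exc
    if not np.all(np.isfinite(sol)):
        raise SolverFailure("Stokes solve returned non-finite values")
    u = np.column_stack([sol[:n], sol[n:2 * n]])
    p = sol[2 * n:]
    # remove residual rigid motion (mass-weighted)
    m = fem.lumped_mass(pts, tris)
    mtot = m.sum()
    u -= (m @ u) / mtot
    rx, ry = pts[:, 0] - xc, pts[:, 1] - yc
    omega = float(m @ (rx * u[:, 1] - ry * u[:, 0])) / float(m @ (rx**2 + ry**2))
    u[:, 0] += omega * ry
    u[:, 1] -= omega * rx
    total_S = _source_integral(mesh, S)
    res = abs(_boundary_flux(mesh, u) - total_S) / max(abs(total_S), 1e-300)
    return VelocitySolution(u=u, p=p, div_residual=res)


def _solve_potential(mesh: GrowingMesh, S: NDArray) -> VelocitySolution:
    pts, tris = mesh.points, mesh.tris
    n = mesh.n_nodes
    K = fem.stiffness_matrix(pts, tris).tolil()
    M = fem.mass_matrix(pts, tris)
    rhs = -(M @ S)
    bnodes = mesh.boundary_nodes
    for i in bnodes:  # Dirichlet phi = 0
        K.rows[i], K.data[i] = [i], [1.0]
    rhs[bnodes] = 0.0
    phi = spla.spsolve(K.tocsc(), rhs)
    if not np.all(np.isfinite(phi)):
        raise SolverFailure("potential-flow solve returned non-finite values")
    # project element gradients to nodes (area-weighted)
    grads = fem.element_gradients(pts, tris, phi)
    area, _, _ = fem.tri_geometry(pts, tris)
    u = np.zeros((n, 2))
    w = np.zeros(n)
    for k in range(3):
        np.add.at(u, tris[:, k], grads * area[:, None])
        np.add.at(w, tris[:, k], area)
    u /= w[:, None]
    total_S = _source_integral(mesh, S)
    res = abs(_boundary_flux(mesh, u) - total_S) / max(abs(total_S), 1e-300)
    return VelocitySolution(u=u, p=np.zeros(n), div_residual=res)


def anisotropy(mesh: GrowingMesh, u: NDArray, radius: float | None = None) -> float:
    """Growth anisotropy epsilon = (d u_y / d y) / (d u_x / d x) at the centroid.

    Velocity gradients are averaged (area-weighted) over elements whose
    centroid lies within `radius` of the domain centroid; a pointwise
    single-element evaluation is mesh-noise sensitive.
    """
    cx, cy = mesh.centroid
    cent = mesh.points[mesh.tris].mean(axis=1)
    if radius is None:
        radius = 3.0 * mesh.target_edge
    near = np.hypot(cent[:, 0] - cx, cent[:, 1] - cy) <= radius
    if not near.any():
        raise InvalidArgument("no elements near the centroid; increase radius")
    area, _, _ = fem.tri_geometry(mesh.points, mesh.tris)
    gx = fem.element_gradients(mesh.points, mesh.tris, u[:, 0])[near]
    gy = fem.element_gradients(mesh.points, mesh.tris, u[:, 1])[near]
    w = area[near]
    dux_dx = float((gx[:, 0] * w).sum() / w.sum())
    duy_dy = float((gy[:, 1] * w).sum() / w.sum())
    return duy_dy / dux_dx
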