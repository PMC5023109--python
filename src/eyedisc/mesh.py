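"""Deforming triangulated representation of the elliptical eye disc.

The mesh is Lagrangian: nodes ride with the tissue velocity (ALE with mesh
velocity equal to material velocity). When accumulated deformation degrades
element quality below a threshold the domain is retriangulated from its
current boundary polygon and all fields are transferred by linear
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import shapely
from numpy.typing import NDArray
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from . import fem
from .errors import GeometryError, InvalidArgument

__all__ = ["GrowingMesh", "make_ellipse_mesh", "remesh", "transfer_fields",
           "write_vtk", "write_csv"]


def _triangle_quality(points: NDArray, tris: NDArray) -> NDArray:
    """Per-element quality 4*sqrt(3)*A / sum(edge^2), in [0, 1] (1 = equilateral)."""
    area, _, _ = fem.tri_geometry(points, tris)
    p = points[tris]
    e01 = ((p[:, 1] - p[:, 0]) ** 2).sum(axis=1)
    e12 = ((p[:, 2] - p[:, 1]) ** 2).sum(axis=1)
    e20 = ((p[:, 0] - p[:, 2]) ** 2).sum(axis=1)
    return 4.0 * np.sqrt(3.0) * area / (e01 + e12 + e20)


@dataclass
class GrowingMesh:
    """2D triangulated domain with cached geometry metadata.

    Attributes
    ----------
    points : (N, 2) node coordinates in um
    tris : (M, 3) positively oriented triangle connectivity
    """

    points: NDArray
    tris: NDArray
    target_edge: float = 5.0
    _bedges: NDArray = dc_field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.tris = np.asarray(self.tris, dtype=np.int64)
        area, _, _ = fem.tri_geometry(self.points, self.tris)
        flip = area < 0
        if np.any(flip):  # normalize orientation once at construction
            self.tris[flip] = self.tris[flip][:, ::-1]
        if self._bedges is None:
            self._bedges = fem.boundary_edges(self.tris)

    # -- geometry -------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def boundary_edge_array(self) -> NDArray:
        return self._bedges

    @property
    def boundary_nodes(self) -> NDArray:
        return np.unique(self._bedges)

    @property
    def element_areas(self) -> NDArray:
        area, _, _ = fem.tri_geometry(self.points, self.tris)
        return area

    @property
    def area(self) -> float:
        return float(self.element_areas.sum())

    @property
    def x_posterior(self) -> float:
        """x of the posterior pole (minimum x over boundary nodes)."""
        return float(self.points[self.boundary_nodes, 0].min())

    @property
    def L_AP(self) -> float:
        """Anterior-posterior extent: max(x) - min(x) over boundary nodes."""
        xb = self.points[self.boundary_nodes, 0]
        return float(xb.max() - xb.min())

    @property
    def quality(self) -> NDArray:
        return _triangle_quality(self.points, self.tris)

    @property
    def min_quality(self) -> float:
        return float(self.quality.min())

    @property
    def centroid(self) -> NDArray:
        area = self.element_areas
        cent = self.points[self.tris].mean(axis=1)
        return (cent * area[:, None]).sum(axis=0) / area.sum()

    def x_relative(self, x: NDArray | float) -> NDArray | float:
        """AP coordinate with origin at the posterior pole."""
        return x - self.x_posterior

    def posterior_margin_edges(self, margin_fraction: float = 0.2) -> NDArray:
        """Boundary edges whose midpoint lies in the posterior Hh margin."""
        mid_x = self.points[self._bedges, 0].mean(axis=1)
        cutoff = self.x_posterior + margin_fraction * self.L_AP
        return self._bedges[mid_x <= cutoff]

    def boundary_loop(self) -> NDArray:
        """Ordered (CCW) node indices of the boundary polygon."""
        nxt = dict(zip(self._bedges[:, 0].tolist(), self._bedges[:, 1].tolist()))
        start = int(self._bedges[0, 0])
        loop = [start]
        node = nxt[start]
        while node != start:
            loop.append(node)
            node = nxt[node]
            if len(loop) > len(nxt) + 1:
                raise GeometryError("boundary is not a single closed loop")
        return np.array(loop, dtype=np.int64)

    # -- deformation ----------------------------------------------------------

    def moved(self, displacement: NDArray) -> "GrowingMesh":
        """New mesh with nodes displaced; raises on element inversion."""
        new_pts = self.points + displacement
        area, _, _ = fem.tri_geometry(new_pts, self.tris)
        if np.any(area <= 0):
            raise GeometryError(
                f"{int((area <= 0).sum())} elements inverted by mesh motion"
            )
        return GrowingMesh(new_pts, self.tris, self.target_edge, _bedges=self._bedges)


def advance_domain(mesh: GrowingMesh, u: NDArray, dt: float) -> GrowingMesh:
    """Explicit ALE step: move every node by dt * u.

    Raises :class:`GeometryError` if any element inverts, which the caller
    should handle by reducing dt or remeshing.
    """
    if dt <= 0:
        raise InvalidArgument("dt must be positive")
    u = np.asarray(u, dtype=float)
    if u.shape != mesh.points.shape:
        raise InvalidArgument("velocity field shape does not match mesh nodes")
    return mesh.moved(dt * u)


# -- mesh generation ---------------------------------------------------------


def _mesh_polygon(boundary_pts: NDArray, target_edge: float) -> GrowingMesh:
    """Quasi-uniform triangulation of a (near-convex) polygon.

    Hexagonal interior lattice + supplied boundary points, Delaunay
    triangulated; triangles whose centroid falls outside the polygon are
    dropped.
    """
    poly = Polygon(boundary_pts)
    if not poly.is_valid:
        raise GeometryError("boundary polygon is self-intersecting")
    h = target_edge
    minx, miny, maxx, maxy = poly.bounds
    inner = poly.buffer(-0.62 * h)
    pts = [boundary_pts]
    if not inner.is_empty:
        dy = h * np.sqrt(3.0) / 2.0
        rows = np.arange(miny + 0.3 * h, maxy, dy)
        for i, y in enumerate(rows):
            xs = np.arange(minx + 0.3 * h + (i % 2) * h / 2.0, maxx, h)
            if len(xs) == 0:
                continue
            cand = np.column_stack([xs, np.full_like(xs, y)])
            keep = shapely.contains_xy(inner, cand[:, 0], cand[:, 1])
            if keep.any():
                pts.append(cand[keep])
    points = np.concatenate(pts, axis=0)
    tri = Delaunay(points)
    cent = points[tri.simplices].mean(axis=1)
    keep = shapely.contains_xy(poly.buffer(1e-9 * h), cent[:, 0], cent[:, 1])
    # drop degenerate hull slivers from (nearly) collinear boundary points
    area, _, _ = fem.tri_geometry(points, tri.simplices)
    keep &= np.abs(area) > 1e-6 * np.median(np.abs(area))
    tris = tri.simplices[keep]
    used = np.unique(tris)
    if len(used) < len(points):  # drop orphan nodes
        remap = -np.ones(len(points), dtype=np.int64)
        remap[used] = np.arange(len(used))
        points = points[used]
        tris = remap[tris]
    return GrowingMesh(points, tris, target_edge)


def _ellipse_boundary(a: float, b: float, target_edge: float) -> NDArray:
    """Points on the ellipse x^2/a^2 + y^2/b^2 = 1 equally spaced in arc length."""
    t = np.linspace(0.0, 2 * np.pi, 4096)
    xy = np.column_stack([a * np.cos(t), b * np.sin(t)])
    seg = np.hypot(*np.diff(xy, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    perim = s[-1]
    n_b = max(12, int(round(perim / target_edge)))
    s_eq = np.linspace(0.0, perim, n_b, endpoint=False)
    x = np.interp(s_eq, s, xy[:, 0])
    y = np.interp(s_eq, s, xy[:, 1])
    return np.column_stack([x, y])


def make_ellipse_mesh(a: float, b: float, target_edge: float) -> GrowingMesh:
    """Quasi-uniform triangulation of an ellipse with semi-axes a (AP), b (DV)."""
    if a <= 0 or b <= 0 or target_edge <= 0:
        raise InvalidArgument("semi-axes and target edge length must be positive")
    if target_edge > min(a, b):
        raise InvalidArgument("target edge length must resolve the ellipse")
    return _mesh_polygon(_ellipse_boundary(a, b, target_edge), target_edge)


# -- remeshing and field transfer --------------------------------------------


def transfer_fields(
    old: GrowingMesh, new: GrowingMesh, fields: dict[str, NDArray]
) -> dict[str, NDArray]:
    """Linearly interpolate nodal fields from `old` onto `new` nodes.

    Points of the new mesh outside the old triangulation (boundary jitter)
    fall back to nearest-node values. Constants transfer exactly.
    """
    out: dict[str, NDArray] = {}
    names = list(fields)
    stacked = np.column_stack([np.asarray(fields[k], dtype=float) for k in names])
    lin = LinearNDInterpolator(old.points, stacked)
    vals = lin(new.points)
    bad = np.isnan(vals).any(axis=1)
    if bad.any():
        near = NearestNDInterpolator(old.points, stacked)
        vals[bad] = near(new.points[bad])
    for i, k in enumerate(names):
        out[k] = vals[:, i]
    return out


def remesh(
    mesh: GrowingMesh, fields: dict[str, NDArray] | None = None
) -> tuple[GrowingMesh, dict[str, NDArray]]:
    """Retriangulate the current boundary polygon and transfer nodal fields.

    The boundary loop is resampled at the target edge length so boundary
    resolution tracks domain growth; the enclosed area is preserved up to
    the polygon resampling error (well below 0.1% at default resolution).
    """
    loop = mesh.boundary_loop()
    bpts = mesh.points[loop]
    # resample the closed polyline at ~target_edge spacing
    closed = np.vstack([bpts, bpts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    perim = s[-1]
    n_b = max(12, int(round(perim / mesh.target_edge)))
    s_eq = np.linspace(0.0, perim, n_b, endpoint=False)
    bx = np.interp(s_eq, s, closed[:, 0])
    by = np.interp(s_eq, s, closed[:, 1])
    new = _mesh_polygon(np.column_stack([bx, by]), mesh.target_edge)
    new_fields = transfer_fields(mesh, new, fields) if fields else {}
    return new, new_fields


# -- snapshot export ----------------------------------------------------------


def write_vtk(mesh: GrowingMesh, fields: dict[str, NDArray], path) -> None:
    """Write the mesh with nodal fields as a legacy-ASCII VTK file."""
    n, m = mesh.n_nodes, len(mesh.tris)
    lines = [
        "# vtk DataFile Version 3.0",
        "eye disc snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for x, y in mesh.points:
        lines.append(f"{x:.8g} {y:.8g} 0")
    lines.append(f"CELLS {m} {4 * m}")
    for a, b, c in mesh.tris:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)  # VTK_TRIANGLE
    if fields:
        lines.append(f"POINT_DATA {n}")
        for name, values in fields.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.8g}" for v in np.asarray(values, dtype=float))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_csv(mesh: GrowingMesh, fields: dict[str, NDArray], path) -> None:
    """Flat CSV snapshot: node id, coordinates and nodal fields."""
    import pandas as pd

    df = pd.DataFrame({
        "node": np.arange(mesh.n_nodes),
        "x_um": mesh.points[:, 0],
        "y_um": mesh.points[:, 1],
        **{k: np.asarray(v, dtype=float) for k, v in fields.items()},
    })
    df.to_csv(path, index=False)
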