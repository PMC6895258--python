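"""Computational-geometry primitives shared across the package.

Provides mask-bounded Voronoi tessellations in 2D (exact polygon clipping via
shapely) and 3D (convex cell polyhedra clipped to the prism spanned by the
mask polygon and an axial slab).
"""

from __future__ import annotations

import math
import numpy as np
import shapely
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, Delaunay, HalfspaceIntersection, Voronoi
from shapely.geometry import Polygon

from .locdata_io import NuclearMask

__all__ = [
    "deduplicate_points",
    "bounded_voronoi_2d",
    "voronoi_cell_volumes_3d",
    "triangulate_polygon",
]

_JITTER = 1e-6  # nm; deterministic nudge for coincident seeds


def deduplicate_points(points: np.ndarray) -> np.ndarray:
    """Jitter exact duplicates deterministically (keyed by row index).

    Tessellation requires distinct seeds; the 1e-6 nm magnitude is far below
    any physical length scale in the data.
    """
    points = np.array(points, dtype=float)
    seen: dict[tuple, int] = {}
    for i, row in enumerate(points):
        key = tuple(row)
        if key in seen:
            angle = 2.399963229728653 * i  # golden-angle spread, deterministic
            points[i, 0] += _JITTER * math.cos(angle)
            points[i, 1] += _JITTER * math.sin(angle)
            if points.shape[1] > 2:
                points[i, 2] += _JITTER * math.sin(angle / 2.0)
        else:
            seen[key] = i
    return points


# ---------------------------------------------------------------------------
# 2D


def _ghost_ring(points: np.ndarray, n_ghosts: int = 24) -> np.ndarray:
    center = points.mean(axis=0)
    span = np.linalg.norm(np.ptp(points, axis=0)) + 1.0
    radius = 10.0 * span
    angles = np.linspace(0.0, 2.0 * np.pi, n_ghosts, endpoint=False)
    return center + radius * np.column_stack([np.cos(angles), np.sin(angles)])


def bounded_voronoi_2d(points: np.ndarray, mask: NuclearMask):
    """Voronoi cells of ``points`` clipped to the usable mask area.

    A distant ring of ghost seeds makes every real cell finite; the ring
    radius is large enough that no ghost bisector intersects the mask, so the
    clipped cells tile the usable area exactly.

    Returns
    -------
    list of shapely geometries (possibly empty for points outside the mask),
    one per input point, in input order.
    """
    points = deduplicate_points(np.asarray(points, float))
    if len(points) < 2:
        return [mask.usable] if len(points) == 1 else []
    all_points = np.vstack([points, _ghost_ring(points)])
    vor = Voronoi(all_points)
    usable = mask.usable
    prepared = shapely.prepared.prep(usable)
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            cells.append(Polygon())
            continue
        poly = Polygon(vor.vertices[region])
        if not poly.is_valid:
            poly = poly.buffer(0)
        # fast path: interior cells need no clipping
        if prepared.contains_properly(poly):
            cells.append(poly)
        else:
            cells.append(poly.intersection(usable))
    return cells


# ---------------------------------------------------------------------------
# 3D


def triangulate_polygon(poly: Polygon) -> list[np.ndarray]:
    """Fan/ear triangulation of a simple polygon (no holes).

    Prefers GEOS constrained Delaunay when available, falling back to ear
    clipping.  Returns a list of (3, 2) vertex arrays.
    """
    try:
        tris = shapely.constrained_delaunay_triangles(poly)
        out = [np.asarray(t.exterior.coords[:-1], float) for t in tris.geoms]
        if out and abs(sum(_tri_area(t) for t in out) - poly.area) < 1e-6 * poly.area:
            return out
    except Exception:  # fall back to ear clipping
        pass
    return _ear_clip(np.asarray(poly.exterior.coords[:-1], float))


def _tri_area(tri: np.ndarray) -> float:
    a, b, c = tri
    return 0.5 * abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))


def _ear_clip(vertices: np.ndarray) -> list[np.ndarray]:
    verts = list(range(len(vertices)))
    # enforce counter-clockwise orientation
    area2 = 0.0
    for i in range(len(vertices)):
        j = (i + 1) % len(vertices)
        area2 += vertices[i, 0] * vertices[j, 1] - vertices[j, 0] * vertices[i, 1]
    if area2 < 0:
        verts.reverse()
    tris = []
    guard = 0
    while len(verts) > 3 and guard < 10000:
        guard += 1
        n = len(verts)
        for k in range(n):
            i0, i1, i2 = verts[(k - 1) % n], verts[k], verts[(k + 1) % n]
            a, b, c = vertices[i0], vertices[i1], vertices[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
            if cross <= 0:
                continue  # reflex vertex
            ear = Polygon([a, b, c])
            if any(ear.contains(shapely.points(vertices[j])) for j in verts
                   if j not in (i0, i1, i2)):
                continue
            tris.append(np.array([a, b, c]))
            verts.pop(k)
            break
        else:
            break
    if len(verts) == 3:
        tris.append(vertices[verts])
    return tris


def _halfspace_volume(halfspaces: np.ndarray, interior: np.ndarray | None = None) -> float:
    """Volume of the polytope {x : A x + b <= 0}; 0 if empty/degenerate."""
    if interior is None:
        interior = _chebyshev_center(halfspaces)
        if interior is None:
            return 0.0
    try:
        hs = HalfspaceIntersection(halfspaces, interior)
        return float(ConvexHull(hs.intersections).volume)
    except Exception:  # qhull degeneracies on slivers
        return 0.0


def _chebyshev_center(halfspaces: np.ndarray):
    """Interior point maximizing distance to all facets, via a small LP."""
    A = halfspaces[:, :-1]
    b = -halfspaces[:, -1]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    dim = A.shape[1]
    c = np.zeros(dim + 1)
    c[-1] = -1.0
    res = linprog(c, A_ub=np.hstack([A, norms]), b_ub=b,
                  bounds=[(None, None)] * dim + [(0, None)], method="highs")
    if not res.success or res.x[-1] <= 1e-12:
        return None
    return res.x[:-1]


def voronoi_cell_volumes_3d(points: np.ndarray, mask: NuclearMask,
                            z_bounds: tuple[float, float] | None = None) -> np.ndarray:
    """Volumes of 3D Voronoi cells clipped to the mask prism over a z slab.

    The cell of each seed is the intersection of bisector half-spaces with its
    Delaunay neighbours; its clipped volume is accumulated over a triangulated
    decomposition of the usable mask area (boundary triangles minus exclusion
    triangles), each triangle contributing the convex intersection
    cell ∩ (triangle × slab).

    Returns an array of volumes (nm³), one per seed, in input order.
    """
    points = deduplicate_points(np.asarray(points, float))
    n = len(points)
    if n < 5:
        raise ValueError("3D tessellation requires at least 5 points")
    if z_bounds is None:
        zpad = 1e-9 + 1e-12 * np.ptp(points[:, 2])
        z_bounds = (points[:, 2].min() - zpad, points[:, 2].max() + zpad)
    z_lo, z_hi = z_bounds

    tri = Delaunay(points)
    indptr, indices = tri.vertex_neighbor_vertices

    boundary_tris = triangulate_polygon(mask.boundary)
    exclusion_tris = [t for p in mask.exclusions for t in triangulate_polygon(p)]

    def prism_halfspaces(t: np.ndarray) -> np.ndarray:
        rows = []
        # CCW orientation so inward normals are consistent
        if _signed_area(t) < 0:
            t = t[::-1]
        for k in range(3):
            a, b = t[k], t[(k + 1) % 3]
            nx, ny = b[1] - a[1], a[0] - b[0]  # outward normal of CCW edge
            rows.append([nx, ny, 0.0, -(nx * a[0] + ny * a[1])])
        rows.append([0.0, 0.0, 1.0, -z_hi])
        rows.append([0.0, 0.0, -1.0, z_lo])
        return np.asarray(rows)

    b_prisms = [prism_halfspaces(t) for t in boundary_tris]
    e_prisms = [prism_halfspaces(t) for t in exclusion_tris]
    b_boxes = [(t[:, 0].min(), t[:, 0].max(), t[:, 1].min(), t[:, 1].max())
               for t in boundary_tris]
    e_boxes = [(t[:, 0].min(), t[:, 0].max(), t[:, 1].min(), t[:, 1].max())
               for t in exclusion_tris]

    volumes = np.zeros(n)
    span = np.linalg.norm(np.ptp(points, axis=0)) + 1.0
    for i in range(n):
        neigh = indices[indptr[i]:indptr[i + 1]]
        p = points[i]
        rows = []
        for j in neigh:
            d = points[j] - p
            mid = 0.5 * (points[j] + p)
            rows.append([d[0], d[1], d[2], -float(d @ mid)])
        # slab + generous lateral box keep the base cell bounded
        rows.append([0.0, 0.0, 1.0, -z_hi])
        rows.append([0.0, 0.0, -1.0, z_lo])
        for sgn in (1.0, -1.0):
            rows.append([sgn, 0.0, 0.0, -(sgn * p[0] + 2 * span)])
            rows.append([0.0, sgn, 0.0, -(sgn * p[1] + 2 * span)])
        cell_hs = np.asarray(rows)

        interior = p.copy()
        interior[2] = min(max(interior[2], z_lo + 1e-12), z_hi - 1e-12)
        slack = cell_hs[:, :3] @ interior + cell_hs[:, 3]
        if np.any(slack >= -1e-12):
            interior = _chebyshev_center(cell_hs)
            if interior is None:
                continue
        try:
            cell_vertices = HalfspaceIntersection(cell_hs, interior).intersections
        except Exception:
            continue
        cx0, cx1 = cell_vertices[:, 0].min(), cell_vertices[:, 0].max()
        cy0, cy1 = cell_vertices[:, 1].min(), cell_vertices[:, 1].max()

        total = 0.0
        for prisms, boxes, sign in ((b_prisms, b_boxes, 1.0), (e_prisms, e_boxes, -1.0)):
            for hs, (tx0, tx1, ty0, ty1) in zip(prisms, boxes):
                if tx1 < cx0 or tx0 > cx1 or ty1 < cy0 or ty0 > cy1:
                    continue
                total += sign * _halfspace_volume(np.vstack([cell_hs, hs]))
        volumes[i] = max(total, 0.0)
    return volumes


def _signed_area(t: np.ndarray) -> float:
    a, b, c = t
    return 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
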