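"""Core geometric containers shared across the package.

All coordinates are world millimetres in a right-handed frame; voxel
centres sit at ``origin + index * spacing`` (0-based indices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh
from scipy.spatial import cKDTree

# Regions of interest along the thoracic aorta.  The aortic arch between
# the brachiocephalic trunk and the left subclavian artery is excluded
# from regional analysis.
ROI_NAMES = ("pAAo", "dAAo", "pDAo", "dDAo")
EXCLUDED = "excluded"
ALL_LABELS = ROI_NAMES + (EXCLUDED,)

STATION_NAMES = (
    "annulus",
    "PA_bifurcation",
    "brachiocephalic",
    "left_subclavian",
    "diaphragm",
)


@dataclass
class SurfaceMesh:
    """Triangulated lumen surface with outward normals and vertex areas.

    ``vertex_area`` is one third of the summed areas of the triangles
    incident to each vertex, so the vertex areas always sum to the total
    triangle area.
    """

    vertices: np.ndarray  # (n, 3) mm
    faces: np.ndarray  # (m, 3) int
    normals: np.ndarray = None  # (n, 3) outward unit vectors
    vertex_area: np.ndarray = None  # (n,) mm^2
    _tree: Optional[cKDTree] = field(default=None, repr=False, compare=False)
    _vf_adj: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.normals is None or self.vertex_area is None:
            tm = trimesh.Trimesh(self.vertices, self.faces, process=False)
            if self.normals is None:
                n = np.asarray(tm.vertex_normals, dtype=float).copy()
                lens = np.linalg.norm(n, axis=1)
                lens[lens == 0] = 1.0
                self.normals = n / lens[:, None]
            if self.vertex_area is None:
                self.vertex_area = vertex_areas(self.vertices, self.faces)

    # -- derived quantities ------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def total_area(self) -> float:
        return float(self.vertex_area.sum())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.vertices)
        return self._tree

    def vertex_face_adjacency(self) -> np.ndarray:
        """Padded (n_vertices, max_degree) array of incident face ids, -1 padded."""
        if self._vf_adj is None:
            n = self.n_vertices
            counts = np.zeros(n, dtype=np.int64)
            np.add.at(counts, self.faces.ravel(), 1)
            maxdeg = int(counts.max()) if n else 0
            adj = np.full((n, maxdeg), -1, dtype=np.int64)
            cursor = np.zeros(n, dtype=np.int64)
            for fi, tri in enumerate(self.faces):
                for v in tri:
                    adj[v, cursor[v]] = fi
                    cursor[v] += 1
            self._vf_adj = adj
        return self._vf_adj

    def translated(self, offset) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices + np.asarray(offset, dtype=float),
            self.faces.copy(),
            self.normals.copy(),
            self.vertex_area.copy(),
        )


def vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=float)
    f = np.asarray(faces, dtype=np.int64)
    tri = v[f]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    fa = 0.5 * np.linalg.norm(cross, axis=1)
    out = np.zeros(len(v))
    for k in range(3):
        np.add.at(out, f[:, k], fa / 3.0)
    return out


def _closest_point_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest points on triangles (a,b,c) to points p, all (k,3) arrays.

    Vectorised version of the standard barycentric-region walk
    (Ericson, Real-Time Collision Detection, ch. 5).
    """
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    t = np.where(denom != 0, d1 / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    t = np.where(denom != 0, d2 / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    t = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


def point_to_surface(points: np.ndarray, mesh: SurfaceMesh):
    """Distance and closest point from query points to a triangle mesh.

    Candidate triangles are those incident to the nearest vertex of each
    query, which is exact on meshes whose triangles are small relative to
    the query offsets (the regime of all surfaces handled here).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    _, vidx = mesh.kdtree().query(points, workers=-1)
    adj = mesh.vertex_face_adjacency()
    cand = adj[vidx]  # (k, maxdeg)
    k, md = cand.shape
    valid = cand >= 0
    cand_safe = np.where(valid, cand, 0)
    tri = mesh.vertices[mesh.faces[cand_safe]]  # (k, md, 3, 3)
    pq = np.repeat(points[:, None, :], md, axis=1).reshape(-1, 3)
    cp = _closest_point_on_triangles(
        pq, tri[:, :, 0].reshape(-1, 3), tri[:, :, 1].reshape(-1, 3), tri[:, :, 2].reshape(-1, 3)
    ).reshape(k, md, 3)
    d = np.linalg.norm(cp - points[:, None, :], axis=2)
    d[~valid] = np.inf
    best = np.argmin(d, axis=1)
    rows = np.arange(k)
    return d[rows, best], cp[rows, best]


def symmetric_surface_distance(
    mesh_a: SurfaceMesh, mesh_b: SurfaceMesh, max_points: int = 1500
) -> float:
    """Symmetric mean nearest-neighbour vertex-to-surface distance (mm)."""

    def directed(src: SurfaceMesh, dst: SurfaceMesh) -> float:
        v = src.vertices
        if len(v) > max_points:
            idx = np.linspace(0, len(v) - 1, max_points).astype(int)
            v = v[idx]
        d, _ = point_to_surface(v, dst)
        return float(d.mean())

    return 0.5 * (directed(mesh_a, mesh_b) + directed(mesh_b, mesh_a))


@dataclass
class Centerline:
    """Ordered lumen-axis points with arclength and named landmark stations."""

    points: np.ndarray  # (k, 3) mm
    arclength: np.ndarray = None  # (k,) cumulative mm from the annulus
    stations: dict = field(default_factory=dict)
    side: np.ndarray = None  # per-point 'ascending' | 'arch' | 'descending'
    _tree: Optional[cKDTree] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.arclength is None:
            seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
            self.arclength = np.concatenate([[0.0], np.cumsum(seg)])
        self.arclength = np.asarray(self.arclength, dtype=float)
        if self.side is None and self.stations:
            self.side = self._compute_side()

    def _compute_side(self) -> np.ndarray:
        bra = self.stations.get("brachiocephalic")
        lsa = self.stations.get("left_subclavian")
        side = np.full(len(self.points), "descending", dtype=object)
        if bra is not None:
            side[self.arclength < bra] = "ascending"
            if lsa is not None:
                side[(self.arclength >= bra) & (self.arclength < lsa)] = "arch"
        return side

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def kdtree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def nearest(self, points: np.ndarray):
        """(distance, arclength, index) of the nearest centerline point."""
        pts = np.atleast_2d(points)
        d, idx = self.kdtree().query(pts, workers=-1)
        return d, self.arclength[idx], idx

    def point_at(self, s: float) -> np.ndarray:
        return np.array(
            [np.interp(s, self.arclength, self.points[:, k]) for k in range(3)]
        )

    def tangent_at(self, s: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.arclength, s), 1, len(self.points) - 1))
        t = self.points[i] - self.points[i - 1]
        return t / np.linalg.norm(t)

    def tangents(self) -> np.ndarray:
        t = np.gradient(self.points, self.arclength, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        return t

    def with_stations(self, stations: dict) -> "Centerline":
        order = ["annulus", "PA_bifurcation", "brachiocephalic", "left_subclavian", "diaphragm"]
        vals = [stations[k] for k in order if k in stations]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("landmark stations are not ordered along the flow direction")
        return Centerline(self.points.copy(), self.arclength.copy(), dict(stations))


@dataclass
class VertexField:
    """Per-vertex scalar or 3-vector values bound to a specific mesh."""

    values: np.ndarray
    mesh: SurfaceMesh
    name: str = ""
    flags: np.ndarray = None  # True where a vertex is unreliable / excluded

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.mesh.n_vertices:
            raise ValueError("field length does not match mesh vertex count")
        if self.flags is None:
            self.flags = np.zeros(self.mesh.n_vertices, dtype=bool)

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == 2


@dataclass
class Deformation:
    """Result of non-rigid registration of a source mesh onto a target surface."""

    mapped_vertices: np.ndarray  # (n, 3) position per source vertex
    residual: np.ndarray  # (n,) distance from mapped vertex to target surface
    source: SurfaceMesh = None
    target: SurfaceMesh = None
    converged: bool = True
    pre_distance: float = np.nan  # symmetric surface distance before registration

    @property
    def displacement(self) -> np.ndarray:
        return self.mapped_vertices - self.source.vertices

    @property
    def mean_residual(self) -> float:
        return float(self.residual.mean())
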