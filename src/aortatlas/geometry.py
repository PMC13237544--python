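"""Surface and centerline geometry.

Masks are converted to world-millimetre surfaces by marching cubes;
centerlines are distance-transform-weighted minimum-cost paths; ROI
labelling, diameter measurement, template selection and non-rigid
surface registration build on these.

The non-rigid registration is a coherent-point-drift-style scheme: the
displacement field is expanded in a Gaussian kernel over a set of control
vertices and iteratively fitted to tangent-plane projections of the
current vertices onto the target surface, with an annealed ridge penalty.
What is guaranteed is the contract, not the algorithm: identity inputs
map to themselves, the mapped vertices land on the target surface
(mean residual below half a voxel), and the deformation is spatially
smooth.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import splev, splprep
from scipy.linalg import cho_factor, cho_solve
from scipy.ndimage import distance_transform_edt, gaussian_filter1d, label as cc_label
from scipy.spatial import cKDTree
from skimage import measure
from skimage.graph import MCP_Geometric
import trimesh

from .core import (
    Centerline,
    Deformation,
    EXCLUDED,
    ROI_NAMES,
    SurfaceMesh,
    VertexField,
    point_to_surface,
    symmetric_surface_distance,
    vertex_areas,
)

__all__ = [
    "mask_to_surface",
    "extract_centerline",
    "label_rois",
    "measure_diameter",
    "select_template",
    "register_nonrigid",
    "interpolate_to_mesh",
]


def mask_to_surface(
    mask: np.ndarray,
    spacing: float,
    origin=(0.0, 0.0, 0.0),
    smoothing_iterations: int = 5,
    step_size: int = 1,
) -> SurfaceMesh:
    """Extract the lumen surface from a binary mask.

    Marching cubes at the 0.5 level, largest connected component only,
    light Laplacian smoothing, with outward normal orientation verified
    against the mask interior.
    """
    mask = np.asarray(mask)
    if not mask.any():
        raise ValueError("empty mask")
    lab, n_comp = cc_label(mask > 0)
    if n_comp > 1:
        sizes = np.bincount(lab.ravel())[1:]
        order = np.argsort(sizes)[::-1]
        if len(sizes) > 1 and sizes[order[1]] > 0.1 * sizes[order[0]]:
            raise ValueError(
                "ambiguous mask: multiple foreground components of comparable size"
            )
        mask = lab == (order[0] + 1)

    verts, faces, _, _ = measure.marching_cubes(
        mask.astype(np.float32), level=0.5, spacing=(spacing,) * 3, step_size=step_size
    )
    tm = trimesh.Trimesh(verts, faces, process=False)
    if smoothing_iterations > 0:
        trimesh.smoothing.filter_laplacian(
            tm, lamb=0.5, iterations=smoothing_iterations, volume_constraint=False
        )
    verts = np.asarray(tm.vertices) + np.asarray(origin, dtype=float)
    faces = np.asarray(tm.faces)
    normals = np.asarray(tm.vertex_normals).copy()
    lens = np.linalg.norm(normals, axis=1, keepdims=True)
    lens[lens == 0] = 1.0
    normals = normals / lens

    # orientation check: stepping inward along -n must land inside the mask
    # more often than stepping outward
    probe = 1.5 * spacing
    inward = _sample_mask(mask, (verts - probe * normals - origin) / spacing)
    outward = _sample_mask(mask, (verts + probe * normals - origin) / spacing)
    if inward.mean() < outward.mean():
        normals = -normals
        faces = faces[:, ::-1]
    return SurfaceMesh(verts, faces, normals, vertex_areas(verts, faces))


def _sample_mask(mask: np.ndarray, idx_coords: np.ndarray) -> np.ndarray:
    ij = np.round(idx_coords).astype(int)
    ok = np.all((ij >= 0) & (ij < np.array(mask.shape)), axis=1)
    out = np.zeros(len(ij), dtype=bool)
    out[ok] = mask[ij[ok, 0], ij[ok, 1], ij[ok, 2]] > 0
    return out


def extract_centerline(
    lumen_mask: np.ndarray,
    spacing: float,
    inlet_point,
    outlet_point,
    origin=(0.0, 0.0, 0.0),
    stations: dict = None,
    smooth_mm: float = 5.0,
    resample_mm: float = 1.0,
) -> Centerline:
    """Lumen axis from inlet to outlet as the distance-transform-weighted
    minimum-cost path, smoothed and resampled at 1 mm arclength steps."""
    origin = np.asarray(origin, dtype=float)
    mask = np.asarray(lumen_mask) > 0
    inlet = np.round((np.asarray(inlet_point, dtype=float) - origin) / spacing).astype(int)
    outlet = np.round((np.asarray(outlet_point, dtype=float) - origin) / spacing).astype(int)
    for name, p in (("inlet", inlet), ("outlet", outlet)):
        if np.any(p < 0) or np.any(p >= np.array(mask.shape)) or not mask[tuple(p)]:
            p2 = _snap_into_mask(mask, p)
            if p2 is None:
                raise ValueError(f"{name} point is outside the lumen mask")
            if name == "inlet":
                inlet = p2
            else:
                outlet = p2

    dt = distance_transform_edt(mask, sampling=spacing)
    cost = np.where(mask, 1.0 / (dt + 0.5 * spacing), np.inf)
    mcp = MCP_Geometric(cost, fully_connected=True, sampling=(spacing,) * 3)
    costs, _ = mcp.find_costs([tuple(inlet)], [tuple(outlet)])
    if not np.isfinite(costs[tuple(outlet)]):
        raise ValueError("lumen mask is disconnected between inlet and outlet")
    path = np.asarray(mcp.traceback(tuple(outlet)), dtype=float)
    pts = origin + path * spacing

    # smooth (moving average in mm) then spline-resample at fixed arclength
    win = max(1, int(round(smooth_mm / spacing)))
    if win > 1 and len(pts) > 2 * win:
        sm = np.copy(pts)
        for k in range(3):
            sm[:, k] = gaussian_filter1d(pts[:, k], win / 2.0, mode="nearest")
        sm[0], sm[-1] = pts[0], pts[-1]
        pts = sm
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], seg > 1e-9])
    pts = pts[keep]
    if len(pts) >= 4:
        tck, _ = splprep(pts.T, s=len(pts) * (0.25 * spacing) ** 2, k=3)
        u = np.linspace(0, 1, 4 * len(pts))
        pts = np.column_stack(splev(u, tck))
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    s_new = np.arange(0.0, s[-1] + resample_mm / 2, resample_mm)
    pts = np.column_stack([np.interp(s_new, s, pts[:, k]) for k in range(3)])
    cl = Centerline(pts, s_new.copy())
    if stations:
        cl = cl.with_stations(
            {k: float(np.clip(v, 0, s_new[-1])) for k, v in stations.items()}
        )
    return cl


def _snap_into_mask(mask: np.ndarray, p: np.ndarray, radius: int = 4):
    """Nearest in-mask voxel within a small neighbourhood, or None."""
    shape = np.array(mask.shape)
    lo = np.maximum(p - radius, 0)
    hi = np.minimum(p + radius + 1, shape)
    if np.any(lo >= hi):
        return None
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if not sub.any():
        return None
    cand = np.argwhere(sub) + lo
    d = np.linalg.norm(cand - p, axis=1)
    return cand[np.argmin(d)]


def descending_pa_level_from_centerline(cl: Centerline) -> float:
    """Arclength on the descending limb at the same axial height as the
    PA-bifurcation station.

    The axial direction is the dominant direction of the descending
    segment of the centerline (the distal half beyond the left subclavian
    station).
    """
    lsa = cl.stations["left_subclavian"]
    pa = cl.stations["PA_bifurcation"]
    desc = cl.arclength >= lsa + 0.2 * (cl.arclength[-1] - lsa)
    if desc.sum() < 2:
        raise ValueError("centerline has no descending segment beyond the arch")
    seg = cl.points[desc]
    axis = seg[-1] - seg[0]
    axis = axis / np.linalg.norm(axis)
    h_pa = float(cl.point_at(pa) @ axis)
    h = cl.points[desc] @ axis
    i = int(np.argmin(np.abs(h - h_pa)))
    return float(cl.arclength[desc][i])


def label_rois(mesh: SurfaceMesh, cl: Centerline) -> np.ndarray:
    """Per-vertex ROI label from the arclength of the nearest centerline point.

    Bands: [annulus, PA_bif) -> pAAo; [PA_bif, brachiocephalic) -> dAAo;
    [brachiocephalic, left_subclavian) -> excluded (arch);
    [left_subclavian, PA-bif level on the descending limb) -> pDAo;
    beyond, up to the diaphragm -> dDAo.
    """
    for st in ("annulus", "PA_bifurcation", "brachiocephalic", "left_subclavian", "diaphragm"):
        if st not in cl.stations:
            raise ValueError(f"missing station {st!r}")
    _, s_v, _ = cl.nearest(mesh.vertices)
    st = cl.stations
    pa_desc = descending_pa_level_from_centerline(cl)
    labels = np.full(mesh.n_vertices, EXCLUDED, dtype=object)
    labels[(s_v >= st["annulus"]) & (s_v < st["PA_bifurcation"])] = "pAAo"
    labels[(s_v >= st["PA_bifurcation"]) & (s_v < st["brachiocephalic"])] = "dAAo"
    labels[(s_v >= st["left_subclavian"]) & (s_v < pa_desc)] = "pDAo"
    labels[(s_v >= pa_desc) & (s_v <= st["diaphragm"])] = "dDAo"
    return labels


def measure_diameter(
    mesh: SurfaceMesh, cl: Centerline, station_arclength: float, mode: str = "area"
) -> float:
    """Diameter of the cross-section perpendicular to the centerline.

    'area' reports the area-equivalent diameter 2*sqrt(A/pi); the root
    station may instead use 'cusp_to_cusp', the maximum point-pair
    distance in the section.
    """
    if not (cl.arclength[0] <= station_arclength <= cl.arclength[-1]):
        raise ValueError("station outside centerline range")
    p0 = cl.point_at(station_arclength)
    n = cl.tangent_at(station_arclength)
    tm = mesh.to_trimesh()
    segments = trimesh.intersections.mesh_plane(tm, n, p0)
    if len(segments) == 0:
        raise ValueError("empty cross-section at the requested station")
    pts = segments.reshape(-1, 3)
    # keep only the loop around this centerline point (a plane through the
    # arch can also cut the other limb)
    d = np.linalg.norm(pts - p0, axis=1)
    r_low = np.percentile(d, 25)
    keep = d < max(2.5 * r_low, r_low + 5.0)
    pts = pts[keep]
    if len(pts) < 6:
        raise ValueError("degenerate cross-section")
    if mode == "cusp_to_cusp":
        from scipy.spatial.distance import pdist

        return float(pdist(pts).max())
    if mode != "area":
        raise ValueError("mode must be 'area' or 'cusp_to_cusp'")
    # project into the section plane and take the polygon area (angular
    # ordering; cross-sections are star-shaped about the axis)
    e1 = np.cross(n, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    rel = pts - pts.mean(axis=0)
    u, v = rel @ e1, rel @ e2
    order = np.argsort(np.arctan2(v, u))
    u, v = u[order], v[order]
    area = 0.5 * abs(np.sum(u * np.roll(v, -1) - v * np.roll(u, -1)))
    return float(2.0 * np.sqrt(area / np.pi))


def select_template(meshes, max_points: int = 1500) -> int:
    """Index of the mesh with the smallest mean symmetric surface distance
    to all the others; ties broken by lowest index."""
    if len(meshes) < 2:
        raise ValueError("template selection needs at least 2 meshes")
    n = len(meshes)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = symmetric_surface_distance(
                meshes[i], meshes[j], max_points
            )
    means = dist.sum(axis=1) / (n - 1)
    return int(np.argmin(means))


def _gauss_kernel(a: np.ndarray, b: np.ndarray, beta: float) -> np.ndarray:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * beta**2))


def register_nonrigid(
    source: SurfaceMesh,
    target: SurfaceMesh,
    beta: float = 20.0,
    n_control: int = 400,
    iterations: int = 30,
    lam_initial: float = 10.0,
    lam_final: float = 1e-2,
    residual_tolerance: float = 0.5,
    seed: int = 0,
) -> Deformation:
    """Non-rigid registration of the source surface onto the target.

    Gaussian-kernel-regularised motion (coherent-point-drift family):
    after centroid alignment, a smooth displacement field parameterised at
    `n_control` evenly spaced source vertices is iteratively fitted to the
    tangent-plane projections of the current vertices onto the target,
    with the ridge penalty annealed from `lam_initial` to `lam_final`.
    `beta` (mm) is the spatial coherence scale of the field.

    A result whose mean surface residual exceeds `residual_tolerance` is
    returned flagged (``converged=False``), never as a silent success.
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise ValueError("cannot register empty meshes")
    V = source.vertices
    pre = symmetric_surface_distance(source, target)

    t0 = target.vertices.mean(axis=0) - V.mean(axis=0)
    # refine the global translation by rigid point-to-plane steps: centroid
    # alignment alone is biased when the target deforms asymmetrically, and
    # its tangential error would otherwise persist as spurious displacement
    t_tree = target.kdtree()
    Tn = target.normals
    Tv = target.vertices
    for _ in range(10):
        cur = V + t0
        _, j = t_tree.query(cur, workers=-1)
        q, nq = Tv[j], Tn[j]
        off = np.einsum("ij,ij->i", cur - q, nq)
        A = nq.T @ nq + 1e-9 * len(nq) * np.eye(3)
        tau = np.linalg.solve(A, -(off[:, None] * nq).sum(axis=0))
        t0 = t0 + tau
        if np.linalg.norm(tau) < 1e-4:
            break
    n_ctrl = min(n_control, source.n_vertices)
    ctrl_idx = np.unique(np.linspace(0, source.n_vertices - 1, n_ctrl).astype(int))
    C = V[ctrl_idx]
    K_cc = _gauss_kernel(C, C, beta)
    K_vc = _gauss_kernel(V, C, beta)
    W = np.zeros((len(ctrl_idx), 3))

    lams = np.geomspace(lam_initial, lam_final, iterations)
    best = None
    cur = V + t0
    for lam in lams:
        _, j = t_tree.query(cur, workers=-1)
        q, nq = Tv[j], Tn[j]
        off = np.einsum("ij,ij->i", cur - q, nq)
        goal = cur - off[:, None] * nq
        D = goal - cur
        try:
            fac = cho_factor(K_cc + lam * np.eye(len(ctrl_idx)))
            W = W + 0.8 * cho_solve(fac, D[ctrl_idx])
        except np.linalg.LinAlgError:
            break
        cur = V + t0 + K_vc @ W
        _, j2 = t_tree.query(cur, workers=-1)
        res_now = np.abs(np.einsum("ij,ij->i", cur - Tv[j2], Tn[j2])).mean()
        if best is None or res_now < best[0]:
            best = (res_now, cur.copy())
    cur = best[1] if best is not None else cur

    residual, _ = point_to_surface(cur, target)
    converged = float(residual.mean()) <= residual_tolerance
    # registration must not worsen the fit relative to the raw input
    if residual.mean() > pre:
        residual0, _ = point_to_surface(V, target)
        if residual0.mean() < residual.mean():
            cur, residual, converged = V.copy(), residual0, False
    return Deformation(
        mapped_vertices=cur,
        residual=residual,
        source=source,
        target=target,
        converged=converged,
        pre_distance=pre,
    )


def interpolate_to_mesh(
    values: VertexField, deformation: Deformation, target: SurfaceMesh, k: int = 3
) -> VertexField:
    """Carry a per-vertex field through a registration onto a target mesh.

    Inverse-distance weighting (power 2) over the k nearest mapped source
    vertices; exact at coincident vertices.
    """
    if len(values.values) != len(deformation.mapped_vertices):
        raise ValueError("field is not bound to the deformation's source mesh")
    if len(values.values) == 0:
        raise ValueError("empty source field")
    tree = cKDTree(deformation.mapped_vertices)
    k = min(k, len(values.values))
    d, idx = tree.query(target.vertices, k=k, workers=-1)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    w = 1.0 / np.maximum(d, 1e-12) ** 2
    exact = d[:, 0] < 1e-9
    w[exact] = 0.0
    w[exact, 0] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    vals = values.values[idx]  # (n, k) or (n, k, 3)
    if values.is_vector:
        out = (vals * w[:, :, None]).sum(axis=1)
    else:
        out = (vals * w).sum(axis=1)
    flags = values.flags[idx[:, 0]].copy()
    return VertexField(out, target, values.name, flags)


def nearest_vertex_transfer(
    values: np.ndarray, deformation: Deformation, target: SurfaceMesh
) -> np.ndarray:
    """Nearest-mapped-vertex transfer (used for binary indicators so that
    counts stay integral)."""
    tree = cKDTree(deformation.mapped_vertices)
    _, idx = tree.query(target.vertices, workers=-1)
    return np.asarray(values)[idx]
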