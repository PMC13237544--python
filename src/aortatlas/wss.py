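"""Wall shear stress from the wall-normal velocity gradient.

Peak systole is the cardiac phase with the highest spatially averaged
velocity magnitude inside the lumen.  At each surface vertex the
velocity is sampled at three points along the inward normal spanning
half the local lumen diameter, the wall sample is forced to zero
(no-slip: boundary voxels mix wall and lumen signal), the unique
quadratic through the three samples is differentiated at the wall, and
the tangential part of the derivative times the dynamic viscosity is the
WSS vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core import Centerline, SurfaceMesh

DEFAULT_VISCOSITY_PA_S = 3.2e-3


@dataclass
class WSSMap:
    vectors: np.ndarray  # (n, 3) Pa, tangential to the wall
    magnitude: np.ndarray  # (n,) Pa
    phase_index: int
    viscosity: float
    mesh: SurfaceMesh = None
    flags: np.ndarray = None  # True where a vertex could not be evaluated


def peak_systole_frame(velocity: np.ndarray, lumen_mask: np.ndarray) -> int:
    """Phase with the highest spatially averaged velocity magnitude within
    the segmented volume; ties break to the earliest phase."""
    lumen = np.asarray(lumen_mask) > 0
    if not lumen.any():
        raise ValueError("empty lumen mask")
    if velocity.shape[2:] != lumen.shape:
        raise ValueError("velocity and lumen mask grids differ")
    means = np.empty(len(velocity))
    for t in range(len(velocity)):
        v = velocity[t][:, lumen].astype(np.float64)
        means[t] = np.sqrt((v**2).sum(axis=0)).mean()
    return int(np.argmax(means))


def local_lumen_diameter(mesh: SurfaceMesh, cl: Centerline) -> np.ndarray:
    """D(v) = 2 * distance from the vertex to the nearest centerline point.

    Vertices beyond the centerline ends use the nearest available point
    (no extrapolation).
    """
    d, _, _ = cl.nearest(mesh.vertices)
    return 2.0 * d


def wss_vectors(
    velocity_frame: np.ndarray,
    mesh: SurfaceMesh,
    cl: Centerline,
    viscosity: float = DEFAULT_VISCOSITY_PA_S,
    spacing: float = 1.0,
    origin=(0.0, 0.0, 0.0),
    lumen_mask: np.ndarray = None,
    phase_index: int = 0,
) -> WSSMap:
    """Per-vertex WSS vectors (Pa) at one cardiac phase.

    velocity_frame is the (3, nx, ny, nz) voxel velocity in cm/s.
    Vertices whose inner sample points leave the lumen mask, or whose
    nearest centerline point is an endpoint (end-cap geometry), are
    flagged and excluded from regional averages downstream.
    """
    origin = np.asarray(origin, dtype=float)
    D = local_lumen_diameter(mesh, cl)
    n = mesh.normals
    v0 = mesh.vertices
    h = D / 4.0  # mm; samples at 0, D/4, D/2 along the inward normal

    def sample(points):
        ic = ((points - origin) / spacing).T  # (3, n)
        comps = [
            map_coordinates(velocity_frame[k].astype(np.float64), ic, order=1, mode="nearest")
            for k in range(3)
        ]
        return np.stack(comps, axis=1)  # (n, 3) cm/s

    p1 = v0 - n * h[:, None]
    p2 = v0 - n * (2 * h)[:, None]
    u1 = sample(p1)
    u2 = sample(p2)
    # u0 is forced to zero (no-slip at the wall)

    flags = ~np.isfinite(u1).all(axis=1) | ~np.isfinite(u2).all(axis=1)
    if lumen_mask is not None:
        lum = np.asarray(lumen_mask)

        def inside(points):
            ij = np.round((points - origin) / spacing).astype(int)
            ok = np.all((ij >= 0) & (ij < np.array(lum.shape)), axis=1)
            out = np.zeros(len(ij), dtype=bool)
            out[ok] = lum[ij[ok, 0], ij[ok, 1], ij[ok, 2]] > 0
            return out

        flags |= ~inside(p1) | ~inside(p2)
    # end caps: nearest centerline point is an endpoint
    _, _, idx = cl.nearest(v0)
    flags |= (idx == 0) | (idx == len(cl.points) - 1)

    # quadratic through (0, 0), (h, u1), (2h, u2): derivative at the wall
    h_m = np.maximum(h, 1e-9) / 1000.0  # mm -> m
    u1_ms = u1 / 100.0  # cm/s -> m/s
    u2_ms = u2 / 100.0
    grad = (4.0 * u1_ms - u2_ms) / (2.0 * h_m[:, None])  # 1/s
    tang = grad - np.einsum("ij,ij->i", grad, n)[:, None] * n
    vec = viscosity * tang
    vec[flags] = 0.0
    mag = np.linalg.norm(vec, axis=1)
    return WSSMap(vec, mag, phase_index, viscosity, mesh, flags)
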