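"""Per-vertex 3D wall displacement across the cardiac cycle.

The end-diastolic surface is registered non-rigidly to every other
cardiac phase and the displacement at a vertex is the Euclidean distance
to its mapped position; the timeframe with the maximum average
displacement is the one carried into regional and atlas analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SurfaceMesh, VertexField
from .geometry import register_nonrigid


@dataclass
class DisplacementMap:
    """Scalar displacement (mm) per vertex of the end-diastolic mesh."""

    values: np.ndarray  # (n,) mm, >= 0
    phase_index: int
    mesh: SurfaceMesh  # the end-diastolic mesh the values are bound to
    flagged: bool = False  # True when the underlying registration failed

    def as_field(self) -> VertexField:
        return VertexField(self.values, self.mesh, name="displacement_mm")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def displacement_series(phase_meshes, ed_index: int, **reg_kwargs):
    """Displacement map per cardiac phase, relative to end-diastole.

    A failed registration yields a flagged map, never a silent zero.
    """
    if len(phase_meshes) < 2:
        raise ValueError("need at least two cardiac phases")
    if not 0 <= ed_index < len(phase_meshes):
        raise ValueError("invalid end-diastolic index")
    ed = phase_meshes[ed_index]
    maps = []
    for t, mesh in enumerate(phase_meshes):
        if t == ed_index:
            maps.append(DisplacementMap(np.zeros(ed.n_vertices), t, ed))
            continue
        d = register_nonrigid(ed, mesh, **reg_kwargs)
        values = np.linalg.norm(d.mapped_vertices - ed.vertices, axis=1)
        maps.append(DisplacementMap(values, t, ed, flagged=not d.converged))
    return maps


def peak_displacement(series):
    """The (phase index, map) with the maximal unweighted vertex-mean
    displacement; ties break to the earliest phase."""
    if not series:
        raise ValueError("empty displacement series")
    means = np.array([m.values.mean() for m in series])
    i = int(np.argmax(means))  # argmax takes the first of equal maxima
    return series[i].phase_index, series[i]


def mean_displacement_table(series, area_weighted: bool = False) -> np.ndarray:
    """Per-phase mean displacement (mm); optionally area-weighted."""
    out = np.empty(len(series))
    for k, m in enumerate(series):
        if area_weighted:
            w = m.mesh.vertex_area
            out[k] = float((m.values * w).sum() / w.sum())
        else:
            out[k] = m.values.mean()
    return out
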