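"""Control-cohort atlases, per-patient abnormality heatmaps, incidence maps.

The normal-value atlas lives on a control geometry template (the control
whose surface has the smallest mean distance to all the others).  Every
control map is registered and interpolated onto the template; the
per-vertex mean and SD define 95% confidence maps (mean +/- 1.96 * SD).
Projecting these maps onto a patient geometry and comparing yields
heatmaps of abnormally increased / decreased values; for WSS vectors,
abnormality is a deviation of more than 120 degrees from the average
control direction.  Incidence maps aggregate binary patient heatmaps on
a patient template as the proportion of patients abnormal per vertex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import SurfaceMesh, VertexField
from .geometry import (
    interpolate_to_mesh,
    nearest_vertex_transfer,
    register_nonrigid,
    select_template,
)

CI_MULTIPLIER = 1.96
DIRECTION_THRESHOLD_DEG = 120.0

# heatmap labels
NORMAL = "normal"
INCREASED = "increased"
DECREASED = "decreased"
ABNORMAL_DIRECTION = "abnormal_direction"


@dataclass
class ScalarAtlas:
    template: SurfaceMesh
    mean: np.ndarray
    sd: np.ndarray  # sample SD (n - 1); control cohorts are small
    n_controls: int
    ci_multiplier: float = CI_MULTIPLIER
    excluded_controls: list = field(default_factory=list)

    @property
    def ci_lower(self) -> np.ndarray:
        return self.mean - self.ci_multiplier * self.sd

    @property
    def ci_upper(self) -> np.ndarray:
        return self.mean + self.ci_multiplier * self.sd


@dataclass
class VectorAtlas:
    template: SurfaceMesh
    mean_direction: np.ndarray  # (n, 3) unit vectors where defined
    resultant_length: np.ndarray  # (n,) in [0, 1]
    n_controls: int
    undefined: np.ndarray = None  # True where no direction could be averaged

    def __post_init__(self):
        if self.undefined is None:
            self.undefined = self.resultant_length < 1e-6


@dataclass
class Heatmap:
    labels: np.ndarray  # per-vertex label strings
    mesh: SurfaceMesh
    kind: str  # 'scalar' | 'direction'
    flags: np.ndarray = None  # vertices classified by fallback rules

    def __post_init__(self):
        if self.flags is None:
            self.flags = np.zeros(self.mesh.n_vertices, dtype=bool)

    def indicator(self, label: str) -> np.ndarray:
        return self.labels == label


@dataclass
class IncidenceMap:
    template: SurfaceMesh
    proportion: np.ndarray  # (n,) in [0, 1]
    n_patients: int
    label: str


def _register_controls(control_meshes, template_index):
    template = control_meshes[template_index]
    deformations = {}
    excluded = []
    for i, mesh in enumerate(control_meshes):
        if i == template_index:
            continue
        d = register_nonrigid(mesh, template)
        if not d.converged:
            warnings.warn(f"control {i} failed registration; excluded from the atlas")
            excluded.append(i)
            continue
        deformations[i] = d
    return template, deformations, excluded


def build_scalar_atlas(
    control_meshes, control_maps, template_index: int = None
) -> ScalarAtlas:
    """Mean / SD / 95% CI maps of a scalar quantity over the control cohort."""
    if len(control_meshes) < 2:
        raise ValueError("atlas construction needs at least 2 controls")
    if len(control_maps) != len(control_meshes):
        raise ValueError("one map per control mesh required")
    if template_index is None:
        template_index = select_template(control_meshes)
    template, deformations, excluded = _register_controls(control_meshes, template_index)

    stacked = [np.asarray(control_maps[template_index], dtype=float)]
    for i, d in deformations.items():
        f = VertexField(np.asarray(control_maps[i], dtype=float), control_meshes[i])
        stacked.append(interpolate_to_mesh(f, d, template).values)
    X = np.vstack(stacked)
    n = X.shape[0]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    return ScalarAtlas(template, mean, sd, n, CI_MULTIPLIER, excluded)


def build_vector_atlas(
    control_meshes, control_vector_maps, template_index: int = None
) -> VectorAtlas:
    """Average control vector direction per vertex (unit-vector mean)."""
    if len(control_meshes) < 2:
        raise ValueError("atlas construction needs at least 2 controls")
    if template_index is None:
        template_index = select_template(control_meshes)
    template, deformations, _ = _register_controls(control_meshes, template_index)

    def unit(v):
        nrm = np.linalg.norm(v, axis=1)
        out = np.zeros_like(v)
        ok = nrm > 1e-12
        out[ok] = v[ok] / nrm[ok, None]
        return out

    stacked = [unit(np.asarray(control_vector_maps[template_index], dtype=float))]
    for i, d in deformations.items():
        f = VertexField(
            unit(np.asarray(control_vector_maps[i], dtype=float)), control_meshes[i]
        )
        stacked.append(unit(interpolate_to_mesh(f, d, template).values))
    U = np.stack(stacked)  # (n_controls, n_vertices, 3)
    # zero vectors are excluded from the per-vertex average
    nonzero = np.linalg.norm(U, axis=2) > 1e-12
    counts = np.maximum(nonzero.sum(axis=0), 1)
    mean_vec = U.sum(axis=0) / counts[:, None]
    resultant = np.linalg.norm(mean_vec, axis=1)
    direction = np.zeros_like(mean_vec)
    ok = resultant > 1e-6
    direction[ok] = mean_vec[ok] / resultant[ok, None]
    undefined = ~ok | (nonzero.sum(axis=0) == 0)
    return VectorAtlas(template, direction, resultant, U.shape[0], undefined)


def project_atlas(atlas, patient_mesh: SurfaceMesh):
    """Carry the atlas fields onto a patient geometry.

    Registers the template to the patient and interpolates; returns a dict
    of per-patient-vertex arrays.  A failed registration raises.
    """
    d = register_nonrigid(atlas.template, patient_mesh)
    if not d.converged:
        raise RuntimeError("template-to-patient registration failed")

    def carry(values):
        return interpolate_to_mesh(
            VertexField(values, atlas.template), d, patient_mesh
        ).values

    if isinstance(atlas, ScalarAtlas):
        return {
            "mean": carry(atlas.mean),
            "sd": carry(atlas.sd),
            "ci_lower": carry(atlas.ci_lower),
            "ci_upper": carry(atlas.ci_upper),
        }
    # vector atlas: interpolate componentwise, renormalize, carry the
    # undefined flag by nearest neighbour
    direction = carry(atlas.mean_direction)
    nrm = np.linalg.norm(direction, axis=1)
    ok = nrm > 1e-9
    direction[ok] = direction[ok] / nrm[ok, None]
    undefined = nearest_vertex_transfer(atlas.undefined.astype(float), d, patient_mesh) > 0.5
    undefined |= ~ok
    return {"mean_direction": direction, "undefined": undefined}


def classify_scalar(patient_map: np.ndarray, projected: dict, mesh: SurfaceMesh) -> Heatmap:
    """Label vertices outside the projected 95% CI; boundary values normal.

    Degenerate vertices (SD = 0) fall back to exact equality with the
    mean — any deviation is abnormal — and are flagged.
    """
    values = np.asarray(patient_map, dtype=float)
    lo, hi = np.asarray(projected["ci_lower"]), np.asarray(projected["ci_upper"])
    if len(values) != len(lo) or len(values) != mesh.n_vertices:
        raise ValueError("patient map and projected CI maps must share the mesh")
    labels = np.full(len(values), NORMAL, dtype=object)
    labels[values > hi] = INCREASED
    labels[values < lo] = DECREASED
    degenerate = hi <= lo
    flags = np.zeros(len(values), dtype=bool)
    if degenerate.any():
        mean = np.asarray(projected["mean"])
        labels[degenerate & (values > mean)] = INCREASED
        labels[degenerate & (values < mean)] = DECREASED
        flags |= degenerate
    return Heatmap(labels, mesh, "scalar", flags)


def classify_direction(
    patient_vectors: np.ndarray,
    projected: dict,
    mesh: SurfaceMesh,
    threshold_deg: float = DIRECTION_THRESHOLD_DEG,
) -> Heatmap:
    """Label vertices whose vector deviates strictly more than the threshold
    angle from the projected mean control direction.

    Zero patient vectors and vertices with undefined atlas direction stay
    normal but flagged.
    """
    v = np.asarray(patient_vectors, dtype=float)
    d = np.asarray(projected["mean_direction"], dtype=float)
    undefined = np.asarray(projected.get("undefined", np.zeros(len(d), dtype=bool)))
    nv = np.linalg.norm(v, axis=1)
    zero = nv < 1e-12
    cosang = np.zeros(len(v))
    ok = ~zero & ~undefined
    cosang[ok] = np.einsum("ij,ij->i", v[ok], d[ok]) / nv[ok]
    cosang = np.clip(cosang, -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))
    labels = np.full(len(v), NORMAL, dtype=object)
    labels[ok & (angle > threshold_deg)] = ABNORMAL_DIRECTION
    return Heatmap(labels, mesh, "direction", flags=zero | undefined)


def build_incidence_map(
    patient_heatmaps,
    patient_meshes,
    template_index: int = None,
    label: str = None,
) -> IncidenceMap:
    """Proportion of patients abnormal at each template vertex.

    Binary indicators travel by nearest-neighbour transfer of mapped
    vertices so per-vertex counts stay integral; proportions are exact
    multiples of 1 / n_patients.
    """
    if len(patient_heatmaps) < 1:
        raise ValueError("need at least one patient")
    if label is None:
        label = INCREASED if patient_heatmaps[0].kind == "scalar" else ABNORMAL_DIRECTION
    if template_index is None:
        template_index = (
            select_template(patient_meshes) if len(patient_meshes) > 1 else 0
        )
    template = patient_meshes[template_index]
    counts = np.zeros(template.n_vertices)
    n_used = 0
    for i, (hm, mesh) in enumerate(zip(patient_heatmaps, patient_meshes)):
        ind = hm.indicator(label).astype(float)
        if i == template_index:
            counts += ind
            n_used += 1
            continue
        d = register_nonrigid(mesh, template)
        if not d.converged:
            warnings.warn(f"patient {i} failed registration; excluded from incidence map")
            continue
        counts += nearest_vertex_transfer(ind, d, template)
        n_used += 1
    if n_used == 0:
        raise RuntimeError("all patients failed registration")
    return IncidenceMap(template, counts / n_used, n_used, label)
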