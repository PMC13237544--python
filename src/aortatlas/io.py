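"""File formats: NIfTI voxel grids, PLY / legacy-VTK surfaces with
per-vertex arrays, CSV centerlines and tables, JSON reports.

The VTK legacy ASCII polydata writer/reader is intentionally minimal: it
covers triangle meshes with named per-vertex scalar and 3-vector arrays,
which is all this pipeline exchanges.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import Centerline, SurfaceMesh


# --------------------------------------------------------------------------
# NIfTI
# --------------------------------------------------------------------------

def save_nifti(path, array: np.ndarray, spacing: float, origin=(0.0, 0.0, 0.0)):
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = np.asarray(origin, dtype=float)
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    affine = img.affine
    spacing = float(affine[0, 0])
    origin = affine[:3, 3].copy()
    return np.asarray(img.dataobj), spacing, origin


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------

def save_ply(path, mesh: SurfaceMesh):
    mesh.to_trimesh().export(str(path))


def load_ply(path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def save_vtk(path, mesh: SurfaceMesh, point_data: dict = None):
    """Legacy VTK ASCII polydata with optional per-vertex arrays."""
    v, f = mesh.vertices, mesh.faces
    lines = [
        "# vtk DataFile Version 3.0",
        "aortatlas surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} float",
    ]
    lines += [" ".join(f"{x:.6f}" for x in p) for p in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in f]
    if point_data:
        lines.append(f"POINT_DATA {len(v)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} float 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{x:.6f}" for x in arr]
            else:
                lines.append(f"VECTORS {name} float")
                lines += [" ".join(f"{x:.6f}" for x in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def load_vtk(path):
    """Read back polydata written by :func:`save_vtk`."""
    tokens = Path(path).read_text().split("\n")
    i = 0
    verts = faces = None
    point_data = {}
    n_pts = 0
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("POINTS"):
            n_pts = int(line.split()[1])
            verts = np.array(
                [list(map(float, tokens[i + 1 + k].split())) for k in range(n_pts)]
            )
            i += n_pts
        elif line.startswith("POLYGONS"):
            n_f = int(line.split()[1])
            faces = np.array(
                [list(map(int, tokens[i + 1 + k].split()))[1:] for k in range(n_f)]
            )
            i += n_f
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            vals = [float(tokens[i + 2 + k]) for k in range(n_pts)]
            point_data[name] = np.array(vals)
            i += n_pts + 1
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            vals = [list(map(float, tokens[i + 1 + k].split())) for k in range(n_pts)]
            point_data[name] = np.array(vals)
            i += n_pts
        i += 1
    mesh = SurfaceMesh(verts, faces)
    return mesh, point_data


# --------------------------------------------------------------------------
# centerlines, tables, reports
# --------------------------------------------------------------------------

def save_centerline(path, cl: Centerline):
    df = pd.DataFrame(cl.points, columns=["x", "y", "z"])
    df["arclength"] = cl.arclength
    df["side"] = cl.side if cl.side is not None else "unknown"
    df.to_csv(path, index=False)
    if cl.stations:
        Path(str(path) + ".stations.json").write_text(json.dumps(cl.stations, indent=1))


def load_centerline(path) -> Centerline:
    df = pd.read_csv(path)
    stations = {}
    sp = Path(str(path) + ".stations.json")
    if sp.exists():
        stations = json.loads(sp.read_text())
    return Centerline(df[["x", "y", "z"]].to_numpy(), df["arclength"].to_numpy(), stations)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def save_json(path, data: dict):
    Path(path).write_text(json.dumps(_to_jsonable(data), indent=1))


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


# --------------------------------------------------------------------------
# subject directory layout
# --------------------------------------------------------------------------

def save_subject(directory, subject):
    """Write a SubjectImageSet to a directory (4D NIfTI masks, three 4D
    velocity components, JSON landmarks and ground truth)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    masks = np.moveaxis(subject.phase_masks, 0, -1)  # (x, y, z, t)
    save_nifti(d / "phase_masks.nii.gz", masks.astype(np.uint8), subject.spacing, subject.origin)
    save_nifti(d / "lumen_mask.nii.gz", subject.lumen_mask.astype(np.uint8), subject.spacing, subject.origin)
    for k, name in enumerate("xyz"):
        comp = np.moveaxis(subject.velocity[:, k], 0, -1).astype(np.float32)
        save_nifti(d / f"velocity_{name}.nii.gz", comp, subject.spacing, subject.origin)
    save_json(
        d / "meta.json",
        {
            "phase_times_ms": subject.phase_times,
            "landmarks_mm": subject.landmarks,
            "inlet_point": subject.inlet_point,
            "outlet_point": subject.outlet_point,
            "ed_index": subject.ed_index,
            "group": subject.group,
            "subject_id": subject.subject_id,
            "viscosity_pa_s": subject.viscosity,
            "ground_truth": subject.ground_truth,
        },
    )


def load_subject(directory):
    from .synthetic import SubjectImageSet

    d = Path(directory)
    masks, spacing, origin = load_nifti(d / "phase_masks.nii.gz")
    masks = np.moveaxis(masks, -1, 0)
    lumen, _, _ = load_nifti(d / "lumen_mask.nii.gz")
    comps = []
    for name in "xyz":
        c, _, _ = load_nifti(d / f"velocity_{name}.nii.gz")
        comps.append(np.moveaxis(c, -1, 0))
    velocity = np.stack(comps, axis=1).astype(np.float32)
    meta = load_json(d / "meta.json")
    return SubjectImageSet(
        phase_masks=np.asarray(masks, dtype=np.uint8),
        phase_times=np.asarray(meta["phase_times_ms"], dtype=float),
        lumen_mask=np.asarray(lumen, dtype=np.uint8),
        velocity=velocity,
        spacing=spacing,
        origin=np.asarray(origin, dtype=float),
        landmarks=meta["landmarks_mm"],
        inlet_point=np.asarray(meta["inlet_point"], dtype=float),
        outlet_point=np.asarray(meta["outlet_point"], dtype=float),
        ed_index=int(meta["ed_index"]),
        group=meta.get("group", "control"),
        subject_id=meta.get("subject_id", "subject"),
        viscosity=float(meta.get("viscosity_pa_s", 3.2e-3)),
        ground_truth=meta.get("ground_truth", {}),
    )
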