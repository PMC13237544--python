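"""End-to-end subject and cohort processing.

``run_subject`` turns one subject's masks and velocity field into
surfaces, a centerline, displacement and WSS maps, a PWV estimate and
regional values.  ``run_cohort`` builds the control atlases, classifies
patients against them, aggregates incidence maps and produces the
group-statistics tables.  Every default the underlying study protocol
left open is recorded in the run's decisions log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import atlas as atlas_mod
from . import displacement as disp_mod
from . import pwv as pwv_mod
from . import quantify
from . import stats_report
from . import wss as wss_mod
from .core import EXCLUDED, ROI_NAMES, SurfaceMesh, VertexField
from .geometry import extract_centerline, label_rois, mask_to_surface, measure_diameter


@dataclass
class RunConfig:
    viscosity: float = 3.2e-3  # Pa s
    ci_multiplier: float = 1.96
    direction_threshold_deg: float = 120.0
    pwv_method: str = "xcorr"
    pwv_planes: int = 8
    mesh_step: int = 1  # marching-cubes step (2 halves the mesh resolution)
    smoothing_iterations: int = 5
    area_weighted_peak: bool = False
    root_diameter_mode: str = "area"  # or 'cusp_to_cusp'
    roi_station_map: dict = field(default_factory=lambda: dict(quantify.ROI_STATION))
    seed: int = 0
    output_dir: str = None

    def validate(self):
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if self.pwv_method not in ("foot", "xcorr"):
            raise ValueError("pwv_method must be 'foot' or 'xcorr'")
        if not 0 < self.ci_multiplier:
            raise ValueError("ci_multiplier must be positive")
        if not 0 < self.direction_threshold_deg < 180:
            raise ValueError("direction threshold must lie in (0, 180) degrees")

    def decisions_log(self) -> dict:
        return {
            "viscosity_pa_s": self.viscosity,
            "sd_convention": "sample (n-1)",
            "ci_multiplier": self.ci_multiplier,
            "direction_threshold_deg": self.direction_threshold_deg,
            "pwv_method": self.pwv_method,
            "pwv_resample_ms": pwv_mod.RESAMPLE_DT_MS,
            "peak_frame_mean": "unweighted over vertices"
            if not self.area_weighted_peak
            else "area-weighted",
            "peak_tie_break": "earliest phase",
            "roi_station_map": self.roi_station_map,
            "rank_test": stats_report.METADATA["rank_test"],
            "incidence_transfer": "nearest mapped vertex (integral counts)",
            "template_distance": "symmetric mean nearest-neighbour surface distance",
        }


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    ed_mesh: SurfaceMesh = None
    lumen_mesh: SurfaceMesh = None
    centerline: object = None
    labels_ed: np.ndarray = None
    labels_lumen: np.ndarray = None
    peak_phase: int = None
    peak_map: object = None  # DisplacementMap
    per_phase_mean_displacement: np.ndarray = None
    wss_map: object = None  # WSSMap
    peak_systole: int = None
    pwv: object = None  # PWVResult
    regional: dict = field(default_factory=dict)
    diameters: dict = field(default_factory=dict)
    adjusted: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def report(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "group": self.group,
            "peak_displacement_phase": self.peak_phase,
            "peak_systole_phase": self.peak_systole,
            "regional": self.regional,
            "diameters_mm": self.diameters,
            "diameter_adjusted": self.adjusted,
            "pwv_m_s": None if self.pwv is None or not self.pwv.ok else self.pwv.pwv,
            "pwv_method": None if self.pwv is None else self.pwv.method,
            "errors": self.errors,
        }


def run_subject(subject, config: RunConfig = None) -> SubjectResult:
    """Geometry -> displacement -> WSS -> PWV -> regional quantification
    for one subject.  Stage failures are recorded and later stages that do
    not depend on them still run."""
    config = config or RunConfig()
    config.validate()
    res = SubjectResult(subject.subject_id, subject.group)
    mesh_kw = dict(
        step_size=config.mesh_step, smoothing_iterations=config.smoothing_iterations
    )

    # --- geometry ----------------------------------------------------------
    try:
        res.lumen_mesh = mask_to_surface(
            subject.lumen_mask, subject.spacing, subject.origin, **mesh_kw
        )
        res.centerline = extract_centerline(
            subject.lumen_mask,
            subject.spacing,
            subject.inlet_point,
            subject.outlet_point,
            origin=subject.origin,
            stations=subject.landmarks,
        )
        res.labels_lumen = label_rois(res.lumen_mesh, res.centerline)
    except Exception as e:  # noqa: BLE001 - cohort runs must continue
        res.errors.append(f"geometry: {e}")
        return res

    # --- displacement ------------------------------------------------------
    try:
        phase_meshes = [
            mask_to_surface(m, subject.spacing, subject.origin, **mesh_kw)
            for m in subject.phase_masks
        ]
        res.ed_mesh = phase_meshes[subject.ed_index]
        res.labels_ed = label_rois(res.ed_mesh, res.centerline)
        series = disp_mod.displacement_series(phase_meshes, subject.ed_index)
        res.per_phase_mean_displacement = disp_mod.mean_displacement_table(
            series, config.area_weighted_peak
        )
        res.peak_phase, res.peak_map = disp_mod.peak_displacement(series)
        res.regional["displacement_mm"] = quantify.roi_means(
            res.peak_map.values, res.labels_ed, res.ed_mesh.vertex_area
        )
    except Exception as e:  # noqa: BLE001
        res.errors.append(f"displacement: {e}")

    # --- hemodynamics ------------------------------------------------------
    if subject.velocity is not None:
        try:
            res.peak_systole = wss_mod.peak_systole_frame(
                subject.velocity, subject.lumen_mask
            )
            res.wss_map = wss_mod.wss_vectors(
                subject.velocity[res.peak_systole],
                res.lumen_mesh,
                res.centerline,
                viscosity=config.viscosity,
                spacing=subject.spacing,
                origin=subject.origin,
                lumen_mask=subject.lumen_mask,
                phase_index=res.peak_systole,
            )
            res.regional["wss_pa"] = quantify.roi_means(
                res.wss_map.magnitude,
                res.labels_lumen,
                res.lumen_mesh.vertex_area,
                flags=res.wss_map.flags,
            )
            res.regional["velocity_cm_s"] = _regional_velocity(
                subject, res.centerline, res.peak_systole
            )
        except Exception as e:  # noqa: BLE001
            res.errors.append(f"wss: {e}")
        try:
            wfs = pwv_mod.plane_flow_waveforms(
                subject.velocity,
                subject.lumen_mask,
                res.centerline,
                n_planes=config.pwv_planes,
                spacing=subject.spacing,
                origin=subject.origin,
                phase_times=subject.phase_times,
            )
            res.pwv = pwv_mod.estimate_pwv(wfs, config.pwv_method)
        except Exception as e:  # noqa: BLE001
            res.errors.append(f"pwv: {e}")
    else:
        res.errors.append("velocity missing: displacement-only report")

    # --- diameters ---------------------------------------------------------
    try:
        res.diameters = station_diameters(
            res.lumen_mesh, res.centerline, config.root_diameter_mode
        )
        res.adjusted = quantify.diameter_adjust(res.regional, res.diameters)
    except Exception as e:  # noqa: BLE001
        res.errors.append(f"diameter: {e}")
    return res


def station_diameters(mesh, cl, root_mode: str = "area") -> dict:
    """Diameters at the four measurement stations (mid-band arclengths)."""
    st = cl.stations
    from .geometry import descending_pa_level_from_centerline

    pa_desc = descending_pa_level_from_centerline(cl)
    mids = {
        "root": 0.5 * (st["annulus"] + st["PA_bifurcation"]),
        "ascending": 0.5 * (st["PA_bifurcation"] + st["brachiocephalic"]),
        "proximal_descending": 0.5 * (st["left_subclavian"] + pa_desc),
        "diaphragm": 0.5 * (pa_desc + st["diaphragm"]),
    }
    out = {}
    for name, s0 in mids.items():
        mode = root_mode if name == "root" else "area"
        try:
            out[name] = measure_diameter(mesh, cl, s0, mode=mode)
        except ValueError:
            out[name] = np.nan
    return out


def _regional_velocity(subject, cl, frame: int) -> dict:
    """Mean intraluminal velocity magnitude (cm/s) per ROI at one phase."""
    lum = np.asarray(subject.lumen_mask) > 0
    idxs = np.argwhere(lum)
    pts = subject.origin + idxs * subject.spacing
    _, s_vox, _ = cl.nearest(pts)
    v = subject.velocity[frame][:, lum].astype(np.float64)
    mag = np.sqrt((v**2).sum(axis=0))
    st = cl.stations
    from .geometry import descending_pa_level_from_centerline

    pa_desc = descending_pa_level_from_centerline(cl)
    bands = {
        "pAAo": (st["annulus"], st["PA_bifurcation"]),
        "dAAo": (st["PA_bifurcation"], st["brachiocephalic"]),
        "pDAo": (st["left_subclavian"], pa_desc),
        "dDAo": (pa_desc, st["diaphragm"]),
    }
    out = {}
    for roi, (a, b) in bands.items():
        m = (s_vox >= a) & (s_vox < b)
        out[roi] = float(mag[m].mean()) if m.any() else np.nan
    return out


# --------------------------------------------------------------------------
# cohort level
# --------------------------------------------------------------------------

@dataclass
class CohortResult:
    subject_results: list
    displacement_atlas: object = None
    wss_atlas: object = None
    wss_vector_atlas: object = None
    heatmaps: dict = field(default_factory=dict)  # subject_id -> {kind: Heatmap}
    abnormal_areas: pd.DataFrame = None
    incidence_maps: dict = field(default_factory=dict)
    regional_table: pd.DataFrame = None
    group_comparisons: pd.DataFrame = None
    rank_tests: pd.DataFrame = None
    correlations: pd.DataFrame = None
    logistic: dict = field(default_factory=dict)
    incidence_table: pd.DataFrame = None
    audit: dict = field(default_factory=dict)
    decisions_log: dict = field(default_factory=dict)
    notices: list = field(default_factory=list)


def run_cohort(subjects, config: RunConfig = None) -> CohortResult:
    """Process a cohort end to end: per-subject pipelines, control
    atlases, patient heatmaps, incidence maps and group statistics."""
    config = config or RunConfig()
    config.validate()
    results = [run_subject(s, config) for s in subjects]
    out = CohortResult(results, decisions_log=config.decisions_log())

    ok = [r for r in results if r.peak_map is not None]
    controls = [r for r in ok if r.group == "control"]
    patients = [r for r in ok if r.group != "control"]

    out.regional_table = regional_table(results)
    out.group_comparisons = group_comparison_table(out.regional_table)

    if len(controls) < 2:
        out.notices.append("fewer than 2 controls: atlas stages skipped")
        return out

    # --- displacement atlas and heatmaps -----------------------------------
    ctrl_meshes = [r.ed_mesh for r in controls]
    ctrl_maps = [r.peak_map.values for r in controls]
    out.displacement_atlas = atlas_mod.build_scalar_atlas(ctrl_meshes, ctrl_maps)
    out.audit["displacement"] = displacement_audit(controls, out.displacement_atlas)

    have_wss = [r for r in controls if r.wss_map is not None]
    if len(have_wss) >= 2:
        out.wss_atlas = atlas_mod.build_scalar_atlas(
            [r.lumen_mesh for r in have_wss], [r.wss_map.magnitude for r in have_wss]
        )
        out.wss_vector_atlas = atlas_mod.build_vector_atlas(
            [r.lumen_mesh for r in have_wss], [r.wss_map.vectors for r in have_wss]
        )

    rows = []
    for r in patients:
        hm = {}
        try:
            proj = atlas_mod.project_atlas(out.displacement_atlas, r.ed_mesh)
            hm["displacement"] = atlas_mod.classify_scalar(
                r.peak_map.values, proj, r.ed_mesh
            )
        except Exception as e:  # noqa: BLE001
            r.errors.append(f"heatmap displacement: {e}")
        if out.wss_atlas is not None and r.wss_map is not None:
            try:
                proj = atlas_mod.project_atlas(out.wss_atlas, r.lumen_mesh)
                hm["wss"] = atlas_mod.classify_scalar(r.wss_map.magnitude, proj, r.lumen_mesh)
                projv = atlas_mod.project_atlas(out.wss_vector_atlas, r.lumen_mesh)
                hm["wss_direction"] = atlas_mod.classify_direction(
                    r.wss_map.vectors, projv, r.lumen_mesh, config.direction_threshold_deg
                )
            except Exception as e:  # noqa: BLE001
                r.errors.append(f"heatmap wss: {e}")
        out.heatmaps[r.subject_id] = hm
        for kind, labels, mesh in (
            ("displacement", r.labels_ed, r.ed_mesh),
            ("wss", r.labels_lumen, r.lumen_mesh),
            ("wss_direction", r.labels_lumen, r.lumen_mesh),
        ):
            if kind not in hm:
                continue
            summ = quantify.abnormal_area_percent(hm[kind], labels, mesh.vertex_area)
            for roi in ROI_NAMES:
                for cls, pct in summ.percent[roi].items():
                    rows.append(
                        {
                            "subject_id": r.subject_id,
                            "group": r.group,
                            "parameter": kind,
                            "roi": roi,
                            "class": cls,
                            "area_percent": pct,
                            "any_abnormal": summ.any_abnormal[roi][cls],
                        }
                    )
    out.abnormal_areas = pd.DataFrame(rows)

    # --- incidence maps -----------------------------------------------------
    if patients:
        for kind, mesh_attr, labels in (
            ("displacement", "ed_mesh", (atlas_mod.INCREASED, atlas_mod.DECREASED)),
            ("wss", "lumen_mesh", (atlas_mod.INCREASED, atlas_mod.DECREASED)),
            ("wss_direction", "lumen_mesh", (atlas_mod.ABNORMAL_DIRECTION,)),
        ):
            with_map = [r for r in patients if kind in out.heatmaps.get(r.subject_id, {})]
            if not with_map:
                continue
            meshes = [getattr(r, mesh_attr) for r in with_map]
            hms = [out.heatmaps[r.subject_id][kind] for r in with_map]
            try:
                tmpl = (
                    atlas_mod.select_template(meshes) if len(meshes) > 1 else 0
                )
                for cls in labels:
                    out.incidence_maps[f"{kind}_{cls}"] = atlas_mod.build_incidence_map(
                        hms, meshes, template_index=tmpl, label=cls
                    )
            except Exception as e:  # noqa: BLE001
                out.notices.append(f"incidence {kind}: {e}")

    # --- statistics ---------------------------------------------------------
    if not out.abnormal_areas.empty:
        out.rank_tests = rank_test_table(out.abnormal_areas)
        out.incidence_table = incidence_summary(out.abnormal_areas)
    out.correlations = correlation_table(results)
    out.logistic = logistic_summary(out, patients)
    return out


def displacement_audit(controls, atl) -> dict:
    """Pre- vs post-registration ROI-combined mean displacement of the
    controls used to build the atlas."""
    from .geometry import interpolate_to_mesh, register_nonrigid

    tmpl = atl.template
    tmpl_ctrl = next(r for r in controls if r.ed_mesh is tmpl)
    labels_t = tmpl_ctrl.labels_ed
    usable_t = labels_t != EXCLUDED
    w_t = tmpl.vertex_area[usable_t]
    pre, post = [], []
    for r in controls:
        usable = r.labels_ed != EXCLUDED
        w = r.ed_mesh.vertex_area[usable]
        pre.append(float((r.peak_map.values[usable] * w).sum() / w.sum()))
        if r.ed_mesh is tmpl:
            vals = r.peak_map.values
        else:
            d = register_nonrigid(r.ed_mesh, tmpl)
            vals = interpolate_to_mesh(
                VertexField(r.peak_map.values, r.ed_mesh), d, tmpl
            ).values
        post.append(float((vals[usable_t] * w_t).sum() / w_t.sum()))
    audit = quantify.registration_audit(pre, post)
    return {
        "mean_difference_mm": audit.mean_difference,
        "ci_95": [audit.ci_lower, audit.ci_upper],
        "p_value": audit.p_value,
        "n": audit.n,
        "degenerate": audit.degenerate,
    }


def regional_table(results) -> pd.DataFrame:
    rows = []
    for r in results:
        base = {"subject_id": r.subject_id, "group": r.group}
        for param, per_roi in r.regional.items():
            for roi, v in per_roi.items():
                rows.append({**base, "parameter": param, "roi": roi, "value": v})
        if r.pwv is not None and r.pwv.ok:
            rows.append({**base, "parameter": "pwv_m_s", "roi": "global", "value": r.pwv.pwv})
        for roi, adj in r.adjusted.items():
            for k in ("displacement_adj", "velocity_adj", "wss_adj_mpa_mm"):
                if k in adj:
                    rows.append({**base, "parameter": k, "roi": roi, "value": adj[k]})
    return pd.DataFrame(rows)


def group_comparison_table(regional: pd.DataFrame) -> pd.DataFrame:
    rows = []
    if regional is None or regional.empty:
        return pd.DataFrame()
    for (param, roi), sub in regional.groupby(["parameter", "roi"]):
        groups = {
            g: v["value"].dropna().to_numpy() for g, v in sub.groupby("group")
        }
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        try:
            gc = stats_report.compare_groups(groups, parameter=param, roi=roi)
        except ValueError:
            continue
        row = {"parameter": param, "roi": roi, "anova_p": gc.anova_p,
               "omnibus_significant": gc.omnibus_significant,
               "degenerate": gc.degenerate}
        for g, (m, sd, n) in gc.groups.items():
            row[f"{g}_mean"] = m
            row[f"{g}_sd"] = sd
            row[f"{g}_n"] = n
        for k, v in gc.pairwise_p.items():
            row[f"tukey_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def rank_test_table(areas: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (param, roi, cls), sub in areas.groupby(["parameter", "roi", "class"]):
        nat = sub[sub.group == "native"]["area_percent"].dropna().to_numpy()
        ars = sub[sub.group == "ars"]["area_percent"].dropna().to_numpy()
        if len(nat) == 0 or len(ars) == 0:
            continue
        rt = stats_report.compare_abnormal_areas(nat, ars)
        rows.append(
            {
                "parameter": param,
                "roi": roi,
                "class": cls,
                "native": rt.formatted("native"),
                "ars": rt.formatted("ars"),
                "p_value": rt.p_value,
                "degenerate": rt.degenerate,
            }
        )
    return pd.DataFrame(rows)


def incidence_summary(areas: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (param, roi, cls, grp), sub in areas.groupby(
        ["parameter", "roi", "class", "group"]
    ):
        rows.append(
            {
                "parameter": param,
                "roi": roi,
                "class": cls,
                "group": grp,
                "incidence": stats_report.incidence_table(sub["any_abnormal"].to_numpy()),
            }
        )
    return pd.DataFrame(rows)


def correlation_table(results) -> pd.DataFrame:
    """Displacement vs same-ROI velocity / WSS and global PWV, per group."""
    rows = []
    groups = sorted({r.group for r in results})
    for g in groups:
        rs = [r for r in results if r.group == g]
        for roi in ROI_NAMES:
            disp = np.array(
                [r.regional.get("displacement_mm", {}).get(roi, np.nan) for r in rs]
            )
            for param in ("velocity_cm_s", "wss_pa"):
                other = np.array(
                    [r.regional.get(param, {}).get(roi, np.nan) for r in rs]
                )
                rows.append(_corr_row(g, roi, param, disp, other))
            pwvs = np.array(
                [r.pwv.pwv if (r.pwv is not None and r.pwv.ok) else np.nan for r in rs]
            )
            rows.append(_corr_row(g, roi, "pwv_m_s", disp, pwvs))
    return pd.DataFrame([r for r in rows if r is not None])


def _corr_row(group, roi, param, x, y):
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4 or x[ok].std() == 0 or y[ok].std() == 0:
        return None
    c = stats_report.correlate(x[ok], y[ok])
    return {
        "group": group,
        "roi": roi,
        "parameter": param,
        "r": c.r,
        "ci_lower": c.ci_lower,
        "ci_upper": c.ci_upper,
        "p_value": c.p_value,
        "n": c.n,
    }


def logistic_summary(out: CohortResult, patients) -> dict:
    """Determinants of abnormally increased pDAo displacement."""
    if out.abnormal_areas is None or out.abnormal_areas.empty:
        return {}
    sub = out.abnormal_areas.query(
        "parameter == 'displacement' and roi == 'pDAo' and `class` == 'increased'"
    )
    outcome = {row.subject_id: bool(row.any_abnormal) for row in sub.itertuples()}
    preds = {}
    for name, getter in (
        ("pwv_m_s", lambda r: r.pwv.pwv if (r.pwv is not None and r.pwv.ok) else np.nan),
        ("diameter_pDAo_mm", lambda r: r.diameters.get("proximal_descending", np.nan)),
    ):
        y, x = [], []
        for r in patients:
            if r.subject_id not in outcome:
                continue
            v = getter(r)
            if np.isfinite(v):
                y.append(float(outcome[r.subject_id]))
                x.append(v)
        if len(y) >= 8 and 0 < sum(y) < len(y):
            res = stats_report.logistic_univariable(y, x)
            preds[name] = {
                "odds_ratio": res.odds_ratio,
                "ci_95": [res.ci_lower, res.ci_upper],
                "p_value": res.p_value,
                "n": res.n,
                "separated": res.separated,
            }
    return preds
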