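"""Synthetic aortic cohort generator.

Builds "candy-cane" aortic phantoms — a straight ascending limb, a
half-torus arch and a straight descending limb — with cyclic wall motion
over the cardiac cycle, near-parabolic intraluminal velocity profiles,
an optional travelling-wave delay for pulse-wave-velocity analysis, and
localised wall-motion abnormalities injected at controlled prevalence.

Default regional wall excursions and peak velocities are the healthy
control means of the study population this pipeline targets (peak
displacement pAAo 9.8 / dAAo 4.5 / pDAo 1.5 / dDAo 1.8 mm; peak velocity
73.2 / 62.0 / 76.9 / 82.6 cm/s; pulse wave velocity 6.6 m/s), with the
Marfan (native) and post-root-surgery (ARS) groups expressed as
per-region multipliers on those values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .core import Centerline, ROI_NAMES, SurfaceMesh, vertex_areas

GROUPS = ("control", "native", "ars")

# Healthy-control regional means (study conditions).
CONTROL_DISPLACEMENT_MM = {"pAAo": 9.8, "dAAo": 4.5, "pDAo": 1.5, "dDAo": 1.8}
CONTROL_DISPLACEMENT_SD = {"pAAo": 1.2, "dAAo": 1.0, "pDAo": 0.4, "dDAo": 0.4}
CONTROL_VELOCITY_CM_S = {"pAAo": 73.2, "dAAo": 62.0, "pDAo": 76.9, "dDAo": 82.6}
CONTROL_VELOCITY_SD = {"pAAo": 9.5, "dAAo": 12.2, "pDAo": 9.2, "dDAo": 11.9}
PWV_MEAN_M_S = {"control": 6.6, "native": 9.0, "ars": 10.0}
PWV_SD_M_S = {"control": 1.4, "native": 3.5, "ars": 2.7}

# Group effects as multipliers on the control regional means.
GROUP_EFFECTS = {
    "displacement": {
        "control": {"pAAo": 1.0, "dAAo": 1.0, "pDAo": 1.0, "dDAo": 1.0},
        "native": {"pAAo": 9.0 / 9.8, "dAAo": 4.6 / 4.5, "pDAo": 1.4 / 1.5, "dDAo": 1.7 / 1.8},
        "ars": {"pAAo": 5.8 / 9.8, "dAAo": 4.3 / 4.5, "pDAo": 1.6 / 1.5, "dDAo": 1.3 / 1.8},
    },
    "velocity": {
        "control": {"pAAo": 1.0, "dAAo": 1.0, "pDAo": 1.0, "dDAo": 1.0},
        "native": {"pAAo": 65.1 / 73.2, "dAAo": 62.7 / 62.0, "pDAo": 69.6 / 76.9, "dDAo": 76.3 / 82.6},
        "ars": {"pAAo": 78.4 / 73.2, "dAAo": 69.0 / 62.0, "pDAo": 66.5 / 76.9, "dDAo": 74.2 / 82.6},
    },
}

DEFAULT_VISCOSITY_PA_S = 3.2e-3  # dynamic viscosity of blood used for WSS

# Lumen radius profile (arclength mm -> radius mm), control-like calibre:
# dilated root tapering towards the diaphragm.
DEFAULT_RADIUS_PROFILE = ((0.0, 16.0), (40.0, 15.0), (90.0, 14.0), (160.0, 12.5), (260.0, 11.5))


@dataclass(frozen=True)
class Abnormality:
    """A localized wall-motion abnormality injected into one ROI band."""

    region: str  # one of ROI_NAMES
    kind: str  # 'increase' | 'decrease'
    multiplier: float  # applied to the regional displacement amplitude

    def __post_init__(self):
        if self.region not in ROI_NAMES:
            raise ValueError(f"unknown region {self.region!r}")
        if self.kind not in ("increase", "decrease"):
            raise ValueError("kind must be 'increase' or 'decrease'")
        if self.kind == "increase" and self.multiplier <= 1.0:
            raise ValueError("an 'increase' abnormality needs multiplier > 1")
        if self.kind == "decrease" and not (0.0 <= self.multiplier < 1.0):
            raise ValueError("a 'decrease' abnormality needs multiplier in [0, 1)")


@dataclass
class SubjectSpec:
    group: str = "control"
    seed: int = 0
    subject_id: str = "subject"
    # geometry (mm)
    ascending_length: float = 50.0
    arch_radius: float = 30.0
    descending_length: float = 110.0
    radius_profile: Sequence = DEFAULT_RADIUS_PROFILE
    shape_perturbation: float = 0.8  # mm, low-frequency radial jitter
    # imaging
    n_phases: int = 30
    spacing: float = 1.0  # mm, isotropic
    rr_ms: float = 1000.0
    systole_fraction: float = 0.4
    # physiology
    displacement_amplitude: dict = field(
        default_factory=lambda: dict(CONTROL_DISPLACEMENT_MM)
    )
    velocity_peak: dict = field(default_factory=lambda: dict(CONTROL_VELOCITY_CM_S))
    wave_speed: Optional[float] = None  # m/s; None = synchronous pulse
    abnormalities: tuple = ()
    viscosity: float = DEFAULT_VISCOSITY_PA_S

    def validate(self):
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(a < 0 for a in self.displacement_amplitude.values()):
            raise ValueError("displacement amplitudes must be >= 0")
        radii = np.array([r for _, r in self.radius_profile])
        if np.any(radii <= 2 * self.spacing):
            raise ValueError("lumen radius must exceed 2 voxels everywhere")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class SubjectImageSet:
    """All voxel-grid inputs for one subject, plus generator ground truth."""

    phase_masks: np.ndarray  # (n_phases, nx, ny, nz) uint8
    phase_times: np.ndarray  # ms from the R-wave, strictly increasing
    lumen_mask: np.ndarray  # time-averaged, (nx, ny, nz) uint8
    velocity: np.ndarray  # (n_phases, 3, nx, ny, nz) cm/s, float32
    spacing: float  # mm, isotropic
    origin: np.ndarray  # world position of voxel (0,0,0), mm
    landmarks: dict  # station name -> arclength mm
    inlet_point: np.ndarray  # world mm, on the annulus
    outlet_point: np.ndarray  # world mm, at the diaphragm
    ed_index: int  # end-diastolic phase
    group: str = "control"
    subject_id: str = "subject"
    viscosity: float = DEFAULT_VISCOSITY_PA_S
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_phases(self) -> int:
        return len(self.phase_masks)


def pulse_waveform(t_ms, rr_ms: float = 1000.0, systole_fraction: float = 0.4):
    """Raised-cosine systolic bump over the first `systole_fraction` of the
    cycle, flat diastole; unit peak at 0.5 * systole_fraction * rr."""
    p = np.mod(np.asarray(t_ms, dtype=float) / rr_ms, 1.0)
    w = np.where(
        p < systole_fraction, 0.5 * (1 - np.cos(2 * np.pi * p / systole_fraction)), 0.0
    )
    return w


def candy_cane_centerline(
    ascending_length: float = 50.0,
    arch_radius: float = 30.0,
    descending_length: float = 110.0,
    step: float = 0.5,
) -> Centerline:
    """Candy-cane axis: ascending limb up +z, half-torus arch, descending limb.

    The annulus sits at (0, 0, -ascending_length); the descending limb runs
    down the line x = 2 * arch_radius.
    """
    if ascending_length <= 0 or descending_length <= 0 or arch_radius <= 0:
        raise ValueError("geometry lengths must be positive")
    la, R, ld = ascending_length, arch_radius, descending_length
    s_arch = np.pi * R
    total = la + s_arch + ld
    s = np.arange(0.0, total + step / 2, step)
    if total - s[-1] > 1e-9:  # always end exactly at the diaphragm
        s = np.append(s, total)
    pts = np.empty((len(s), 3))
    asc = s <= la
    pts[asc] = np.column_stack(
        [np.zeros(asc.sum()), np.zeros(asc.sum()), s[asc] - la]
    )
    arch = (s > la) & (s <= la + s_arch)
    th = (s[arch] - la) / R
    pts[arch] = np.column_stack(
        [R - R * np.cos(th), np.zeros(arch.sum()), R * np.sin(th)]
    )
    desc = s > la + s_arch
    pts[desc] = np.column_stack(
        [np.full(desc.sum(), 2 * R), np.zeros(desc.sum()), -(s[desc] - la - s_arch)]
    )
    stations = default_stations(la, R, ld)
    return Centerline(pts, s.copy(), stations)


def half_torus_centerline(arch_radius: float, step: float = 0.5) -> Centerline:
    """Pure semicircular arc of the given radius (test geometry)."""
    th = np.arange(0.0, np.pi + step / arch_radius / 2, step / arch_radius)
    pts = np.column_stack(
        [arch_radius - arch_radius * np.cos(th), np.zeros(len(th)), arch_radius * np.sin(th)]
    )
    return Centerline(pts)


def default_stations(ascending_length: float, arch_radius: float, descending_length: float) -> dict:
    """Landmark arclengths consistent with the candy-cane geometry.

    The PA bifurcation sits at 80% of the ascending limb; the descending
    boundary between pDAo and dDAo is the descending-limb arclength at the
    same axial (z) height, which for this geometry is analytic.
    """
    la, R, ld = ascending_length, arch_radius, descending_length
    s_arch = np.pi * R
    pa = 0.8 * la
    return {
        "annulus": 0.0,
        "PA_bifurcation": pa,
        "brachiocephalic": la + 0.10 * s_arch,
        "left_subclavian": la + 0.75 * s_arch,
        "diaphragm": la + s_arch + ld,
    }


def descending_pa_level(stations: dict, ascending_length: float, arch_radius: float) -> float:
    """Arclength on the descending limb at the axial height of the PA bifurcation."""
    la, R = ascending_length, arch_radius
    z_pa = stations["PA_bifurcation"] - la  # z on the ascending limb (<= 0)
    return la + np.pi * R + (-z_pa)


def region_bands(stations: dict, pa_level_descending: float) -> dict:
    """Arclength interval per ROI (arch excluded)."""
    return {
        "pAAo": (stations["annulus"], stations["PA_bifurcation"]),
        "dAAo": (stations["PA_bifurcation"], stations["brachiocephalic"]),
        "pDAo": (stations["left_subclavian"], pa_level_descending),
        "dDAo": (pa_level_descending, stations["diaphragm"]),
    }


def _regional_profile(s: np.ndarray, bands: dict, values: dict, smooth_mm: float = 6.0,
                      fill: float = None) -> np.ndarray:
    """Piecewise-constant per-region profile over arclength, smoothed so the
    wall stays geometrically coherent across ROI boundaries."""
    prof = np.full(len(s), np.nan)
    for roi, (a, b) in bands.items():
        prof[(s >= a) & (s < b)] = values[roi]
    # arch (and any uncovered span): interpolate between flanking regions
    if np.any(np.isnan(prof)):
        idx = np.where(~np.isnan(prof))[0]
        prof = np.interp(np.arange(len(s)), idx, prof[idx])
    if fill is not None:
        prof = np.where(np.isnan(prof), fill, prof)
    step = float(np.median(np.diff(s))) if len(s) > 1 else 1.0
    return gaussian_filter1d(prof, smooth_mm / step, mode="nearest")


def make_subject(spec: SubjectSpec) -> SubjectImageSet:
    """Voxelize one synthetic subject from its specification.

    Per phase t the wall radius is r(s, t) = r0(s) * (1 + a(s) * w(t)) with
    w the raised-cosine systolic pulse and a(s) the region-dependent
    fractional amplitude; the voxel velocity is
    tangent(s) * v_peak(s) * (1 - (rho / r_lum)^2) * w(t - s/c), a parabola
    vanishing at the time-averaged lumen radius r_lum(s) and zero outside
    the time-averaged lumen mask (the surface on which wall shear stress
    is evaluated).  Ground truth records the per-region analytic wall
    shear stress 2 * mu * v_max / r_lum at peak systole.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    cl = candy_cane_centerline(
        spec.ascending_length, spec.arch_radius, spec.descending_length
    )
    s = cl.arclength
    stations = dict(cl.stations)
    pa_desc = descending_pa_level(stations, spec.ascending_length, spec.arch_radius)
    bands = region_bands(stations, pa_desc)

    prof = np.asarray(spec.radius_profile, dtype=float)
    r0 = np.interp(s, prof[:, 0], prof[:, 1])
    # smooth low-frequency shape variability
    if spec.shape_perturbation > 0:
        for k in (1, 2, 3):
            amp = rng.normal(0.0, spec.shape_perturbation / np.sqrt(3))
            phase = rng.uniform(0, 2 * np.pi)
            r0 = r0 + amp * np.cos(2 * np.pi * k * s / s[-1] + phase)
    if np.any(r0 <= 2 * spec.spacing):
        raise ValueError("degenerate geometry: lumen radius below 2 voxels")
    if 2 * spec.arch_radius <= 2 * r0.max():
        raise ValueError("geometry error: ascending and descending limbs overlap")

    amp_values = dict(spec.displacement_amplitude)
    for ab in spec.abnormalities:
        amp_values[ab.region] = amp_values[ab.region] * ab.multiplier
    amp = _regional_profile(s, bands, amp_values)  # mm radial excursion
    vpk = _regional_profile(s, bands, dict(spec.velocity_peak))  # cm/s
    a_frac = amp / r0

    # --- voxel grid -------------------------------------------------------
    pad = 3.0 * spec.spacing
    r_env = r0 * (1 + a_frac)  # maximum radius over the cycle
    lo = (cl.points - (r_env.max() + pad)).min(axis=0)
    hi = (cl.points + (r_env.max() + pad)).max(axis=0)
    origin = np.floor(lo / spec.spacing) * spec.spacing
    shape = tuple(np.ceil((hi - origin) / spec.spacing).astype(int) + 1)

    idx = np.indices(shape, dtype=np.float32).reshape(3, -1).T
    coords = origin[None, :] + idx * spec.spacing
    tree = cKDTree(cl.points)
    rho, near = tree.query(coords, workers=-1)
    s_vox = s[near]
    cand = rho <= r_env[near] + spec.spacing
    cand_idx = np.where(cand)[0]
    rho_c = rho[cand_idx]
    near_c = near[cand_idx]
    s_c = s_vox[cand_idx]

    phase_times = np.arange(spec.n_phases) * spec.rr_ms / spec.n_phases
    w_t = pulse_waveform(phase_times, spec.rr_ms, spec.systole_fraction)
    ed_index = int(np.argmin(w_t))  # ties -> earliest; phase 0 by construction

    masks = np.zeros((spec.n_phases,) + shape, dtype=np.uint8)
    flat = masks.reshape(spec.n_phases, -1)
    r0_c = r0[near_c]
    a_c = a_frac[near_c]
    for t in range(spec.n_phases):
        r_t = r0_c * (1 + a_c * w_t[t])
        flat[t, cand_idx[rho_c <= r_t]] = 1

    # time-averaged lumen: the static surface on which hemodynamics live
    w_mean = float(w_t.mean())
    r_lum = r0 * (1 + a_frac * w_mean)
    r_lum_c = r_lum[near_c]
    lumen = np.zeros(int(np.prod(shape)), dtype=np.uint8)
    lumen[cand_idx[rho_c <= r_lum_c]] = 1

    tangents = cl.tangents()
    tan_c = tangents[near_c]
    velocity = np.zeros((spec.n_phases, 3) + shape, dtype=np.float32)
    vel_flat = velocity.reshape(spec.n_phases, 3, -1)
    delay_ms = s_c / spec.wave_speed if spec.wave_speed else 0.0
    vpk_c = vpk[near_c]
    parab = np.maximum(0.0, 1.0 - (rho_c / r_lum_c) ** 2)
    for t in range(spec.n_phases):
        w_del = pulse_waveform(phase_times[t] - delay_ms, spec.rr_ms, spec.systole_fraction)
        vmag = vpk_c * parab * w_del
        sel = vmag != 0
        cols = cand_idx[sel]
        vel_flat[t, :, cols] = (tan_c[sel] * vmag[sel, None]).astype(np.float32)

    # --- ground truth -----------------------------------------------------
    peak_phase = int(np.argmax(w_t))
    w_peak = float(w_t[peak_phase])
    gt_disp, gt_vel, gt_wss = {}, {}, {}
    for roi, (a, b) in bands.items():
        m = (s >= a) & (s < b)
        gt_disp[roi] = float(np.mean(amp[m]))
        gt_vel[roi] = float(np.mean(vpk[m]) * w_peak)
        v_max_m_s = vpk[m] * w_peak / 100.0
        gt_wss[roi] = float(np.mean(2 * spec.viscosity * v_max_m_s / (r_lum[m] / 1000.0)))

    return SubjectImageSet(
        phase_masks=masks,
        phase_times=phase_times,
        lumen_mask=lumen.reshape(shape),
        velocity=velocity,
        spacing=spec.spacing,
        origin=origin,
        landmarks=stations,
        inlet_point=cl.points[0].copy(),
        outlet_point=cl.points[-1].copy(),
        ed_index=ed_index,
        group=spec.group,
        subject_id=spec.subject_id,
        viscosity=spec.viscosity,
        ground_truth={
            "displacement_mm": gt_disp,
            "velocity_cm_s": gt_vel,
            "wss_pa": gt_wss,
            "wave_speed_m_s": spec.wave_speed,
            "ed_index": ed_index,
            "peak_phase_index": peak_phase,
            "pa_level_descending_mm": pa_desc,
            "abnormal_regions": [ab.region for ab in spec.abnormalities],
        },
    )


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------

def sample_subject_specs(
    n_per_group,
    group_effects: dict = None,
    prevalence: float = 0.0,
    abnormality: Abnormality = None,
    seed: int = 0,
    **overrides,
):
    """Draw per-subject specifications with between-subject variability.

    Regional amplitudes and velocities are drawn from normal distributions
    whose means are the control values scaled by the group-effect
    multipliers and whose SDs are the control between-subject SDs scaled
    the same way.  Abnormalities are assigned to patient (non-control)
    subjects by Bernoulli(prevalence) and recorded in the manifest.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    effects = group_effects or GROUP_EFFECTS
    if isinstance(n_per_group, dict):
        counts = {g: int(n_per_group.get(g, 0)) for g in GROUPS}
    elif np.isscalar(n_per_group):
        counts = {g: int(n_per_group) for g in GROUPS}
    else:
        counts = dict(zip(GROUPS, n_per_group))
    rng = np.random.default_rng(seed)
    specs, rows = [], []
    for group in GROUPS:
        for i in range(counts.get(group, 0)):
            disp = {}
            vel = {}
            for roi in ROI_NAMES:
                e_d = effects["displacement"][group][roi]
                e_v = effects["velocity"][group][roi]
                mu_d = CONTROL_DISPLACEMENT_MM[roi] * e_d
                mu_v = CONTROL_VELOCITY_CM_S[roi] * e_v
                disp[roi] = max(
                    0.2 * mu_d, rng.normal(mu_d, CONTROL_DISPLACEMENT_SD[roi] * e_d)
                )
                vel[roi] = max(
                    0.2 * mu_v, rng.normal(mu_v, CONTROL_VELOCITY_SD[roi] * e_v)
                )
            wave = max(1.0, rng.normal(PWV_MEAN_M_S[group], PWV_SD_M_S[group]))
            abnormal = False
            abnormalities = ()
            if abnormality is not None and group != "control":
                abnormal = bool(rng.random() < prevalence)
                if abnormal:
                    abnormalities = (abnormality,)
            sid = f"{group}_{i:03d}"
            spec = SubjectSpec(
                group=group,
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=sid,
                displacement_amplitude=disp,
                velocity_peak=vel,
                wave_speed=wave,
                abnormalities=abnormalities,
                **overrides,
            )
            specs.append(spec)
            row = {"subject_id": sid, "group": group, "abnormal": abnormal,
                   "seed": spec.seed, "wave_speed_m_s": wave}
            for roi in ROI_NAMES:
                row[f"true_displacement_{roi}_mm"] = disp[roi] * (
                    abnormality.multiplier
                    if abnormal and abnormality.region == roi
                    else 1.0
                )
                row[f"true_velocity_{roi}_cm_s"] = vel[roi]
            rows.append(row)
    manifest = pd.DataFrame(rows)
    return specs, manifest


def make_cohort(
    n_per_group,
    group_effects: dict = None,
    prevalence: float = 0.0,
    abnormality: Abnormality = None,
    seed: int = 0,
    **overrides,
):
    """Generate a full synthetic cohort (image sets + manifest).

    Fully reproducible for a given seed.  Any group used downstream for
    atlas construction needs n >= 2.
    """
    specs, manifest = sample_subject_specs(
        n_per_group, group_effects, prevalence, abnormality, seed, **overrides
    )
    subjects = [make_subject(sp) for sp in specs]
    return subjects, manifest


# --------------------------------------------------------------------------
# analytic fixtures for straight-tube validation
# --------------------------------------------------------------------------

def cylinder_mesh(
    radius: float = 10.0,
    length: float = 100.0,
    n_theta: int = 96,
    dz: float = 1.0,
    center=(0.0, 0.0, 0.0),
) -> SurfaceMesh:
    """Open cylinder along +z with vertices exactly on the wall and exact
    outward radial normals; used as an analytic wall fixture."""
    n_z = max(2, int(round(length / dz)) + 1)
    z = np.linspace(-length / 2, length / 2, n_z)
    th = np.arange(n_theta) * 2 * np.pi / n_theta
    zz, tt = np.meshgrid(z, th, indexing="ij")
    verts = np.column_stack(
        [radius * np.cos(tt).ravel(), radius * np.sin(tt).ravel(), zz.ravel()]
    ) + np.asarray(center, dtype=float)
    faces = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, b, d))
            faces.append((a, d, c))
    faces = np.asarray(faces, dtype=np.int64)
    normals = np.column_stack(
        [np.cos(tt).ravel(), np.sin(tt).ravel(), np.zeros(n_z * n_theta)]
    )
    return SurfaceMesh(verts, faces, normals, vertex_areas(verts, faces))


def straight_tube_subject(
    radius: float = 10.0,
    length: float = 200.0,
    v_max: float = 100.0,
    spacing: float = 1.0,
    n_phases: int = 30,
    rr_ms: float = 1000.0,
    wave_speed: Optional[float] = None,
    steady: bool = False,
    profile: str = "parabolic",
    viscosity: float = DEFAULT_VISCOSITY_PA_S,
) -> SubjectImageSet:
    """Straight rigid tube along +z with Poiseuille (or plug) flow.

    With ``steady=True`` the velocity is time-constant at its peak value
    (w = 1 at every phase); otherwise the raised-cosine pulse applies,
    delayed by s / wave_speed when a wave speed is given.
    """
    pad = 3.0 * spacing
    n_side = int(np.ceil((radius + pad) / spacing))
    xy = (np.arange(-n_side, n_side + 1)) * spacing
    nz = int(np.ceil(length / spacing)) + 1
    z = np.arange(nz) * spacing
    origin = np.array([xy[0], xy[0], 0.0])
    X, Y = np.meshgrid(xy, xy, indexing="ij")
    rho2 = X**2 + Y**2
    mask2d = rho2 <= radius**2
    shape = (len(xy), len(xy), nz)
    lumen = np.repeat(mask2d[:, :, None], nz, axis=2).astype(np.uint8)
    masks = np.repeat(lumen[None], n_phases, axis=0)

    phase_times = np.arange(n_phases) * rr_ms / n_phases
    if profile == "parabolic":
        shape2d = np.where(mask2d, 1.0 - rho2 / radius**2, 0.0)
    elif profile == "plug":
        shape2d = mask2d.astype(float)
    else:
        raise ValueError("profile must be 'parabolic' or 'plug'")

    velocity = np.zeros((n_phases, 3) + shape, dtype=np.float32)
    for t in range(n_phases):
        if steady:
            w = np.ones(nz)
        else:
            delay = z / wave_speed if wave_speed else np.zeros_like(z)
            w = pulse_waveform(phase_times[t] - delay, rr_ms)
        velocity[t, 2] = (shape2d[:, :, None] * w[None, None, :] * v_max).astype(
            np.float32
        )

    w_t = np.ones(n_phases) if steady else pulse_waveform(phase_times, rr_ms)
    peak_phase = int(np.argmax(w_t))
    wss = 2 * viscosity * (v_max * float(w_t[peak_phase]) / 100.0) / (radius / 1000.0)
    stations = {
        "annulus": 0.0,
        "PA_bifurcation": 0.25 * length,
        "brachiocephalic": 0.4 * length,
        "left_subclavian": 0.5 * length,
        "diaphragm": length,
    }
    return SubjectImageSet(
        phase_masks=masks,
        phase_times=phase_times,
        lumen_mask=lumen,
        velocity=velocity,
        spacing=spacing,
        origin=origin,
        landmarks=stations,
        inlet_point=np.array([0.0, 0.0, 0.0]),
        outlet_point=np.array([0.0, 0.0, length]),
        ed_index=0,
        subject_id="tube",
        viscosity=viscosity,
        ground_truth={
            "wss_pa": wss,
            "v_max_cm_s": v_max,
            "radius_mm": radius,
            "wave_speed_m_s": wave_speed,
            "peak_phase_index": peak_phase,
            "ed_index": 0,
        },
    )
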