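"""Regional quantification: ROI averages, abnormal-surface-area
percentages, diameter-adjusted parameters and the registration audit.

Area percentages are area-weighted ("% of total area"), not vertex
counts, so they are stable under mesh refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import ROI_NAMES

# ROI -> diameter-station pairing used for diameter adjustment
ROI_STATION = {
    "pAAo": "root",
    "dAAo": "ascending",
    "pDAo": "proximal_descending",
    "dDAo": "diaphragm",
}


def roi_means(values: np.ndarray, labels: np.ndarray, areas: np.ndarray,
              flags: np.ndarray = None) -> dict:
    """Area-weighted mean per ROI over unflagged vertices.

    An ROI with no usable vertices yields NaN (missing), never zero.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    areas = np.asarray(areas, dtype=float)
    if not (len(values) == len(labels) == len(areas)):
        raise ValueError("values, labels and areas must share the mesh")
    usable = np.ones(len(values), dtype=bool) if flags is None else ~np.asarray(flags)
    out = {}
    for roi in ROI_NAMES:
        m = (labels == roi) & usable
        if not m.any():
            if (labels == roi).any():
                warnings.warn(f"all vertices flagged in {roi}; mean reported missing")
            out[roi] = np.nan
            continue
        out[roi] = float((values[m] * areas[m]).sum() / areas[m].sum())
    return out


@dataclass
class AbnormalAreaSummary:
    """Per-ROI, per-class abnormal surface area as % of the ROI area."""

    percent: dict  # {roi: {class_label: percent}}
    any_abnormal: dict  # {roi: {class_label: bool}}
    classes: tuple


def abnormal_area_percent(heatmap, labels: np.ndarray, areas: np.ndarray,
                          classes=None) -> AbnormalAreaSummary:
    """100 * abnormal area / ROI area per class, excluding flagged vertices
    from both numerator and denominator."""
    hm_labels = heatmap.labels
    if classes is None:
        classes = ("increased", "decreased") if heatmap.kind == "scalar" else ("abnormal_direction",)
    areas = np.asarray(areas, dtype=float)
    usable = ~heatmap.flags
    percent, any_ab = {}, {}
    for roi in ROI_NAMES:
        m = (np.asarray(labels) == roi) & usable
        tot = areas[m].sum()
        percent[roi] = {}
        any_ab[roi] = {}
        for cls in classes:
            if tot <= 0:
                percent[roi][cls] = np.nan
                any_ab[roi][cls] = False
                continue
            a = areas[m & (hm_labels == cls)].sum()
            percent[roi][cls] = float(100.0 * a / tot)
            any_ab[roi][cls] = bool(a > 0)
    return AbnormalAreaSummary(percent, any_ab, tuple(classes))


def diameter_adjust(regional: dict, diameters: dict) -> dict:
    """Diameter-adjusted regional parameters.

    displacement -> displacement / diameter * 100 (mm*100/mm)
    velocity     -> velocity / diameter (cm/s/mm)
    wss          -> wss * 1000 / diameter (mPa/mm)
    A zero or missing diameter yields a missing adjusted value.
    """
    out = {}
    for roi in ROI_NAMES:
        st = ROI_STATION[roi]
        dia = diameters.get(st, np.nan)
        good = np.isfinite(dia) and dia > 0
        disp = regional.get("displacement_mm", {}).get(roi, np.nan)
        vel = regional.get("velocity_cm_s", {}).get(roi, np.nan)
        w = regional.get("wss_pa", {}).get(roi, np.nan)
        out[roi] = {
            "displacement_adj": disp / dia * 100.0 if good else np.nan,
            "velocity_adj": vel / dia if good else np.nan,
            "wss_adj_mpa_mm": w * 1000.0 / dia if good else np.nan,
            "diameter_mm": dia if good else np.nan,
        }
    return out


@dataclass
class AuditResult:
    mean_difference: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    degenerate: bool = False  # zero variance of the paired differences


def registration_audit(pre_values, post_values) -> AuditResult:
    """Paired comparison of subject values before and after projection to
    the template: mean difference (post - pre) with t-based 95% CI."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post values must be paired")
    d = post - pre
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 paired values")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return AuditResult(mean, mean, mean, 1.0 if mean == 0 else 0.0, n, degenerate=True)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    tstat = mean / se
    p = 2 * stats.t.sf(abs(tstat), n - 1)
    return AuditResult(mean, mean - tcrit * se, mean + tcrit * se, float(p), n)
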