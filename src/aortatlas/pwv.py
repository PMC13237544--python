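"""Global aortic pulse wave velocity from plane-wise flow waveforms.

Flow waveforms are extracted on planes perpendicular to the centerline,
resampled to a fixed 20 ms temporal resolution, and the transit time of
the systolic wave along the aorta is estimated either from the
systolic-upstroke foot or from the cross-correlation lag against the
most proximal plane (with parabolic sub-sample refinement, since 20 ms
sampling is coarse relative to aortic transit times).  PWV is the
inverse slope of the arrival-time-versus-arclength regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import map_coordinates

from .core import Centerline

RESAMPLE_DT_MS = 20.0


@dataclass
class FlowWaveformSet:
    arclengths: np.ndarray  # (p,) mm
    waveforms: np.ndarray  # (p, t) mL/s at fixed dt
    dt: float = RESAMPLE_DT_MS  # ms


@dataclass
class PWVResult:
    pwv: float  # m/s (nan when flagged)
    arrival_times: np.ndarray  # ms per plane
    arclengths: np.ndarray  # mm per plane
    method: str = "xcorr"
    ok: bool = True
    message: str = ""


def plane_flow_waveforms(
    velocity: np.ndarray,
    lumen_mask: np.ndarray,
    cl: Centerline,
    n_planes: int = 8,
    spacing: float = 1.0,
    origin=(0.0, 0.0, 0.0),
    phase_times: np.ndarray = None,
    rr_ms: float = None,
    margin_mm: float = 5.0,
    sample_step: float = None,
    dt: float = RESAMPLE_DT_MS,
) -> FlowWaveformSet:
    """Flow-rate waveforms (mL/s) on equally spaced perpendicular planes,
    linearly resampled to the fixed temporal resolution."""
    if n_planes < 3:
        raise ValueError("need at least 3 planes")
    origin = np.asarray(origin, dtype=float)
    lum = np.asarray(lumen_mask)
    phase_times = np.asarray(phase_times, dtype=float)
    if rr_ms is None:
        rr_ms = float(phase_times[-1] + (phase_times[1] - phase_times[0]))
    step = sample_step or spacing
    s_planes = np.linspace(margin_mm, cl.length - margin_mm, n_planes)

    arclengths, waveforms = [], []
    extent = 30.0  # mm half-width of the in-plane sampling grid
    offs = np.arange(-extent, extent + step / 2, step)
    A, B = np.meshgrid(offs, offs, indexing="ij")
    keep0 = A**2 + B**2 <= extent**2
    ab = np.column_stack([A[keep0], B[keep0]])
    n_t = len(velocity)
    for s0 in s_planes:
        p0 = cl.point_at(s0)
        nrm = cl.tangent_at(s0)
        e1 = np.cross(nrm, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(nrm, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)
        pts = p0 + ab[:, :1] * e1 + ab[:, 1:] * e2
        ij = np.round((pts - origin) / spacing).astype(int)
        ok = np.all((ij >= 0) & (ij < np.array(lum.shape)), axis=1)
        inside = np.zeros(len(ij), dtype=bool)
        inside[ok] = lum[ij[ok, 0], ij[ok, 1], ij[ok, 2]] > 0
        if not inside.any():
            warnings.warn(f"plane at s={s0:.1f} mm has no lumen samples; dropped")
            continue
        pts_in = pts[inside]
        ic = ((pts_in - origin) / spacing).T
        flow = np.empty(n_t)
        for t in range(n_t):
            vn = sum(
                map_coordinates(velocity[t, k].astype(np.float64), ic, order=1, mode="nearest")
                * nrm[k]
                for k in range(3)
            )
            # cm/s * mm^2 -> mm^3/s needs *10; /1000 -> mL/s
            flow[t] = vn.sum() * step**2 * 10.0 / 1000.0
        arclengths.append(s0)
        waveforms.append(flow)
    if len(arclengths) < 3:
        raise ValueError("fewer than 3 usable planes")

    t_new = np.arange(0.0, rr_ms, dt)
    t_ext = np.concatenate([phase_times, [rr_ms]])
    resampled = []
    for w in waveforms:
        w_ext = np.concatenate([w, [w[0]]])  # cyclic
        resampled.append(np.interp(t_new, t_ext, w_ext))
    return FlowWaveformSet(np.asarray(arclengths), np.asarray(resampled), dt)


def _xcorr_lag(ref: np.ndarray, sig: np.ndarray, dt: float) -> float:
    """Circular cross-correlation lag of sig relative to ref (ms), with
    parabolic sub-sample refinement of the correlation peak."""
    a = ref - ref.mean()
    b = sig - sig.mean()
    n = len(a)
    cc = np.fft.irfft(np.fft.rfft(b) * np.conj(np.fft.rfft(a)), n)
    k = int(np.argmax(cc))
    km, kp = (k - 1) % n, (k + 1) % n
    denom = cc[km] - 2 * cc[k] + cc[kp]
    delta = 0.0 if denom == 0 else 0.5 * (cc[km] - cc[kp]) / denom
    lag = k + delta
    if lag > n / 2:
        lag -= n
    return lag * dt


def _foot_time(w: np.ndarray, dt: float) -> float:
    """Systolic-upstroke foot: intersection of the 20-80% upslope regression
    with the diastolic baseline."""
    base = float(w.min())
    peak_i = int(np.argmax(w))
    peak = float(w[peak_i])
    if peak - base <= 0:
        return np.nan
    # rising edge before the peak (wrap so the upstroke is contiguous)
    rel = (w - base) / (peak - base)
    idx = []
    i = peak_i
    for _ in range(len(w)):
        i = (i - 1) % len(w)
        if rel[i] < 0.2:
            break
        idx.append(i)
    sel = [j for j in idx if 0.2 <= rel[j] <= 0.8]
    if len(sel) < 2:
        # too few samples on the upstroke: interpolate the 50% crossing
        sel = idx[-2:] + [peak_i] if idx else [peak_i]
    # unwrap times so they are monotone along the upstroke
    tt = []
    for j in sel:
        t = j * dt
        if j > peak_i:
            t -= len(w) * dt
        tt.append(t)
    tt = np.asarray(tt, dtype=float)
    yy = w[sel]
    if len(tt) < 2 or np.ptp(tt) == 0:
        return np.nan
    slope, intercept = np.polyfit(tt, yy, 1)
    if slope <= 0:
        return np.nan
    return (base - intercept) / slope


def estimate_pwv(wfs: FlowWaveformSet, method: str = "xcorr") -> PWVResult:
    """PWV (m/s) from arrival time versus arclength.

    Arrival per plane is the upstroke foot ('foot') or the lag maximising
    the circular cross-correlation with the most proximal plane ('xcorr').
    A non-positive or non-finite fitted slope is a flagged failure.
    """
    if method not in ("foot", "xcorr"):
        raise ValueError("method must be 'foot' or 'xcorr'")
    if len(wfs.arclengths) < 3:
        raise ValueError("need at least 3 usable planes")
    if method == "xcorr":
        ref = wfs.waveforms[0]
        arrivals = np.array([_xcorr_lag(ref, w, wfs.dt) for w in wfs.waveforms])
    else:
        arrivals = np.array([_foot_time(w, wfs.dt) for w in wfs.waveforms])
    ok = np.isfinite(arrivals)
    if ok.sum() < 3:
        return PWVResult(np.nan, arrivals, wfs.arclengths, method, False, "arrival detection failed")
    res = stats.linregress(wfs.arclengths[ok], arrivals[ok])
    slope = res.slope  # ms per mm
    if not np.isfinite(slope) or slope <= 0:
        return PWVResult(
            np.nan, arrivals, wfs.arclengths, method, False,
            "non-positive transit-time slope (degenerate or infinite wave speed)",
        )
    return PWVResult(float(1.0 / slope), arrivals, wfs.arclengths, method, True)
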