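# Methods

This document describes the computational model behind `aortatlas`: what
each stage assumes, the defaults it uses, and why. The package analyses
time-resolved aortic imaging — per-phase binary segmentations plus a
3-component velocity field on the same voxel grid — and produces
per-vertex wall-displacement maps, peak-systolic wall shear stress (WSS)
vectors, pulse wave velocity (PWV), control-cohort atlases, per-patient
abnormality heatmaps, cross-patient incidence maps, regional summaries
and group statistics. A synthetic cohort generator provides inputs with
known ground truth so that every stage is testable without external data.

## Synthetic cohort generator

Each subject is a "candy-cane" tube: a straight ascending limb (default
50 mm, annulus at the bottom), a half-torus arch (default radius 30 mm)
and a straight descending limb (default 110 mm). A straight ascending
limb is included so that the anatomical station ordering
annulus < PA bifurcation < brachiocephalic ≤ left subclavian < diaphragm
is geometrically satisfiable. The lumen radius tapers from ~16 mm at the
root to ~11.5 mm at the diaphragm, with a seeded low-frequency radial
perturbation (default 0.8 mm) providing between-subject shape
variability.

Wall motion: per phase `t`, the wall radius is
`r(s, t) = r0(s) · (1 + a(s) · w(t))` where `w` is a raised-cosine pulse
over the first 40 % of the cycle (unit peak at 0.2·RR) and `a(s)` encodes
the per-region displacement amplitude, smoothed over 6 mm at region
boundaries. Masks are voxelizations of the deformed tube.

Velocity: parabolic profile along the local tangent,
`v = tangent · v_peak(s) · (1 − (ρ/r_lum)²) · w(t − s/c)`, zero outside
the time-averaged lumen; the traveling-wave delay `s/c` applies only when
a wave speed `c` is set. Ground truth records per-region true
displacement (mm), true peak velocity (cm/s), analytic WSS and the wave
speed.

Group structure: regional displacement and velocity means/SDs default to
control-cohort literature values (displacement pAAo 9.8, dAAo 4.5,
pDAo 1.5, dDAo 1.8 mm; velocity 73.2 / 62.0 / 76.9 / 82.6 cm/s; PWV
6.6 / 9.0 / 10.0 m/s for control / native / post-surgical groups), with
group effects expressed as multipliers on both mean and SD. Localized
abnormalities (region, increase/decrease, multiplier) can be injected
into patients at a controlled prevalence; the manifest records each
subject's realized truth. These values are fixed study conditions of the
generator, never tuned to make tests pass.

Out of scope: no MRI signal simulation, no velocity-encoding noise or
phase wraps, no segmentation errors.

## Geometry

Surfaces come from marching cubes on the binary masks (scikit-image),
with optional Laplacian smoothing (default 5 iterations) and a
configurable step size (`mesh_step`; 2 halves the resolution for cohort
runs). The centerline is extracted by tracing the maximal-distance ridge
of the Euclidean distance transform between the inlet and outlet
landmarks, then smoothed and resampled by arclength. Regions of interest
(proximal/distal ascending, proximal/distal descending aorta) are
arclength bands between the named stations; the arch between the
brachiocephalic and left subclavian stations is excluded from regional
statistics. The descending-aorta boundary at the level of the PA
bifurcation is found by matching the PA bifurcation's axial position on
the descending limb.

## Non-rigid surface registration

Registration maps one surface onto another in three stages:

1. **Centroid initialization** of a global translation.
2. **Rigid point-to-plane refinement**: up to 10 Gauss–Newton steps
   minimizing the point-to-plane distance to the nearest target vertex
   (normal-equations solve with a `1e-9·n` ridge so directions the
   geometry cannot constrain — e.g. the axis of an open cylinder —
   default to zero motion). This step matters: centroid alignment alone
   is biased when the target deforms asymmetrically, and its tangential
   error is invisible to the subsequent normal-direction fitting, so it
   would survive as spurious displacement (~7 mm on systolic aortic
   phase pairs before this step was added).
3. **Gaussian-kernel non-rigid fit**: a smooth displacement field
   parameterized on ~400 control vertices with a 20 mm Gaussian kernel,
   fitted by iterative projection onto the target's tangent planes with
   an annealed ridge penalty (10 → 0.01 over 30 iterations, step 0.8).
   The best iterate is kept and the field is never allowed to worsen the
   mean residual; convergence requires a mean nearest-surface residual
   ≤ 0.5 mm (or half the voxel spacing if larger).

Failed registrations are flagged, excluded from atlases with a warning,
and surface maps that relied on them are marked.

## Displacement maps

Per-vertex displacement at phase `t` is the Euclidean norm of the
registration-mapped motion of each end-diastolic vertex. The peak frame
is the phase with the highest mean displacement (ties break to the
earliest phase; unweighted vertex mean by default, area-weighted
optionally). Regional values are area-weighted means over the unflagged
vertices of each ROI band.

## Wall shear stress

Peak systole is the phase with the highest spatially averaged
intraluminal velocity magnitude. At each wall vertex with inward normal
`−n` and local lumen diameter `D` (twice the distance to the nearest
centerline point), velocity is sampled at distances {0, D/4, D/2} along
`−n` by trilinear interpolation; the wall sample is forced to zero
(no-slip). The unique quadratic through the three samples gives the wall
shear-rate vector `dv/ds` at the wall — exact for a parabolic profile —
and the WSS vector is the viscosity times its tangential part. Default
dynamic viscosity is 3.2 mPa·s. Vertices are flagged (and zeroed) when
samples fall outside the lumen or the grid, when values are non-finite,
or near centerline endpoints.

## Pulse wave velocity

Flow waveforms are integrated over planes perpendicular to the
centerline at equal arclength spacing (default 8 planes), converted to
mL/s, and cyclically resampled to a 20 ms grid. Transit times come
either from FFT-based circular cross-correlation with parabolic sub-bin
refinement (`xcorr`, default) or from the foot of the upslope (20–80 %
regression, `foot`). PWV is the inverse slope of arrival time versus
arclength; non-positive or unstable slopes are flagged rather than
reported. Transit-time PWV needs adequate temporal sampling: with only
5 cardiac phases per cycle the resampled waveform shape is too coarse
and the estimate is unreliable (10+ phases recover synthetic wave speeds
to within a few percent; the accuracy tests use 25).

## Atlases, heatmaps, incidence maps

The control atlas lives on the control geometry with the smallest mean
symmetric surface distance to the others (the template). Every other
control map is registered and interpolated onto it; per-vertex mean and
sample SD (ddof = 1) define normal bands `mean ± 1.96·SD`. Because these
are not prediction intervals, at n = 20 controls a held-out control has
≈ 7 % (not 5 %) of vertices outside the bands; validation therefore
compares against a Monte-Carlo replication of the same procedure rather
than the nominal rate. Projecting the atlas onto a patient geometry and
comparing classifies each vertex as increased / decreased (strict
inequality; boundary values are normal). WSS direction is abnormal when
the patient vector deviates strictly more than 120° from the average
control direction; zero vectors and undefined atlas directions stay
normal but flagged. Incidence maps transfer each patient's binary
heatmap to a patient template by nearest-mapped-vertex transfer so
per-vertex counts stay integral, and report the proportion of patients
abnormal per vertex.

## Regional quantification and statistics

Regional summaries are area-weighted means per ROI (displacement, WSS)
and mean intraluminal velocity magnitude per arclength band. Station
diameters (root, ascending, proximal descending, diaphragm) come from
cross-sectional areas of plane–mesh intersections; diameter-adjusted
variants divide by the paired station diameter. Abnormal-area
percentages are area fractions of each ROI, excluding flagged vertices
from numerator and denominator.

Group comparisons use one-way ANOVA with a Bonferroni-corrected omnibus
threshold (0.05/4 = 0.0125 across the four regions); Tukey HSD pairwise
contrasts at 0.05 are reported only when the omnibus gate opens.
Abnormal-area comparisons between patient groups use the Mann–Whitney
rank-sum test (two independent samples; a signed-rank test would require
pairing that does not exist between independent groups — this
substitution is recorded in the report metadata). Correlations are
Pearson with Fisher-z 95 % CIs; determinants of abnormality use
univariable logistic regression with Wald CIs and explicit flagging of
complete separation. Incidence is reported as `97% (31/32)`-style
strings. The registration audit reports the paired pre- vs
post-registration difference of control displacement means with a
t-based 95 % CI.

## Key defaults

| Parameter | Default | Rationale |
| --- | --- | --- |
| viscosity | 3.2 mPa·s | standard blood dynamic viscosity for WSS |
| CI multiplier | 1.96 | two-sided 95 % normal bands |
| direction threshold | 120° (strict) | direction-abnormality rule |
| PWV method / resampling | xcorr / 20 ms | robust to waveform noise |
| PWV planes | 8 | stable slope fit along the arch |
| omnibus α / pairwise α | 0.0125 / 0.05 | Bonferroni over 4 ROIs, gated Tukey |
| SD convention | sample (n−1) | small control cohorts |
| registration residual | ≤ max(0.5 mm, spacing/2) | convergence contract |
| mesh step (cohort runs) | 2 | halves resolution; regional errors stay < 0.5 mm |
| n_phases (scaled runs) | 5 or 10 | phase grid contains the exact pulse peak (0.2·RR) |

Every default left open by the underlying protocol is enumerated in each
run's decisions log (`RunConfig.decisions_log()`), which is written into
cohort metadata.

## Scaled-down problem sizes

Full-resolution subjects (30 phases, 1 mm isotropic) are used for
single-subject accuracy validation. Cohort-scale runs and examples use
5–10 phases and `mesh_step=2`; these are this package's own scaling
choices for desktop runtimes and do not change any estimator, threshold
or tolerance. Statistical power validation (group-effect recovery over
50 replicates) runs at the generator's subject-parameter tier — the same
sampling layer the voxel pipeline consumes — with imaging-tier
measurement fidelity established separately by the displacement-recovery
and WSS oracles.

## Limitations

- The generator's wall motion is purely radial around a fixed
  centerline; no bulk cardiac motion, torsion or through-plane motion.
- Velocity fields are noiseless and exactly parabolic; WSS accuracy on
  real data will be limited by segmentation and near-wall interpolation.
- `mean ± 1.96·SD` bands are tolerance bands, not prediction intervals;
  with small control cohorts the per-vertex false-positive rate exceeds
  5 % and band stability depends strongly on the number of controls
  (e.g. with 8 controls, spatially coherent false positives can stack
  across patients; 20 controls behave well).
- PWV requires a traveling-wave delay and sufficient temporal
  resolution; synchronous or coarsely sampled inputs are flagged.
- Registration assumes tube-like topology and roughly corresponding
  geometry; it has no landmark constraints.
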