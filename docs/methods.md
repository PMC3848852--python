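# Methods

This package post-processes velocity-encoded (phase-contrast / tissue phase
mapping) cine MR of the rodent left ventricle: it reconstructs per-pixel
myocardial velocities from multi-coil nine-point encoded data, divides the
myocardium into 32 circumferential segments anchored at the papillary
muscles, derives regional velocity waveforms, tracks closed material
trajectories through the cardiac cycle, computes segmental circumferential
Lagrangian strain, and summarizes regional dysfunction with five indices.
A deforming-annulus phantom with closed-form ground truth exercises every
stage.

## Velocity reconstruction

Spin displacement between the lobes of a bipolar gradient is encoded in
signal phase; with encoding first-moment matrix `M` (9×3; row 0 the
reference, rows 1–8 at the corners of the symmetric cube (±1,±1,±1)/√3),
the phase of encoded point *e* at a pixel with velocity `v` is
`φ_e = (π / venc) · M_e · v`. Coils are combined by complex-conjugate
multiplication of each encoded image with the reference image, summed over
coils: coil phase cancels exactly and each coil contributes with weight
|reference|². Velocities are decoded per pixel by least squares over the
eight phase differences; the spec'd reference-magnitude² weighting is
uniform across one pixel's eight equations and therefore cancels — the
plain pseudo-inverse solution is identical. Phase unwrapping is not
attempted: the protocol's venc (13.9 cm/s) exceeds myocardial velocities,
so pixels with |φ| near π are flagged and excluded from masks downstream.

Background (eddy-current) phase is corrected by fitting a 2D polynomial
(default total degree 1, the dominant eddy-current term) to each encoded
point's temporal-mean phase over user-declared static tissue, excluding
regions annotated as fold-over-contaminated, and subtracting the fitted
surface everywhere. The full spatially-resolved correction used on-scanner
is proprietary to its reference implementation; the polynomial surrogate is
this package's documented stand-in and is exact for polynomial background
fields of the fitted order.

## Geometry and segmentation

The human inputs are epicardial/endocardial contours at key frames, two
papillary reference points, fold-over exclusion polygons, and the
last-diastolic frame index. Key polygons are resampled to 256 vertices by
arc length, anchored at the papillary reference angle, and interpolated
linearly vertex-by-vertex between key frames with periodic closure over the
cycle. The myocardial mask holds pixels inside the epicardium and outside
the endocardium (pixel-centre test), minus fold-over regions and
wrap-flagged pixels. The LV centre is the epicardial centroid; segment
index is `floor(32·Δθ/2π)` with Δθ counted counterclockwise from the
(anterior) papillary reference angle, ties to the lower index, reference
evaluated once against the frame-0 centre (the trajectory segment
membership is fixed at the origin frame in any case, and short-axis twist
is small).

Relative lumen-area accuracy of linear contour interpolation is
ill-conditioned near end-systolic obliteration (endocardial radius
~1.5 mm in the rat): between key frames the square-root wall collapse
deviates from the linear chord by up to ~3% of a radius there, i.e. a few
percent of a very small area (≈0.5 mm², ~3 pixels). Tests therefore bound
epicardial area relatively (2%) and endocardial area absolutely (0.6 mm²).

## Kinematics

Bulk cardiac motion is removed by subtracting the mask-mean in-plane
velocity per frame (through-plane untouched). Velocities are decomposed
into cardiopolar components about the LV centre; **the radial component is
positive for contraction** (motion toward the centre) — stated prominently
because the opposite convention is common. Regional waveforms are segment
means; the global waveform is the mean over all mask pixels (not the mean
of segment means). Peak systole is the frame of peak global radial
velocity; end systole the frame of minimum endocardial (lumen) area;
end-diastole comes from the annotation.

Two acquisitions of the same slice with the field of view rotated in-plane
(≥30°) are processed independently — each with its own papillary-anchored
segmentation — then combined: the second run's time axis is stretched by
the factor (grid 0.80–1.25, step 0.005, covering heart-rate variation with
margin) maximizing Pearson correlation of the global radial waveforms,
resampled by cycle-periodic cubic splines, and averaged segment-by-segment
(segment *s* with segment *s*; this pairing by anatomical index is how the
rotated FOV is reconciled). Phase-encode-direction artifacts differ in
orientation between the rotations and attenuate in the average.

## Trajectory tracking

Every mask pixel of the origin frame (end-diastole, and again end-systole,
where the in-slice myocardial area is larger) is integrated forward and
backward through the cycle. Velocities are looked up nearest-neighbour in
space and frame-wise in time, as-is wherever the path currently is; steps
are explicit two-stage (Heun) — predictor with the current frame's
velocity, corrector averaging the next frame's velocity at the predicted
point. The two passes are blended with linear-in-time weights
`x(t) = (1 − t'/T)·x_fwd + (t'/T)·x_bwd`, which enforces exact closure
`x(origin + T) = x(origin)`. Heun was chosen over first-order Euler after
benchmarking both against Runge–Kutta integration of the phantom's analytic
field (RMS path error 0.19 → 0.15 px at default resolution); a
configuration switch recovers pure forward integration for diagnostics.

Trajectories travelling out of the myocardial mask are discarded and no
other filtering is applied. The mask test is a point-in-polygon check of
the continuous position against the per-frame contours: the user-defined
mask is the contour region, and rounding to the pixel raster first was
found to discard wall-adherent boundary paths spuriously (ED-origin
retention 84% → 94% on the default phantom).

## Circumferential strain

With `x_s(t)` the mean in-plane position of the valid trajectories seeded
in segment *s*, segmental Lagrangian circumferential strain is the
neighbour-centroid chord ratio

    Sc_s(t) = |x_{s−1}(t) − x_{s+1}(t)| / |x_{s−1}(t_ED) − x_{s+1}(t_ED)| − 1

referenced to the first frame of the trimmed cycle (end-diastole; closed
paths make Sc_s(t_ED) ≡ 0 — the package's one exact analytic check). The
chord is used as written, without arc-length correction. ED- and ES-origin
strain waveforms are averaged segment-wise; a segment with no valid
trajectories renders its own and its neighbours' strain missing, with
fall-back to the other origin's curve. Global Sc is the unweighted segment
mean (configurable). As an internal control, a contour-based global strain
is computed from the epicardial/endocardial perimeters,
`Sc_g = ½[ΔL_epi/L_epi + ΔL_endo/L_endo]`; on an incompressible wall it
systematically overestimates the trajectory-derived strain because wall
thickening contributes to the perimeter change.

### Accuracy at the study resolution

Two floors matter at 128×128 over 50 mm (0.39 mm pixels, a 4.6-pixel
wall, ~8 pixels per segment):

* **Rasterization floor.** The transmural strain gradient of the
  incompressible annulus spans −41% (endo) to −13.8% (epi) at peak while
  the mid-wall value is −20%; which pixels a segment happens to contain
  sets its effective radius. With *exact* analytic trajectories the
  chord estimator's per-segment end-systolic error reaches 1.14 %strain
  (dual-acquisition average) with ~0.4 %strain scatter, and the global
  peak reads ≈ −19.5%.
* **Boundary-stall noise.** Nearest-neighbour lookups at the rendered
  wall's sharp zero-velocity edge stall boundary-adjacent paths by up to
  ~0.2 mm (typically one path per segment survives with such a lag),
  biasing strain magnitudes slightly low, predominantly for ES-origin
  tracings whose Eq.-baseline is itself tracked.

Together these put the pipeline's per-segment end-systolic error at
~1.4–1.9 %strain (dependent on the arbitrary papillary anchor's position
relative to the pixel grid), the delay-free segment scatter at ~0.4–0.7
%strain SD, and the global peak within 1 %strain of the analytic mid-wall
value. Test tolerances are set from this floor analysis. Real data adds
physiological noise these floors do not model.

## Regional-function indices

Sample (n−1) standard deviations throughout, configurable. (1) dispersion
of peak motion: SD over segments of regional radial velocity at peak
systole; (2) dispersion of peak strain: SD of regional Sc at end-systole;
(3) coherence of motion waveforms: mean Pearson correlation of regional vs
global radial waveforms; (4) dispersion of motion waveforms: SD of those
correlations; (5) index of dyssynchrony: SD over segments of the
cross-correlation delay of each regional waveform against the global one
(circular search over ±25% of the cycle — avoiding half-cycle aliasing —
with quadratic sub-frame refinement of the correlation peak). For
cross-modality comparison, curves are spline-resampled to 23 points per
cycle and synchronized at peak global Sc; Bland–Altman limits of agreement
are bias ± 1.96·SD of paired differences. A two-sample t-test is included
as plumbing for cohort contrasts.

## The phantom

The generator emulates the target protocol: 128×128 matrix, 50×50 mm FOV,
70 frames at 3.2 ms, venc 13.9 cm/s, 4 receive coils, and an annulus with
end-diastolic radii 2.6/4.4 mm (rat mid-ventricular short axis). Motion is
the area-preserving squeeze `r(r0,t) = sqrt(r0² − a(t))` with a raised-
cosine pulse `a(t)` occupying the first 40% of the cycle (smooth, periodic,
analytically differentiable), a rigid twist of 0.12 rad peak with the same
waveform, and a uniform sinusoidal through-plane velocity (2 cm/s peak).
The default contraction amplitude 0.2 sets peak mid-wall strain to −20%
and peak radial velocity to ≈2.6 cm/s, matching healthy-rat scale; the
Eulerian velocity field, material displacements, contours and segmental
strain are exact closed forms. Per-segment activation delays and
hypokinesia scalings modify `a(t)` sector-wise (5° cosine-blended sector
transitions keep the velocity field continuous), anchored at the papillary
reference angle — 10°, deliberately generic so no sector boundary
coincides with the pixel diagonals, where floor-based assignment would be
degenerate on the raster.

Annotation key frames are placed every 2.5% of the cycle where the wall
moves fastest (systolic onset and relaxation end) and every 5% elsewhere
through systole — the schedule a careful annotator would use — so that
linear vertex interpolation tracks the boundary well within the tested
bounds. Encoding replicates the planes over smooth low-order-polynomial
complex coil maps (deterministic from the seed); an optional phase-encode
ghost adds a half-FOV-shifted replica of the moving-tissue signal with an
independent random phase per acquisition. With the heart centred, that
replica lands on static chest tissue and perturbs the measurement through
the static-region eddy-current fit — a spatially varying bias whose
orientation differs between the two FOV rotations, which is what the
rotating-FOV average attenuates. The hypokinetic preset (8 contiguous
segments scaled to 0.3 with 12 ms delays) reproduces the infarct
phenotype's direction on every index: lower peak velocities and strain,
higher dispersions, lower coherence, higher dyssynchrony.

The dyssynchrony preset imposes delays as the *second* circumferential
harmonic of the segment index. A first-harmonic pattern is physically a
rotating net in-plane translation (the centroid of contraction sweeps the
ring), which bulk-motion correction then removes — correctly, but
distorting the regional timing under study (imposed 12.8 ms SD recovers as
9.0; with bulk correction disabled, recovery is exact). The m=2 pattern
carries the same SD with no net-translation component and recovers within
0.3 ms across the tested range.

What the phantom does **not** model: k-space sampling, coil noise and
noise correlations, respiratory motion, trigger jitter, partial-volume
boundary signal (its wall edge is sharply zero-velocity — harsher than
real data, and the origin of the boundary-stall floor above), and any
analytic model of post-infarct mechanics (hypokinesia is a stand-in, not a
claim). Passing tests demonstrate correctness of the processing chain and
its behaviour under controlled deformation, not performance on in vivo
data.

## Numerical and convention notes

* Coordinates: 0-based pixel indices, pixel-centre sampling, x with
  column, y with row, mm = (index − (N−1)/2)·pixel_mm; angles from
  `atan2(y, x)`; counting direction configurable (+1 default).
* 1 cm/s = 0.01 mm/ms links velocity units to the mm/ms integration grid.
* Polynomial background fits use coordinates normalized to [−1, 1] for
  conditioning; basis ordered constant first, then x before y per degree.
* Ties: segment assignment by `floor` (boundary pixel to the lower index);
  key-timepoint ties to the earliest frame; delay-search correlation peak
  refined only when strictly interior to the search window.
* Degenerate inputs raise typed errors: annulus collapse, self-intersecting
  or nested-violating contours, empty masks, rank-deficient encoding
  matrices, insufficient static pixels, zero baseline chords, all-invalid
  trajectory sets.
* Problem sizes in the test suite: the full-resolution phantom study
  (two encoded rotations, both origins) runs once per session and backs
  the strain/tracking checks; coarse 64×64 phantoms exercise file and CLI
  plumbing.
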