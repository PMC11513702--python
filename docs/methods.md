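# Methods

## Coordinate conventions

All geometry is in millimetres in a right-handed frame.  Measurement
directions are never inferred from the mesh: each tooth's annotation carries
a unit `coronal_axis` (pointing crown-ward; apical is its negation) and a
unit `buccal_normal` (out of the cheek-facing surface), and every metric is
defined relative to these.  The synthetic generator emits occlusal = +z for
the mandible and −z for the maxilla, with the buccal direction radially
outward from the arch axis; real scans may be oriented arbitrarily as long
as the annotation vectors are consistent with the mesh.

## Registration

The post-operative mesh is mapped into the pre-operative frame by a strictly
rigid transform (no scale: both casts are metric scans from the same
scanner).

*Coarse alignment* matches centroids and principal axes.  The eigenvector
basis leaves a four-fold sign ambiguity (two axis flips preserving
handedness); all four candidates are scored by symmetric mean
nearest-vertex distance on a 500-point subsample and the best kept.
Rank-deficient vertex covariance (e.g. a single triangle) raises an error.

*Refinement* is point-to-plane ICP restricted, by default, to crown
vertices — the predicate selects vertices within 3.5 mm of a tooth's margin
centroid in the plane orthogonal to its axis and at least 0.8 mm coronal of
the margin.  The gingiva changed between timepoints, so including it drags
the transform toward the soft-tissue displacement; the masked estimate is
never worse, and the test suite asserts this against ground truth.
Correspondence rejection thresholds start at 1.0 mm and shrink by 0.7 per
stage to a 0.2 mm floor.  Early stages pair moving points with nearest fixed
*vertices* and their area-weighted normals; the final stage switches to exact
nearest points on the fixed *surface* with face normals, because the vertex
shortcut leaves a curvature-dependent bias of order (edge length)² (~1e-3 mm
at 0.25 mm edges) that matters when a post-operative margin sits within a
micron of the CEJ.  Updates solve the standard linearised 6-DOF system
J = [p×n, n]; rotations are re-orthonormalised by SVD after every step.  An
update that would increase the point-to-plane RMS is rejected and ends the
stage, which makes the residual non-increasing within each stage.
Termination: relative RMS change < 1e-6, at most 200 total iterations, at
most 4000 moving points (deterministic stride subsample).  Nearest-neighbour
ties resolve to the lowest index (scipy's KD-tree is deterministic), so runs
are exactly reproducible.

On noise-free synthetic pairs the crown surfaces are identical point sets,
so the true transform is an exact fixed point and is recovered to machine
precision; with 0.01 mm vertex noise the residual sits at the noise floor
(~0.01 mm RMS).

## Measurement

*Deepest recession point*: the margin polyline point with minimal coordinate
along the coronal axis; ties break to the lowest index.

*Recession depth* (CEJ-dependent): the CEJ partner point is the polyline
point nearest in the plane orthogonal to the axis — plain nearest-point
pairing could jump to the contralateral CEJ arm.  The depth is the axial
coordinate difference, positive when the margin is apical to the CEJ and
possibly negative post-operatively.  Teeth without a CEJ polyline are
flagged and excluded from mRC/cRC, mirroring clinical practice of excluding
cases where the CEJ is not discernible.

*Recession reduction* (CEJ-independent): the distance between the deepest
pre- and post-operative margin points after registration.  The classical
two-point distance is unsigned; a sign is attached from the axial
displacement component so a worsened recession is representable (mRC can be
negative, so the CEJ-free metric must be too).  The default is the full 3-D
Euclidean distance; `MeasurementConfig(reduction="axial")` switches to the
axial projection.  In the pure-axial limit the two coincide exactly.

*Thickness profile*: a sagittal plane through the recession apex is spanned
by the coronal axis and buccal normal.  Sample locations are the pre-op
surface points at axial offsets −3…+3 mm in 1 mm steps (7 points; whether
the apex itself belongs to the grid is genuinely ambiguous, so
`include_apex=False` gives the 6-point variant — the apex sample is always
measured for the fallback).  The deviation at each location is the signed
distance to the post-op surface along the buccal normal, positive outward;
deviations beyond 3 mm, or rays that miss (holes from impression
artifacts), mark the sample invalid.  All samples valid → `full_profile`
mode with the mean; any invalid → `apex_only` mode with the offset-0
deviation, matching the single-point fallback used clinically when papilla
artifacts corrupt the casts; an invalid apex sample fails the tooth.
Deviation along the annotated buccal normal (not the local surface normal)
keeps the measurement annotation-driven and reproducible, and coincides
with surface-comparison heat-map semantics for near-parallel surfaces.
Ray-surface queries use a vectorised Möller–Trumbore intersector with a
per-tooth triangle prefilter; hits are sorted, so results are deterministic.

Replicated measurement (raters × replicates) re-runs the landmark-dependent
metrics with iid Gaussian jitter on the polyline points, emulating repeated
manual landmark selection.  The default jitter of 0.02 mm reflects the
~0.01 mm point-picking accuracy of digital cast metrology and yields
replicate ICCs in the high 0.9s; larger jitter causes the deepest-point
selection to switch between margin points and degrades agreement rapidly.

Per-tooth values are kept at full precision; summaries are reported to two
decimals.

## Synthetic arch model

The arch is a height field r(θ, z) about a vertical axis: a cylindrical
gingival wall (radius = `arch_radius`, default 25 mm), a mucosal flare
below z = −6, and per-tooth smooth crown bulges (plateaued cosine windows of
0.45·`tooth_spacing` half-width, ~2 mm prominence, rising 0.8 mm coronal of
the CEJ).  Teeth sit every 7 mm along the arc.  The grid is triangulated at
`mesh_edge_length` (default 0.25 mm — comfortably below the scale of every
feature measured, with chord error ≪ 1 µm on the wall; finer meshes change
results only in the fourth decimal).

Per tooth, drawn from a stream hashed from (seed, tooth_id) so results are
independent of tooth ordering:

| parameter | default | note |
|---|---|---|
| pre-op recession depth | N(1.34, 0.92²) mm, truncated at 0, clipped at 4 | clinical scale of the cohorts this emulates |
| coverage fraction | N(0.65, 0.48²), clipped to [0, 1.2] | values > 1 put the margin beyond the CEJ, so complete coverage occurs stochastically (~25 % of teeth) |
| thickness gain | N(0.33, 0.30²) mm, may be negative | plateau amplitude of the inflation band |
| CEJ height | U(−0.2, 0.2) mm | per-tooth jitter |
| artifact | Bernoulli(0.10) | papilla-region crater |

The gingival margin is a scalloped curve (deepest mid-tooth, rising 0.8 mm
toward the papillae) *marked on* the surface rather than modelled as a
radial step: the pre-to-post mesh difference is exactly the thickness
inflation field, applied along the buccal direction over a 6 mm band apical
of the post-operative margin with a 1.2 mm ramp below the margin curve and a
1.5 mm apical fade.  This "flush" model keeps every ground-truth quantity
closed-form: the margin apexes differ only axially (so the true reduction
equals depth_pre − depth_post under both reduction conventions), and the
expected deviation at each thickness sample is the analytic taper value.
`true_thickness_gain` records the expectation of the deviation field over
the 7-point grid (and `true_thickness_gain_apex` over the apex alone),
which is the quantity the measurement can recover; the drawn plateau
amplitude is kept separately as `drawn_thickness_gain` — samples coronal of
the post-operative margin lie on unchanged root surface and legitimately
read zero, so the grid mean is below the plateau for typical reductions.

The post mesh is additionally perturbed by a random rigid transform
(rotation ≤ 10°, translation ≤ 5 mm, recorded in the truth) and iid Gaussian
vertex noise (default sd 0.01 mm, the scanner accuracy scale).  Landmark
polylines are exact in each mesh's own frame.  Artifacts remove faces within
a 1.6 mm radius of a point 2.5 mm apical of the recession apex and 1 mm off
the mid-plane: the apical thickness samples (−2, −3 mm) fall in the hole and
go invalid while the apex band stays intact, exercising the fallback path.

A study-scale layout (`study_design`) arranges 82 teeth over 19 patients
(six 5-tooth and thirteen 4-tooth arches; 38 maxillary / 44 mandibular
sites) for the clustered statistical layer.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: anatomical tooth shapes and interdental
embrasures (teeth are smooth bulges on a continuous wall); a visible margin
step or sulcus; the soft-tissue step where newly advanced gingiva covers
previously exposed root (the flush model reads zero deviation there, so the
cohort-mean measured thickness gain, ~0.17 mm at defaults, is below the
drawn 0.33 mm plateau); correlated scanner noise or impression distortion
beyond local craters; CEJ mislabelling by raters.  Parameter *recovery* is
validated against the generator's own truth, which is the strongest claim a
synthetic oracle supports.

## Statistics

*Group comparisons.*  Outcomes are compared across recession type, jaw or
tooth type with teeth clustered in patients.  The default fits a linear
mixed model with a patient random intercept (statsmodels MixedLM, REML);
`patient_effect="fixed"` instead absorbs patients as OLS dummy effects — a
deliberately exposed alternative reading, since "patient as a fixed effect"
appears in the clinical literature interchangeably with mixed modelling.
The overall factor test is a Wald F with containment-style denominator df
(N − k − n_patients + 1) rather than the asymptotic χ²: at 19 clusters the
χ² reference is anticonservative, while the F reference holds the nominal
5 % level (measured 5.2 % over 1000 null simulations).  Pairwise contrasts
use Scheffé's correction, p = P(F_{k−1,df} ≥ F_contrast/(k−1)), which can
never undercut the unadjusted p and is coherent with the overall test.
Replicated measurements are collapsed to per-tooth means before modelling.

*Agreement.*  ICC(2,1) — two-way random effects, absolute agreement, single
measurement — from the ANOVA mean squares, with the McGraw–Wong F-based
confidence interval (Satterthwaite df); ICC(3,1) is available.  Degenerate
tables (zero between-tooth variance) return 0 with a warning.  The
implementation is cross-checked in the tests against an independent one
(pingouin's ICC(A,1)/(C,1)) to 1e-9.

*Sample size.*  n = ⌈((z_{1−α/2} + z_{power})·σ/δ)²⌉ with a two-sided α
quantile; with the 87 %/10-point/σ=25/90 %/5 % planning inputs this gives
⌈65.67⌉ = 66 teeth.  A variance-inflation-factor adjustment for clustered
teeth, ⌈VIF·65.67⌉ = 198, is reported alongside: how a VIF of 3 combines
with the unadjusted 66 is not standard, so both figures are exposed and
neither silently preferred.  σ = 0 returns the enforced minimum of one
tooth.

## Numerical choices

* Vertex merge tolerance 1e-6 mm (below scanner resolution; removes STL's
  per-facet duplication).  Faces with repeated indices or area < 1e-12 mm²
  are dropped.
* Binary STL stores float32; at 25 mm coordinates the round-trip error is
  ~1e-6 mm, which the I/O tests bound.
* ICP: rejection 1.0 → 0.2 mm (×0.7), tolerance 1e-6 relative, ≤ 200
  iterations, ≤ 4000 points, final-stage exact surface correspondences.
* Thickness rays start 8 mm outside the surface; deviations are capped at
  ±3 mm; ray–triangle ε = 1e-9.
* Truncated-normal depth draws use scipy's truncnorm, so the realised mean
  (~1.48 mm) sits slightly above the nominal 1.34 mm location parameter, as
  truncation at 0 implies.
* All randomness flows from integer seeds through numpy Generators; derived
  streams hash (seed, tooth_id) so per-tooth draws are order-independent.

## Problem sizes

The test suite and the acceptance script use 0.25–0.5 mm mesh edges,
4–10-tooth arches for unit and registration tests, the 19-patient/82-tooth
layout for cohort-level checks, and 600–1000 null simulations for the
type-I calibration — sizes at which every tolerance above is met with an
order of magnitude to spare while a full run stays in the minutes range on
one CPU.

## Known limitations

* No automatic tooth segmentation or CEJ detection: landmarks come from the
  annotation file (clinically they are transferred from the physical cast).
* Strictly rigid registration; prosthetic changes between timepoints that
  alter crown geometry would bias the mask and are out of scope.
* The Scheffé correction is applied per factor; no correction across the
  several outcome parameters.
* The mixed-model denominator df is a containment approximation, not
  Kenward–Roger; at very small cluster counts (< ~8 patients) the level may
  drift.
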