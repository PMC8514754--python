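# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `pulmobif`. Units are fixed package-wide: geometry in
millimetres, velocity in m/s, wall shear in Pa, time in seconds; only the
dimensionless-number computations convert lengths to metres.

## Centerline model and Frenet quantities

A branch centerline is a cubic/quintic smoothing spline fitted to the raw
ordered points (chord-length parametrized), then reparametrized by arc
length on a uniform grid (default step 0.25 mm). First and second
derivatives come from the spline via the chain rule; the third derivative,
needed only for torsion, is a finite difference of the analytic second
derivative on the uniform grid — torsion is the noisiest of the reported
quantities and is masked to zero where |c′×c″| < 1e−9 (straight spans).

The smoothing factor is a per-point residual budget in mm² (scipy's `s`
equals `smooth_factor · n_points`). The default, 1e−6, is effectively
interpolating and keeps curvature errors below 0.3 % on circle and helix
fixtures at the default sampling; for noisy inputs the appropriate budget
is about 3σ² of the per-coordinate noise (with σ = 0.05 mm this recovers a
20 mm-radius circle's curvature to better than 1 %). A fixed factor was
chosen over cross-validation deliberately: determinism matters more here
than adaptivity, and the inputs (VMTK-style exports or the in-package
generator) have known noise levels.

Branch statistics (curvature mean/max, tortuosity, minimum inscribed
radius) are evaluated from the bifurcation origin O to the branch end,
excluding 0.5 D_ref at each extremity, where D_ref is the trunk inlet
diameter. The exclusion keeps artificial extensions and end-cap effects
out of the statistics; whether published cohort tables include such
extension regions is generally unstated, so this is fixed here by
convention.

Inscribed radii are nearest-point distances from the centerline to the
triangulated wall (a cKDTree candidate search over face centroids followed
by exact point-triangle projection — no spatial-index extension needed).
Near capped tube ends the nearest surface is the cap, not the wall, which
is exactly the end-cap artifact the 0.5 D_ref exclusion removes.

## Bifurcation origin, plane, and angles

* **Origin O** — the first point moving downstream along the trunk
  centerline where the two daughter centerlines (which share the upstream
  trunk run, as VMTK emits them) separate by more than the local inscribed
  radius. This surrogate reproduces the analytic junction of generated
  geometries to within one local radius.
* **Bifurcation plane** — the total-least-squares plane through centerline
  samples within 1.5 D_ref of O on all three branches. An important
  property of any symmetric fit: when a daughter leaves the plane, the
  fitted plane rotates partway toward it (the trunk, lying along the
  rotation axis, cannot pin the plane). Out-of-plane angles are therefore
  meaningful only relative to this documented convention, and all
  recovery tests compare the discrete pipeline against the same convention
  evaluated on exact analytic paths. A robust (redescending-weight) fit
  was evaluated and rejected: with one tilted branch, the planes through
  trunk+RPA and trunk+LPA each fit exactly two thirds of the samples, so
  the robust objective is bistable and the selected branch is an accident
  of initialization.
* **Angles** — branch direction is the mean unit tangent over 1.0 D_ref of
  arc downstream of O; the trunk direction is the mean tangent over the
  same arc upstream, reversed. The in-plane angle is measured between the
  two directions after projection into the plane, so a branch continuing
  straight scores 180°. The out-of-plane angle is the signed angle between
  the branch direction and its in-plane projection; the plane normal is
  oriented so that n·(t_RPA × t_LPA) ≥ 0, and the sign is positive when
  the branch direction has a positive component along n (the "clockwise"
  sense viewed along the normal). A reflection of the input flips the
  sign, as it must.

Curvature profiles are resampled on an abscissa normalized by the arc
distance to the interior curvature peak nearest the bifurcation (grid
[0, 2], 81 points); straight branches with no interior peak are excluded
from cohort averages with a per-point count reported.

## Torsion formula

The torsion denominator is the standard Frenet |c′×c″|²; a printed variant
with a first-power, mixed-order denominator is dimensionally inconsistent
and is not implemented.

## Flow characterization

Flux from voxel series is the mask sum of v·(pixel area) — with velocity
in m/s and pixel area in mm² this is directly ml/s. Lumen area is the mask
count times pixel area, and U(t) = Q/A. Net volumes use the trapezoidal
rule with periodic closure, the positive and negative lobes integrated
separately. Cohort waveforms are averaged after normalizing each cycle's
time by its own period (periodic linear interpolation onto a 100-point
grid); Qm* is the cycle mean of the averaged waveform.

The missing-split estimator scales the cohort-average branch-flow ratio by
the squared ratio of branch radii; the "average radii" are arithmetic
means of the per-patient radii (ratio of means), matching how an averaged
branch radius would be tabulated. The estimator is invariant to a common
rescaling of all radii.

Dean numbers use the daughter's maximum curvature by default (the Dean
peak tracks the curvature peak along the branch); mean curvature is a
config option and the per-sample profile De(s) is also available. The
k–ω SST inflow spec implements I = 0.16 Re^{−1/8}, k = 1.5 (UI)²,
L = 0.07 D, and ω = √k/(0.09^{1/4} L); a literal ω = k/(0.09 L) variant is
available behind a flag because that dimensionally inconsistent form
circulates in print, but it is not the default.

## Inlet mapping

Both the masked voxel set and the inlet nodes are centered on their own
centroids and projected into a single in-plane basis constructed from the
inlet normal (the voxel plane is assumed aligned with the inlet, as the
acquisition workflow arranges). Radii are normalized by each set's own
maximum radius — this absorbs lumen-size mismatch between the imaging
plane and the meshed inlet. Matching is nearest-neighbour in
(r·cosθ, r·sinθ), with ties resolved to the lowest voxel index. Because
one shared basis is used, a common rigid rotation of both grids rotates
both 2-D point sets identically and the matching is invariant.

The mapped velocity is a scalar along the inlet normal (through-plane
only; in-plane components are out of scope). Nodal flux uses lumped nodal
areas (one third of each incident triangle). Flux conservation is a
separate, explicit repair: a per-timestep uniform rescale to a target
waveform, exact to machine precision. No temporal interpolation happens
inside the mapping; a periodic resampling utility covers solver-timestep
mismatch.

Convergence note: as voxel spacing decreases, nodal values converge to the
sampled profile at first order; the *flux* additionally carries a fixed
inlet-quadrature term (nearest-vertex sampling on a coarse triangulation),
so flux error plateaus at the inlet resolution rather than decreasing
indefinitely.

## Wall-shear post-processing

TAWSS integrates |τ_w(t)| by the trapezoidal rule over one period on a
grid whose first and last samples are identified (t = 0 and t = T); OSI is
the standard 0.5(1 − |∫τ|/∫|τ|), set to 0 where the magnitude integral
vanishes, clipped to [0, 0.5]. Doubling time resolution moves TAWSS by
< 0.2 % on smooth series.

The inlet normalization reference is the area-weighted mean TAWSS over the
wall band adjacent to the inlet, one local radius wide — "at the inlet" is
not a well-defined wall region, so the band is the documented surrogate.

Cross-sections are plane cuts (normal = local centerline tangent) at a
prescribed fraction of D_ref in arc length from O; when a cut near the
junction intersects several wall loops, the loop whose centroid is nearest
the centerline point is kept and the rest are discarded with a log entry.
Perimeter sampling places n points (default 8) equally spaced in arc
length, anchored at the loop point most aligned with a caller-supplied
direction (default: the first loop point) so that results are
reproducible; the anchor choice shifts individual samples but not the
8-point mean on smooth fields.

## Mean-shape template

The template is the zero isosurface of the average of signed-distance
fields sampled on a common 1 mm grid (matching the 1 mm convergence
tolerance). Distances are clamped to a band; outside the band the sign
comes from the nearest vertex's area-weighted pseudonormal, inside it from
the nearest face. The loop registers all surfaces at their origins
(translation-only by default, optional trunk-tangent rotation), averages,
and measures the symmetric maximum surface distance between the round's
reference and the template it produced; the reference participates in the
average (as in forward atlas estimation), so the initial cohort-member
reference biases the first template and iterating washes that bias out,
with the bias shrinking by roughly 1/(n+1) per round. Convergence is
declared at ≤ 1 mm; hitting the iteration cap (default 7) flags the result
instead of raising.

This is deliberately **not** a diffeomorphic atlas: no correspondences,
no deformation kernels. The downstream use of the template is a mean
*surface* to run flow on, and the signed-distance mean delivers that with
a transparent convergence rule. All template outputs are labelled with the
surrogate method name.

## Synthetic-data generator

The generator is the package's study-conditions definition, not a test
dial:

* **Geometry** — trunk along +z ending at O; daughters leave O along
  directions set by their in-plane/out-of-plane angles, run straight for
  0.8 D_MPA (so 0.4D/0.6D cross-sections land on analytically known tube
  segments), then follow a circular arc of prescribed radius, optionally
  perturbed by an envelope-windowed sinusoid normal to the branch plane.
  Tubes are swept with parallel-transported frames (64 circumferential ×
  0.5 mm longitudinal by default), capped, united, and lightly
  Laplacian-filleted within one trunk diameter of O. A sweep whose
  path curvature × tube radius approaches 1 would self-intersect and
  raises instead. Cohort draws are uniform over ranges reflecting the
  printed seven-patient tables (trunk diameter 17–30 mm — the 50 mm
  dilated-trunk outlier is excluded because it cannot be swept at the
  default branch lengths — in-plane 124–164°/110–168°, out-of-plane
  −35..10°/−21..59°), with geometrically infeasible corner combinations
  rejected and redrawn deterministically.
* **Ground truth** — every generated model carries its exact parametric
  path polylines, nominal angles, junction point, and trimmed-span
  curvature/tortuosity statistics computed directly on the fine paths.
  Angle-recovery oracles evaluate the pipeline's own angle/plane
  conventions on these exact paths, so tests measure discrete-pipeline
  error, not convention mismatch.
* **Waveforms** — a sin² systolic lobe over 35 % of the cycle plus, for
  regurgitant cases, a negative diastolic sin² lobe scaled so backward
  volume equals the requested fraction of forward volume. Cohort periods
  0.6–1.0 s, cycle-mean flows 34–114 ml/s, regurgitant fractions
  0.30–0.50, all matching the printed cohort's ranges.
* **Voxel grids** — plug, parabolic, or Womersley-like (steady Poiseuille
  part plus the first two harmonics of the analytic oscillatory profile,
  full Bessel evaluation) profiles on a square pixel grid; each frame is
  flux-normalized over the discrete mask so the integral matches the
  waveform exactly before optional Gaussian noise.
* **Wall fields** — constant-vector (TAWSS = A, OSI = 0), zero-mean
  oscillatory (TAWSS = 2A/π, OSI = 0.5), and Poiseuille-scaled
  (τ_w = 4μQ/(πR³)) patterns with closed-form ground truth.

What the generator does **not** emulate: image-intensity formation, phase
wrapping, eddy-current offsets, wall compliance, segmentation artifacts,
or real junction anatomy (the fillet is cosmetic). Passing tests therefore
demonstrate correctness of the measurement machinery on idealized
vessels; they do not validate segmentation or acquisition steps.

## Problem sizes

Default test and acceptance runs use reduced problem sizes chosen to keep
the whole suite comfortably under a minute of compute per stage: cohort
sweeps at 16–32 circumferential samples, five-model cohorts, and
12–16 mm trunk diameters for template cohorts. The defaults for actual
use (64 circumferential samples, 0.5 mm sweep step, 1 mm template grid)
are the resolutions at which the discretization errors quoted above were
measured.

## Known limitations

* No Navier–Stokes solver: wall-shear inputs come from files or the
  synthetic generator; absolute cohort TAWSS magnitudes from CFD are out
  of scope.
* Out-of-plane angles are convention-relative (see above); comparing them
  across software requires matching the plane definition.
* The origin-detection surrogate approximates, but does not reproduce,
  centerline-tree branch-splitting definitions from other toolkits;
  agreement is within one local radius on generated geometries.
* Torsion on noisy centerlines is sensitive to the smoothing budget; its
  cohort statistics should be read qualitatively.
* The voxel-flow loader infers pixel area from coordinate spacing and
  assumes a constant voxel set across frames.
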