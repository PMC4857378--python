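# Methods

## Measurement model

A subject (or calibration object) stands on a platform rotating at constant
angular speed ω (default 0.7 rpm) while a fixed camera films at a constant
frame rate (default 30 Hz). Every frame is a 2D central projection of the
scene; only structures lying in the plane through the rotation axis parallel
to the image plane are measured at true scale. A structure at angular
offset φ from that plane is foreshortened by ≈ |cos φ| (exactly |cos φ| in
the orthographic limit; the pinhole model adds a perspective correction of
order (L/2D)², with L the structure size and D the camera distance).

The package therefore treats a posture measurement not as one number but
as a *series*: many frames near the target orientation are selected,
measured independently, and aggregated. The mean suppresses zero-mean
annotation jitter by 1/√n and averages the (one-sided) foreshortening bias
over the selection window; the accumulated-CV analysis (below) decides how
large n must be.

## Calibration

Marked fiducial points on a calibration support give pixel→world
correspondences (u, v) → (x, y) in centimetres. The fitted map is

    world = A · pixel + t

- **Affine** (6 parameters; default with ≥ 3 non-collinear marks), solved
  by orthogonal-decomposition least squares on world-space residuals. The
  affine family is the weakest that accommodates camera tilt, non-square
  sampling and independent axis scales — and, importantly, the vertical
  flip between image coordinates (v down) and world coordinates (y up).
- **Similarity** (rotation + isotropic scale + translation, 4 parameters;
  used with exactly 2 marks or on request), solved as a complex linear
  regression w = a·z + b. This family is orientation-preserving: it cannot
  absorb a mirrored axis convention, so it should only be used when the
  marked world axes follow the image orientation.

Degenerate inputs are rejected up front: fewer than 2 marks, duplicate
pixel points, and (for affine) collinear pixel marks, detected scale-freely
as smallest/largest singular value of the centred pixel matrix < 1e-8.
Model invertibility is enforced at construction, so applying the map and
its inverse never fails downstream. `residual_rms` is the root mean square
world-space residual over the marks (cm); on noise-free correspondences it
is < 1e-9, and it grows with annotation noise, giving the operator a direct
calibration-quality readout.

## Curvature index and frame metrics

For a spinal curve bounded by its limit vertebrae U and L with apex A:
x = |UL|, f = perpendicular distance from A to the *infinite line* UL
(computed as twice the triangle area over the base), CI = 100·f/x. The
infinite-line convention is the standard "arrow" of flexicurve-style
indices; for realistic anatomy the apex projects inside the chord, where
line and segment distances coincide. A `clamp_to_segment` flag is provided
for degenerate configurations. CI is dimensionless and invariant under
rigid motion and uniform scaling, so it is insensitive to calibration scale
and subject distance.

Angles are unsigned interior angles in [0°, 180°] from the normalised dot
product (clinical convention); areas are absolute shoelace areas. Metric
values carry no rounding internally — rounding happens only in reporting.

A frame measurement maps each landmark through the calibration and
evaluates every metric of the protocol; a metric whose landmarks are absent
from the frame is flagged as missing, never silently dropped, and the
aggregation stage skips and counts such frames per metric.

## Accumulated statistics and the repetition number

For values v₁…vₙ and each k ≤ n:

- X̄_accum(k) = mean of v₁…v_k (full precision),
- σ_accum(k) = **sample SD of the running means** X̄_accum(1)…X̄_accum(k)
  (denominator k−1; defined 0 at k = 1),
- CV_accum(k) = 100 · σ_accum(k) / X̄_accum(k).

σ_accum deliberately measures the dispersion of the *estimates*, not of the
raw values: it quantifies how much the averaged result is still moving as
frames accrue, which is the quantity a stabilization criterion should watch.
This definition reproduces the reference validation table's accumulated
cells (e.g. width: 0.025 at k=4, 0.050 at k=5, 0.062 at k=10), which no
raw-value SD does.

Summary statistics use the sample SD (n−1); the reference table's bottom
row (width SD 0.22) matches n−1 (0.216) and not n (0.212).

**Rounding policies.** The `"printed-table"` policy (default) forms CV from
mean and SD each rounded **half-up** to 2 decimals first — the convention
under which published tables of this kind are computed — while `"exact"`
uses full precision. Half-up matters: banker's rounding breaks several
reference cells. The two policies agree within 0.05 CV percentage points
on the reference data. Individual printed CV cells of the reference table
mix precisions (some one-decimal, two cells three-decimal) and cannot all
be reproduced by any single convention; the package recomputes everything
from the raw per-frame values and asserts only the self-consistent cells.

**Stabilization rules.**

- `terminal-plateau` (default): k_stable is the smallest k ≥ 2 such that
  CV_accum rounded to 2 decimals is identical from k through the final
  frame. On the reference height series this yields k = 26, matching the
  published repetition number; the width series reaches its terminal
  plateau much earlier (k = 11 under the default policy). The published
  width figure of 18 follows from no recoverable criterion and is treated
  as an open discrepancy, not a target.
- `delta-threshold(ε, w)`: smallest k whose CV range over the full window
  [k, k+w] is ≤ ε; returns a not-stabilized flag when no complete window
  qualifies.

Percent error is the literal 100·|measured − truth|/|truth|. Against the
known rectangle this gives 0.048 % (width) and 0.080 % (height) for the
aggregated means — comfortably inside the instrument's claimed <1 %
accuracy. (Narrative error figures of "about 1 % / 0.3 %" quoted alongside
the reference data follow from no computation on the printed values and are
not reproduced.)

## Turntable simulator

Scene: named 3D landmarks in a body frame (origin on the rotation axis at
platform height, Y up, +Z toward the camera at platform angle 0°,
angles increasing counter-clockwise seen from above, 90° = right profile).
Camera: pinhole at distance D on the axis' +Z normal, horizontal optical
axis, principal point at image centre, square pixels — the minimal model
that produces perspective foreshortening. Platform speed uses 0.7 rpm (the
instrument's stated speed; the alternative "one turn per 1.5 min" phrasing
≈ 0.667 rpm is inconsistent with it and not used). Frames are generated at
the camera frame rate, so one revolution at defaults yields
floor(30·60/0.7) = 2571 frames. Annotation error is modelled as isotropic
Gaussian pixel jitter from a seeded generator; identical scene + seed gives
bitwise-identical output. Landmarks whose rotated depth falls behind the
axis plane are dropped — a simple half-space stand-in for body
self-occlusion, adequate for frame-selection logic but not a soft-tissue
visibility model.

The known-rectangle generator places a width × height rectangle parallel to
the image plane (its projection is then an exact uniform scaling, so the
noise-free case must be recovered exactly — a sharp end-to-end test), with
the lower edge 150 cm above the platform base and default magnification
1 px/cm, and returns frames, calibration marks taken from the noise-free
corner projections, and the ground truth.

### What the simulator does and does not emulate

It emulates the acquisition geometry (rotation, perspective projection,
frame timing), annotation jitter, and far-side landmark loss. It does not
emulate postural sway, soft-tissue artefact, lens distortion, lighting or
marker-detection failure. Passing tests therefore demonstrate correctness
of the geometry and statistics pipeline and the *mechanism* of multi-frame
error reduction — not the magnitude of errors to expect on real subjects,
where subject motion dominates (the reference data's subject-series CVs are
an order of magnitude above the rigid-object CVs for exactly that reason).

## Numerical choices and problem sizes

- Least squares via `numpy.linalg.lstsq` (SVD); contractually matches the
  normal-equations solution to 1e-9 on well-conditioned inputs (tested).
- Collinearity/duplicate tolerance 1e-8, scale-free (singular-value ratio,
  pairwise-distance ratio).
- Round-half-up implemented with `decimal` on the shortest float repr.
- Angle cosines clipped to [−1, 1] before `acos`.
- Circular angle distance for frame selection; ties broken by earlier
  frame index.
- Test problem sizes: series of ≤ 40 values for statistics oracles, one
  simulated revolution (2571 frames, one landmark) for timing-sensitive
  checks, 30-frame fixtures for end-to-end recovery, 40 000 Monte-Carlo
  samples for the area oracle — all chosen to keep the full suite in the
  low seconds while leaving no code path untested.

## Known limitations

- 2D single-camera calibration only; no lens-distortion or multi-camera
  3D reconstruction.
- Landmarks are taken as given; no automatic detection or soft-tissue
  artifact correction.
- The stabilization literature offers several stopping rules; the
  terminal-plateau rule is the one that reproduces the reference
  repetition number, but it depends on the rounding granularity (its
  `decimals` parameter) and, like any plateau rule, returns the trivial
  k = n when the CV is still drifting at the end of the series — inspect
  `cv_series` before trusting a late k_stable.
- "Probabilistic density" reporting and inter-rater statistics are out of
  scope.
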