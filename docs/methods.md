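# Methods

## Rig model and coordinate frames

The camera model is a 640×480 pinhole (default focal length 525 px, a
typical structured-light value; any value consistent with the frustum
works) mounted 0.6 m above the table with its optical axis tilted 45° down
at the surface, reporting depth along the optical axis in millimetres over
a 500–3000 mm working range.  Depth is metric throughout; the sensor's
11-bit resolution is modelled as optional uniform quantization of the
working range into 2048 levels (step ≈ 1.2 mm), not as raw disparity —
the pipeline consumes metric depth and disparity conversion is a sensor
detail.

Two frames are fixed once, in `camera_geometry`:

* camera frame — x right, y down, z along the optical axis;
* table frame — z up, x along the table edge nearest the camera
  (parallel to camera x), y away from the camera.

The camera→table rotation is parameterized by the tilt angle θ and
satisfies the defining contract that every table-surface point maps to a
constant height z; the contract, not a printed matrix, is what the tests
pin down.  Any table point may serve as origin; the pipeline uses the
centroid of the detected plane's inliers.  The named anatomical projection
planes are derived from azimuth/elevation angles through the spherical
construction `(cos el · sin az, cos el · cos az, sin el)`, which maps
transverse (0°, 90°) to the vertical axis and frontal (90°, 0°) /
sagittal (0°, 0°) to the two horizontal axes; in-plane coordinates use an
orthonormal basis from the singular decomposition of the normal, so
projection is an isometry for in-plane points.

## Synthetic scenes

The simulator ray-casts analytic surfaces — the finite table rectangle,
spheres, oriented boxes, vertical cylinders, and a mug modelled as a
cylinder with a box handle — so every depth value has a closed form and
ground truth is exact by construction.  The arm is a horizontal forearm
slab crossing the right table edge, ending in a thin planar hand paddle
(175 × 90 × 6 mm; an open hand is well approximated by a plane, which is
all the orientation estimator assumes).  The paddle pose is pronation
about the forearm axis followed by flexion about the wrist axis; positive
pronation turns the palm toward the camera, positive flexion sends the
fingertips toward the table.  The ground-truth hand reference point is the
metacarpophalangeal region at 60% of the hand length from the wrist — the
centre of the grasp, which is also what the tracker's median-hand-pixel
reference estimates.

Sensor emulation adds i.i.d. Gaussian depth noise (σ = 3 mm at the study
conditions), clamps to the working range (out-of-range → invalid 0) and
optionally applies the 11-bit quantization.  Color is flat-shaded and
noise-free; segmentation robustness to color texture is governed by the
deviation threshold and is exercised through the threshold tradeoff, not
through photometric noise.  An optional shadow decal darkens the table in
an ellipse behind an object's far base — reaching past the object's own
occlusion border so a visible ribbon merges with the segmented mask — to
exercise the shadow-exclusion rule; no IR shadow physics is modelled.

What the simulator does **not** emulate, and hence what green tests do not
show about real data: real depth cameras have range-dependent,
surface-angle-dependent noise and holes around depth discontinuities;
RGB-D registration has residual parallax; real tables have texture, and
real objects specularities and color gradients.  The pipeline's thresholds
are chosen to be generous against these effects, but the synthetic
evaluation measures algorithmic correctness, not sensor robustness.

### Evaluation test set

`generate_test_set` draws scenes whose analytically correct grasp matches
a requested per-class count (the evaluation composition is 42 lateral /
17 palmar / 19 pinch / 6 spherical).  Object archetypes follow the
household objects of the four classes, one object per scene:

* lateral — pencils/spoons (thin boxes 120–180 × 6–14 × 6–14 mm) and
  mugs with the handle toward the hand side (radius 35–45, height 90–120,
  handle 35–50 × 16–24 mm, yaw within ±40° of the hand side);
* palmar — bottles (radius 30–45, height 180–260), CD cases standing on
  edge (120–140 × 8–14 × 120–140), and mugs with the handle turned away;
* pinch — phones/key fobs (flat boxes, width 0.5–0.85 of a 90–140 mm
  length, height 8–18) and flat discs (radius 55–65, height 6–10);
* spherical — balls of radius 28–42 mm.

Dimension ranges keep a margin to the classifier thresholds so the labels
are unambiguous; positions are sampled inside the frustum with taller
objects placed nearer the camera so their tops stay in view.  About 30% of
the larger objects carry the shadow decal.  Everything is deterministic
given the generator seed.

## Plane detection and background

RANSAC samples 200 point triplets (default), models a plane from each and
keeps the candidate with the most inliers at a 10 mm distance threshold;
the winner is polished by a total-least-squares refit on its inliers and
ties break toward the lowest candidate index for reproducibility.  Inlier
scoring uses a fixed random subsample of at most 6000 points — scoring is
a counting estimate and does not need every pixel — while the final inlier
set and mask are computed on the full cloud.  The clustered variant first
groups candidate normals by greedy angular agglomeration (5° cone,
sign-blind, each candidate joining the first matching cluster) and scores
only the largest cluster's members; with a dominant plane this returns the
same plane at a fraction of the inlier evaluations.  Defaults were chosen
so that a table covering ≥60% of the frame is detected essentially always
at σ ≤ 5 mm.

The background image (BCG) averages the first `N = 15` frames (the
10–20 range is the sensible envelope; 15 is the middle).  Per frame, the
plane's inliers form the table mask, holes inside it (on-table objects or
invalid pixels) are padded with the plane's analytic depth along each
pixel ray, and the padded frames are averaged; the final plane is refit on
inliers pooled across frames.  A frame whose dominant plane holds less
than half the valid pixels is rejected ("no dominant plane").

## Hand tracking

Edges come from a Sobel magnitude threshold at 3% of the frame maximum:
low enough to catch the ≈50 mm depth step of a hand hovering near the
table at extreme pronation, while staying roughly an order of magnitude
above the σ = 3 mm noise floor.  The BCG's two longest edge chains
(8-connected components) are fitted with total-least-squares lines.  Gap
search samples each line over its chain extent, marks positions with no
frame edge within 2 px, closes sub-9-px interruptions (the arm's own
silhouette edges crossing the line), and verifies candidate runs of ≥8 px
by requiring the frame to be ≥30 mm nearer than the BCG at the gap centre.
With gaps on both edges, the nearer (to-camera) one wins.

The arm primitive is the 4-connected flood-fill component of the non-edge
image seeded at the gap centre (4-connectivity leaks less across 1-px
diagonal edge gaps), grown back by one pixel to recover the silhouette
ring the edges occupy, and rejected if it floods more than half the frame.
The start point is the arm point on the off-table side of the crossed edge
— decided by horizontal position against the 3D edge line, since image
space is distorted by the parallax of an arm hovering above the table —
farthest from that line; the fingertip is the arm point farthest from the
start (ties toward the lowest pixel index); hand pixels lie within 120 mm
of the fingertip (adult hand length; configurable); the reference point is
the hand pixel nearest the coordinate-wise median of the hand points.

Orientation: a RANSAC plane through the hand points gives the hand normal
(oriented upward).  The spatial angle is the angle to the table normal.
Pronation is the signed angle of the normal's projection onto the frontal
plane against the vertical.  Flexion is the signed angle between the
hand's principal axis and the forearm axis, both projected on the sagittal
plane — with the forearm axis estimated from the forearm points (arm minus
hand) so a flexed hand does not drag its own reference axis.  Flexion is
physically observable only while the fingertips stay clear of the table
(roughly −40°…+15° for the default arm height); beyond that the depth
step under the fingertips vanishes below any reasonable edge threshold.
The orientation budget is 15°; the synthetic sweep measures ≈2° worst
case, leaving the budget to absorb real-sensor effects.

## Object extraction

The table color template is the channel-wise median of all pixels (valid
while the table covers >50% of the image).  The table mask is the set of
pixels within 30 intensity units of the template in every channel (L∞;
the simplest faithful reading of a per-channel deviation range); objects
are the connected components (8-connected, ≥20 px) of the filled-minus-
unfilled table mask.  Target selection takes the largest mask, or the mask
whose 3D centroid is nearest the hand reference point under the
`closest_to_hand` policy.

The 3D primitive back-projects the mask, moves to the table frame and
drops points with z ≤ 10 mm (above the noise, below the 4 cm height gate)
— the shadow margin that removes decal/real shadows attached by
segmentation.  Footprint axes are the equivalent-second-moment ellipse
(4·√eigenvalues of the coordinate covariance) of the **region** covered by
the transverse projection: the raw surface points oversample silhouette
rims (pixel density piles up where a surface turns away from the camera),
so the projection is rasterized at 2 mm, closed and filled before taking
moments.  Under depth noise the region's extent grows by roughly the
transverse noise spread (≈2σ·sin θ per side); the classifier's relative
thresholds absorb this.  Objects flatter than the shadow margin raise a
flat-object error and fall back to a metric 2D route: the mask is
projected through the camera onto the table plane (a homography) and
measured there — exact for flat objects and free of image-space
foreshortening, which would otherwise bend the Rule-1 ratio by up to
±30% with orientation.  Height is a robust upper percentile of z (99th;
98th of the raw points on the 2D route), trading a ≤1σ bias for outlier
immunity.

## Grasp classification

The decision sequence: height gate at 40 mm → small objects by Rule 1
(elongation `(major − minor)/major > 0.60` → lateral, else pinch) → large
objects by Rule 2 (spherical) then Rule 3 (handle side).  The elongation
reading is the only scale-free, [0, 1]-bounded interpretation of an axis
"difference in length" ratio, and it makes the spec'd boundary cases
(pencil 0.93+, phone 0.5, disc ≈0) come out right.

Rule 2 measures roundness on the *image silhouette*, not on the 3D
transverse footprint: a ball's visible surface projected to the horizontal
plane is a truncated cap (≈15% elongated) while its silhouette is a
circle.  Two refinements make the silhouette reading robust:

* the mask is rectified by a gnomonic projection about its central viewing
  ray before taking ellipse moments, cancelling the off-axis perspective
  distortion that would make a corner ball's silhouette up to ~8%
  elliptical;
* spherical additionally requires silhouette convex-solidity ≥ 0.95 and
  height within 25% of the footprint diameter.  The solidity gate exists
  because a mug whose handle widens the silhouette by just the amount of
  its vertical elongation can reach near-isotropic second moments
  (observed elongation 0.02–0.05) — but its silhouette is visibly
  non-convex (solidity ≤ 0.92 vs ≈ 0.975 for balls).  The height gate
  keeps upright cylinders (bottles), whose top disc yields a circular
  footprint, out of the spherical class.

Handle detection rasterizes the transverse footprint (4 mm cells), closes
and fills it, and opens with a disc whose radius is 0.55× the body's
maximum inscribed-disc radius (from the distance transform).  What the
opening removes, if it is a single component of ≥3% of the body area, is
the handle; its side is the sign of its centroid offset from the body
centroid along the table-edge axis.  Scaling the disc to the inscribed
radius rather than the footprint's minor ellipse axis matters: the handle
itself deflates the minor axis, which would leave the disc too small to
remove the handle it is meant to find.  Two guards: a body whose inscribed
radius is under 15 mm (a thin slab on edge) cannot bear a handle, and an
opening that erases ≥75% of the footprint means the object is thin and
handleless.

Apertures add a 20 mm clearance to the relevant span (minor axis for
palmar/pinch, handle span for a handle-borne lateral, diameter for
spherical); palmar decisions carry the major footprint axis for aligning
the hand during prehension.

## Stimulation control

A three-phase state machine at 10 Hz (matching a ≈100 ms perception
cycle): IDLE → REACH on hand + decision (emit `open_<grasp>` with aperture
and orientation targets each tick) → trigger `close_<grasp>` at the first
tick within 50 mm of the object → HOLD for the per-object hold time
(default 3 s) → `release` → IDLE, restarting the loop.  Losing the hand
for >1 s during the reach reverts to IDLE with a neutral `idle` command —
a release pattern is only ever emitted after a close, an invariant the
fuzz tests enforce.  The transport is an in-process JSONL logger; real
stimulator hardware, electrode-pad patterns and the aperture→amplitude
mapping live behind it and are out of scope.

## Problem sizes and numerical choices

The synthetic evaluation runs 84-scene test sets (the per-class
composition 42/17/19/6) over five generator seeds with one background
session per seed — mirroring deployment, where the BCG is recorded once
per session and objects are swapped on the same table.  The orientation
sweep covers −80°…+80° pronation in 10° steps with 10 seeds per pose.
These sizes give stable pooled estimates (n = 420 and n = 170) at a few
minutes of CPU.

Degenerate inputs are contracts, not crashes with stack traces: fewer than
three non-collinear points → "no plane"; a dominant plane under 50% of
valid pixels → "no dominant plane"; fewer than two BCG edge chains →
"table edges not found"; a flood fill covering half the frame → "edge
leak"; an all-shadow-filtered object → flat-object fallback; no segmented
object → the explicit "no object detected" outcome.  All randomized
stages are seeded and tie-breaks are deterministic (lowest index), so
identical inputs give bit-identical outputs.

## Known limitations

* Only right-edge arm entry is modelled (camera lateral to the tracked
  arm); left entry is a mirror the simulator does not currently render.
* Flexion is reported but only trustworthy in its observable range (see
  above); the orientation claim is carried by the spatial angle and
  pronation.
* The color route requires objects to differ from the table color by more
  than the deviation threshold in at least one channel; a table-colored
  object is invisible by construction.
* Rule 2's solidity and height gates are extensions of the bare ellipse
  rule; squat non-handled cylinders with height ≈ diameter would still
  read as spherical.
* The mug handle must subtend a clear left/right offset; a handle pointing
  straight at or away from the camera is unreliable to lateralize (and,
  pointing away, often invisible) — such poses read as palmar, which is
  the safe grasp for a mug body.
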