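# Methods

## The measurement problem

Gait symmetry — how alike the left and right halves of the body move during
walking — is a standard clinical indicator for lower-limb pathology, stroke
recovery, leg-length discrepancy and post-surgical rehabilitation.
`gaitsym` measures it from a single frontal-view depth camera watching a
subject walk on a treadmill, with no markers, no skeleton fitting and no
gait-cycle detection.

## Pipeline

1. **Reprojection.** Each depth frame's body pixels (u, v, d) are
   back-projected through the pinhole model to camera-space points
   x = (u − cx)·d/fx, y = −(v − cy)·d/fy, z = d. The y term is negated so
   the camera frame has y up and z pointing from the camera to the subject.
   The sign of x carries no anatomical meaning: every comparison below is
   left-versus-right within this one convention.

2. **Surface normals.** For every point, the neighbors within a metric
   radius (default 0.03 m, closed ball, self included) are gathered with a
   KD-tree; the normal is the eigenvector of the neighborhood's population
   covariance with the smallest eigenvalue. Normals are oriented toward the
   camera (z ≤ 0). Points with fewer than 3 neighbors, or whose two
   smallest eigenvalues are relatively tied (gap < 1e−9 of the largest
   eigenvalue), have no identifiable normal and are skipped downstream
   rather than zero-filled. The small radius is deliberate: robustness
   comes from the next step's accumulation, not from smoothing.

3. **Region accumulation.** The tight pixel bounding box of the silhouette
   is split at its arithmetic midlines into a 2×2 grid (midline pixels go
   to the left/top cell); the valid unit normals of each cell are summed
   into {v_TL, v_TR, v_BL, v_BR}. This normalizes clouds of varying size
   to a fixed-length descriptor and averages out per-point noise.

4. **Anatomical-plane angles.** Left and right accumulated vectors are
   compared after projection onto each anatomical plane:
   - transverse: û = (x, 0, z), right vector reflected about +z;
   - sagittal:   û = (0, y, z), no reflection;
   - coronal:    û = (x, y, 0), right vector reflected about +y.
   Each comparison is arccos of the clamped cosine, in [0, π]; a perfectly
   mirror-symmetric posture scores 0 in the transverse and coronal planes
   and 0 in the sagittal plane (equal left/right pitch). The per-frame
   index per plane is the top-pair angle plus the bottom-pair angle
   (bottom only in lower-body mode).

5. **Temporal schemes.** For a sequence of n frames:
   - frame-based: I_f = (1/n) Σᵢ I(vᵢ) — mean of per-frame angles;
   - segment-based: I_s = I((1/n) Σᵢ vᵢ) — one angle of the mean posture.
   The segment-based index is near zero for any symmetric gait, no matter
   how asymmetric each instantaneous stride snapshot is, because
   left-leg-forward and right-leg-forward postures cancel in the vector
   mean; this makes it the better detector, which the evaluation
   reproduces directionally.
   - combined: I = w_t·I_t + w_s·I_s + w_c·I_c with each plane's weight the
     population variance of that plane's (segment-based) index over
     *normal-gait* training sequences — variance as a measure of how much
     information a plane carries. Weights are used unnormalized; ROC
     analysis is invariant to positive rescaling.

No gait-cycle segmentation is performed anywhere: a sequence is whatever
frame window is supplied. Two seconds or more is recommended so the mean
posture covers at least one full stride; windows that cover whole strides
give the cleanest segment-based nulls.

## Evaluation

Sequences are labelled normal/abnormal and scored; separation is measured
as ROC AUC with abnormal positive (equivalently the Mann–Whitney
statistic, ties counted half). Two schemes: *all-subjects* pools every raw
score into one ROC; *leave-one-out* computes an AUC per held-out subject
(its 1 normal vs 8 abnormal sequences — high-variance by construction,
since one class has a single sample) and averages. Combination weights are
always fitted on the training subjects' normal sequences only, never on
the held-out subject. The 12 basic processing flows are
{frame, segment} × {transverse, sagittal, coronal} × {full, lower body};
combined flows cover every nonempty plane subset via zero weights.

## Synthetic data

The simulator emulates a treadmill depth-gait lab: a level camera 1.7 m
above the floor, subject 2.3 m away, 13 fps, Kinect-2-like intrinsics
(512×424, fx = fy = 365 px). The body is a torso ellipsoid, head sphere,
cylinder arms and legs, and foot ellipsoids, with sinusoidal limb swing at
the stride cadence (default 1.0 strides/s — a typical treadmill rate,
chosen so a 13-frame second covers exactly one stride), contralateral
arm/leg pairs in antiphase, and a constant 8° forward leg flexion (flexed
knees/shins give the lower body a stable vertical normal component, as
real legs do). Surfaces are sampled on deterministic parametric grids at
~0.7 pixel footprint, projected, and z-buffered per pixel (nearest wins;
depth ties go to the first-rendered primitive, torso first). i.i.d.
Gaussian depth noise (default sd 5 mm, time-of-flight-like) is added to
rendered pixels. The mask is exactly the rendered pixels, so segmentation
is perfect by construction — the method under study begins after
segmentation, and no treadmill or background is rendered.

Two induced asymmetries mirror the usual induced-pathology protocols:

- **Lateral tilt** (sole padding): the whole body rolls about the depth
  axis through the hips; benchmark levels ±4° and ±8°.
- **Leg asymmetry** (ankle weight): the loaded leg's swing amplitude is
  scaled by 1 − |a|, its phase lags by |a|·π/8, and its mean position
  shifts backward by 0.35·|a| rad — the unequal speed *and* displacement
  of a weighted leg. The displacement term matters: amplitude and phase
  changes alone average out of the mean posture entirely and would leave
  the segment-based index blind to this family. Benchmark levels ±0.15
  and ±0.30.

The benchmark mirrors a 9-subjects × 9-gaits acquisition: per
pseudo-subject (stature 1.54–1.86 m, width ±10%, cadence 0.9–1.1
strides/s, all drawn from the seed) one normal walk plus the 8 abnormal
ones, 200 frames each. The benchmark camera runs at half resolution
(256×212, same field of view), which quarters the pixel count per frame
and keeps the full 81-sequence evaluation at desk scale; geometry, noise
level and every downstream statistic are unaffected in kind.

### What the simulator does and does not capture

It reproduces the geometry the method relies on: camera-facing surfaces,
perspective (the forward leg projects larger — per-frame silhouettes are
*not* mirror-symmetric mid-stride, which is exactly why the frame-based
index is nonzero during strides), occlusion, depth noise, and
whole-stride periodicity. It does not render clothing, soft tissue, hair,
treadmill furniture, or Kinect-specific artifacts (flying pixels, edge
dropout), and its segmentation is noiseless. Passing tests therefore
demonstrate the correctness and the qualitative orderings of the method —
segment-based over frame-based, full body over lower body, monotone
response to tilt — not the AUC values any particular real sensor would
achieve. One geometric consequence of the emulated rig is faithful and
worth knowing: with a level camera at 1.7 m and the subject at 2.3 m, the
vertical field of view ends ~0.36 m above the floor, so feet and ankles
are clipped in every frame; the "lower body" cells mostly see thighs and
shins.

## Numerical choices

- Depth is metric (metres) throughout; PNG I/O converts via `unit_scale`
  (default 1 mm units). Invalid (zero) depth pixels are dropped before
  reprojection.
- Box segmentation uses half-open bounds [min, max) — deterministic at
  boundaries.
- arccos arguments are clamped to [−1, 1]; projected vectors shorter than
  1e−12 raise a degenerate-feature error, and such frames are dropped from
  the frame-based mean with a warning rather than scored 0 (a zero would
  fake symmetry).
- Eigen-ties: a relative gap below 1e−9 between the two smallest
  covariance eigenvalues marks the normal unidentifiable.
- Normals with exactly zero z keep a fixed sign convention (first nonzero
  of x, y positive) purely for reproducibility.
- The simulator reduces stride phase modulo one cycle before evaluating
  the kinematics so that whole-cycle frames repeat bitwise.
- Rendering rounds to pixels via floor(u + 0.5) with integer principal
  points, keeping rasterization mirror-consistent.

## Known limitations

- The 2×2 grid is the coarsest useful resolution; per-limb decomposition
  is out of scope.
- The per-subject leave-one-out AUC rests on a single normal sequence per
  subject and is accordingly noisy.
- The frame-based scheme's polarity can invert on gaits whose asymmetry
  *reduces* instantaneous swing (a damped leg lowers the per-frame mean);
  the segment-based scheme does not share this failure mode and is the
  recommended default.
- Real-data effects absent from the simulator (clothing, segmentation
  bleed, sensor-specific noise) must be expected to lower separation
  relative to the synthetic benchmark.
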