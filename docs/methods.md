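# Methods

## Problem and data model

The package estimates the three-dimensional shape of the spine — a curve
represented by 10 ordered points, the topmost anchored at the vertebra
prominens (C7) — from the readings of three accelerometers mounted on an
elastic strip worn along the back. A motion-capture system tracking ten
retro-reflective markers on the same strip provides the ground truth. All
positions are in millimetres in a right-handed frame with x = right,
y = up, z = forward; accelerometer readings are in units of g; time is in
seconds.

The estimation chain is:

1. **Mocap processing.** Frames in which any marker is invisible are
   eliminated. Within each surviving frame the markers arrive unordered;
   they are sorted by nearest-neighbour chaining, starting from the marker
   closest to the ground (minimal up-coordinate), each next marker being
   the nearest unused one, ties broken toward the lower original index.
   The origin is then moved to the first (lowest) marker, and positions
   are scaled anisotropically: right and forward axes divided by 50 mm,
   the up axis by 500 mm. Values beyond ±1 pass through unchanged.
2. **Synchronization.** The strip and the capture system run on
   independent clocks. Each mocap timestamp *t* is served by the IMU frame
   recorded at exactly *t* when one exists, otherwise by per-channel
   linear interpolation between the bracketing frames at *t₀* < *t* < *t₁*:
   IMU(t) = IMU(t₀) + (IMU(t₁) − IMU(t₀))·(t − t₀)/(t₁ − t₀). Targets
   outside the IMU record are dropped (default) or clamped.
3. **Regression.** A fully connected hourglass network 9 → 27 → 18 → 9 →
   18 → 27 (ReLU hidden, linear output, 1638 parameters) maps the nine
   accelerometer channels to the 27 normalized coordinates of markers
   2–10; marker 1 is the fixed origin. Training: mini-batch RMSprop,
   learning rate 1e-4, rho 0.9, momentum 0, batch 512, 250 epochs, mean
   squared error, per-epoch reshuffling. Whole sessions are assigned to
   train/validation/test at 50/25/25 % of frames by a greedy
   largest-deficit rule, so temporally adjacent frames never straddle a
   split boundary.
4. **Evaluation.** Signed component-wise errors (predicted − truth) in cm,
   aggregated per axis, per marker and overall (mean ± population SD over
   the 27 predicted components), plus mean Euclidean marker error in mm
   and normalized-unit MSE. Generalization across bodies is measured by
   participant holdout: one male and one female participant contribute no
   frames to any split part and are evaluated once, after training.
   The Cobb angle of a curve is the unsigned angle between its most and
   least tilted segments; segment tilt is the signed angle from the up
   axis in the coronal (right–up) projection (a `plane="3d"` variant uses
   full 3D angles). Tilt of a point is realized as the tilt of the
   forward-difference segment starting at that point, since a point alone
   has no tangent. The angle is invariant to translation, uniform scaling
   and sagittal reflection.

## Synthetic data generator

No recordings ship with the package; a simulator generates statistically
comparable sessions so that every stage is testable offline.

**Strip kinematics.** The strip is an inextensible chain of nine 50 mm
segments (10 markers, total span 450 mm). A trunk pose is parameterized by
sagittal flexion (+forward, −45…95°), coronal lateral bend (+left,
−60…60°), axial twist (−45…45°) and, for the second motion set, a
head-raise angle (0…90°) that undoes part of the flexion. The top
orientation is R = Rz(lateral)·Rx(flexion − head_raise)·Ry(twist); segment
*i* of the chain points along R(sᵢ·r)·ŷ, where r is the rotation vector of
R and sᵢ = i/(n−2) runs from 0 (vertical base) to 1 (full rotation at the
top). This is the simplest smooth model consistent with slow, steady
movement: inter-marker distances and total strip length are conserved
exactly, the tangent varies smoothly, and mirroring lateral (and twist)
reflects the curve across the sagittal plane exactly.

**Motion scripts.** Set 1 holds ten step poses — 90° flexion, −30°
extension, ±45° lateral bends, four flexion/extension × lateral
combinations (45°/±30° and −20°/±30°), and ±30° twists — with a return to
neutral stance between steps. Set 2 is a continuous sweep sequence
starting at 90° flexion bent 30° to the right, alternating lateral sweeps
with head raises of 22.5°, 30° and 45°, ending upright. The magnitudes of
the unquantified steps (maximal extension, combined bends, twists) are the
package's choice of realistic ranges within the pose bounds. Poses dwell
1.4 s and transition linearly over 1.4 s — a deliberately brisk pacing
that gives a 12-session default cohort (6 participants × both sets) of
about 58 000 mocap frames.

**Sampling.** Mocap frames are drawn at 120 Hz: chamber-centred positions
(random constant offset per session), Gaussian jitter of SD 0.5 mm, marker
rows permuted per frame (markers carry no identity), and with probability
0.02 a frame loses one or two markers. IMU frames are drawn at 100 Hz on a
phase-offset grid so the two streams never share timestamps. Under the
quasi-static assumption a noiseless accelerometer reads the unit gravity
reaction in its local frame — (0, 1, 0) g when upright; a sensor pitched
until its tangent is horizontal-forward reads (0, 0, −1) g, the gravity
reaction appearing along local −z because the sensor's forward axis then
points at the ground. Per-axis Gaussian noise of SD 0.02 g is added. The
three sensors sit 115, 320 and 440 mm from the strip top (the clinical
attachment offsets), reported bottom/middle/top.

**What the simulator does not model:** dynamic (non-gravitational)
acceleration, gyroscope or magnetometer channels, soft-tissue artefacts,
two-apex scoliotic shape priors, clock drift, and marker ghosting beyond
simple dropout. Passing tests on synthetic data therefore demonstrate that
the pipeline recovers curves whose information is genuinely present in
quasi-static gravity directions; they do not bound performance on real
recordings, where dynamic motion and tissue artefacts add error.

## Numerical and design choices

- **Initialization** is uniform Glorot with a recorded seed; biases start
  at zero. Any standard scheme converges to the same loss range under the
  250-epoch recipe.
- **Epoch budget.** The published recipe trains for 250 epochs, and the
  package keeps that number everywhere, including the desk-scale
  experiment. RMSprop's update magnitude is bounded by roughly the
  learning rate, so total parameter travel scales with
  lr × number of updates; at 1e-4 with batch 512 on a ~16k-frame training
  split, a budget much below 250 epochs cannot move the output biases the
  ~0.5–0.7 (normalized units) they need and the network stalls on its
  early plateau. At full budget the experiment still completes in well
  under a minute on one CPU.
- **RMSprop epsilon** is the conventional 1e-7, added outside the square
  root; it is recorded in the model metadata.
- **Inputs** are fed as raw accelerometer values in g — already O(1) —
  with no further standardization. Final-epoch weights are kept; no early
  stopping or best-epoch checkpointing.
- **Nearest-neighbour ordering** can fail on hairpin geometries where a
  non-adjacent marker comes closer than the next one. The poses reachable
  within the pose bounds keep adjacent spacing well below non-adjacent
  distances; as a guard, any ordered frame whose consecutive distances
  exceed 1.5× their median is flagged and dropped, and the count reported.
- **Ghost markers** (more than 10 detections) are treated as incomplete
  frames and eliminated, like frames with missing markers.
- **Normalization inversion** is exact to one ulp (divide-then-multiply
  rounding); tests assert machine precision rather than bitwise equality.
- **Session splitting** uses a greedy largest-deficit assignment over
  seed-shuffled sessions; with whole-session granularity the realized
  frame fractions typically land within a few points of 50/25/25.
- **Degenerate inputs**: zero-length curve segments make the Cobb angle
  undefined and raise; duplicate IMU timestamps raise before
  interpolation; an all-incomplete mocap stream returns empty with a
  warning rather than raising.

## Scale of the shipped experiments

The default experiment — 12 sessions, ~58 000 frames, noise 0.02 g, one
male and one female participant held out, full 250-epoch recipe — is
sized to run in seconds on a single CPU while leaving the held-out
reconstruction error (~5 mm mean marker error, |bias| well under 1 mm)
an order of magnitude inside the package's 10 mm acceptance bar. The
real study's dataset is ~8× larger; the reader and pipeline accept it
unchanged (see the dataset integrity helpers), but it is not downloaded
or bundled.

## Known limitations

- The strip model has a single rotation-vector apex; real spines,
  especially scoliotic ones, can have two. Axial twist about the vertical
  axis moves neither markers nor gravity readings, mirroring the real
  system's blindness to orientation about gravity.
- Cobb angles from estimated curves use segment tilts of a 10-point
  polyline, not radiographic endplate orientations; agreement with X-ray
  Cobb angles on patients cannot be verified without the clinical
  coordinates.
- The CSV dialect is the package's own; the public dataset release may
  need the documented adapter in `stream_processing.load_dataset_dir`.
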