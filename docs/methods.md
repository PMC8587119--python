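# Methods

This note documents the models, conventions, and design choices behind
`myoadapt`: what is simulated, what is assumed, and where the genuinely open
decisions were made.

## Signal model and feature pipeline

**Acquisition model.** An 8-channel armband samples EMG at 200 Hz as 8-bit
signed integers (−128..127) and orientation quaternions at 50 Hz against a
space-fixed frame. The device is assumed to filter internally; no notch or
band-pass filtering is applied here.

**Segmentation.** Contiguous recordings are cut into 200 ms windows sliding
by 50 ms (40 samples, 10-sample increment at 200 Hz). Indices are 0-based
and windows are half-open `[start, start + win)`; a recording shorter than
one window is an explicit error. Windows never straddle recording
boundaries or the calibration retention cuts — each retained segment is
windowed independently.

**EMG features.** Per channel: mean absolute value, zero crossings,
slope-sign changes, waveform length. The zc/ssc deadzone threshold defaults
to 0: the raw signal is integer-quantized, so sub-LSB chatter cannot
produce spurious crossings, and the synthetic generator's noise floor is
explicit. Hardware users with analog front ends should raise it above their
noise floor (`SegmentationConfig.zc_ssc_threshold`).

**Orientation.** Euler angles use the intrinsic Z-Y-X (yaw-pitch-roll)
convention, fixed package-wide (`features.EULER_ORDER`), with the Y (pitch)
angle mapped to summed shoulder + elbow flexion. The convention is used
consistently by the generator and the decoder, so the system is
self-consistent; conversions round-trip to 1e-6 away from the pitch
singularity at ±π/2. Quaternions off unit norm by more than 1e-6 are
renormalized with a warning, and rejected above 1e-3.

**Fusion.** Each window carries one IMU feature: the circular mean of the X
Euler angles of all IMU samples whose timestamps fall in the half-open
window interval (EMG and IMU rates differ, so a window holds 0–10 IMU
samples; circular averaging avoids wrap artifacts). A window with no
in-window IMU sample reuses the last earlier orientation; a window before
any orientation exists is an error. The pose label is derived the same way
from the windowed mean Y angle.

**Pose bands.** Pose 1 for y < −π/3, pose 2 for −π/3 ≤ y < π/3, pose 3 for
y ≥ π/3. The lower bound of each band is inclusive, so y = −π/3 is pose 2
and y = +π/3 is pose 3; the three bands are disjoint and exhaust the axis.

## Classifier

Pooled-covariance LDA over the 33-dimensional fused space. Sufficient
statistics make training order-invariant; priors are the empirical class
frequencies of the training part (near-uniform by protocol design —
uniform vs empirical is not observably different here, empirical was
chosen). The pooled covariance uses the n − K denominator. If its smallest
eigenvalue falls below 1e-10 of the largest, a ridge λI with
λ = 1e-6 · trace(Σ)/d is added with a warning; prediction ties break toward
the earlier class in class order, deterministically. The top-2 generalized
eigenvectors of between- versus within-class scatter provide the 2-D
projection used for reduced feature maps; with only two classes a single
discriminant direction exists, and the second axis is padded with the
leading principal direction orthogonalized against it (with a warning).

**Reference selection.** Three *independent* random 3:1 splits (not a
partition-based cross-validation), stratified by motion class so every
class appears in every test part — stratification is required for
per-class sensitivity to be defined. Each split's model is scored by
macro-averaged (unweighted over classes) held-out sensitivity; the best
split wins, ties to the lowest split index. A split missing a class in its
test part is redrawn (up to 10 times). All randomness flows from one seed.

**Serialization** is a single versioned JSON document (class order, priors,
means, covariance, projection axes, training metadata); the model is small
(33 × 33), so a separate binary container is unnecessary.

## Screening and adaptation

Per-state (motion × pose) confusion counts are computed from the winning
split's held-out predictions — the screening reuses exactly the data that
selected the model, not a re-prediction of the full calibration set. A
state is flagged when sensitivity < 0.90 (strict) and precision ≥ 0.90
(non-strict), so a state at exactly 90/90 is healthy; the thresholds aim at
nine in ten correct executions. Undefined measures (zero denominators)
never flag a state: absence of evidence is not treated as evidence of
underrepresentation.

The majority-vote filter outputs, at each position, the modal label of the
trailing 5 decisions (2m + 1 with m = 2 decisions inside the 250 ms
acceptable actuation delay at the 50 ms decision period); the first
positions use the available prefix. Ties (2-2-1 over six classes is
possible) resolve to the tied label seen most recently, favoring the
current intent with bounded delay. A sample is *retained* only when its raw
prediction equals the voted label; unstable samples are discarded rather
than relabeled — discarding is the conservative reading of vote-based
post-processing, since a relabeled transition sample would import boundary
noise into the training set.

Adaptation is append-only: exactly the flagged cells' pool samples are
appended with their voted labels as ground truth; original calibration
rows are never altered or removed; a flagged state with an empty pool cell
is logged and skipped. The familiarization pool is consumed once (a single
adaptation event per session); forgetting factors, data deletion and
information-gain screening are out of scope. Retraining repeats the full
reference-selection procedure with the same configuration and seed policy.

## TAC-test simulator

A virtual hand with three DOFs — aperture (oh/ch), wrist rotation (wp/ws),
pinch (pg, no antagonist) — moves at `dof_speed` (default 40°/s) in the
direction mapped to each decoded class, one decision per 50 ms tick; rest
holds still. Free excursions clip at ±180°. The instructed target posture
is modeled as the displaced DOF's end stop (e.g. "fully open hand"), so
sustained correct activation parks the hand at the target; wrong-class
excursions on other DOFs must be corrected by antagonist activity. A trial
(distance 60°, allowance ±8°, dwell 1 s, timeout 15 s) completes at the
first instant every DOF has stayed continuously within the allowance for
the dwell time; completion time therefore includes the dwell and, for a
perfect decision stream, equals (D − W)/v + dwell = 2.3 s at defaults.
Selection time is the first tick decoding the target class. Completion-time
statistics cover completed trials only; selection-time statistics cover
trials in which the target class was ever decoded.

`dof_speed` is a simulator choice, not a measured constant: 40°/s makes a
perfect trial take ~2.3 s, the order of magnitude of realistic virtual
prosthesis use, and it is fully configurable.

## Synthetic world

The generator produces what the decoder consumes — amplitude statistics —
not physiological EMG (no motor-unit structure, no spectral shape, no
electrode-shift or fatigue dynamics). Per channel, EMG is zero-mean
Gaussian with standard deviation

σ(motion, channel) · M(pose, channel) · g(load) · effort(t),

quantized to the 8-bit range. Defaults: distinct per-motion channel
patterns (peak ≈ 24 counts), pose modulation ≈ 0.90/1.00/1.15 with a small
channel tilt, monotone load gains g = (1.0, 1.25, 1.4) for (0, 400, 600) g,
a rest/noise floor of σ = 3 counts, and a lognormal effort gain (σ = 0.25,
redrawn every 0.5 s) modeling trial-to-trial fluctuation of voluntary
effort — this is what gives feature clouds realistic width relative to
between-class distances. A configured amplitude hot enough to clip more
than 1% of samples warns; transient effort excursions clip silently, as
hardware would.

Orientation streams place the Y angle at band centers −1.3/0/+1.3 rad with
0.5 s cosine transitions and small jitter. The centers sit deep inside the
±π/3 decision bands but deliberately off ±π/2, which is the pitch-axis
singularity of the Z-Y-X convention; pushing the bands onto the gimbal lock
would make the conversion ill-conditioned for no modeling gain. Wrist
rotations add ±0.8 rad X offsets, which is what makes the X Euler angle an
informative fusion feature.

**Calibration protocol.** Per motion and repetition: a 10 s block with pose
commands every 2 s in the order 1-1-2-3-1 (pose 1 buffers reaction time at
both ends), the middle 6 s retained (first/last 20% cut), three repetitions
of six motions — 18 s of labeled data per class, 2106 feature windows at
the default segmentation. Inter-block rest pauses are not synthesized.

**Closed loop.** Familiarization and testing couple the generator, a
classifier and a scripted virtual user: each tick the user intends the
motion reducing the largest DOF error beyond the allowance (rest when all
are inside; a DOF without a corrective motion, like an overshot pinch, is
skipped), with a 3% per-tick intent-noise probability; the generator emits
50 ms of EMG/IMU for that intent; the decoder classifies the trailing
200 ms window; the decoded class moves the hand. Decisions before the first
full window default to rest. Familiarization runs one 5-target series per
pose × load combination (9 series, ≤ 675 s); testing runs three
baseline/adapted series pairs in randomized alternating order with the
load redrawn per pair and the pose varied per target (6 series, ≤ 450 s).

**Shift scenario.** `shifted_pose1_open_hand()` rescales the open-hand
pattern in pose 1 to 0.85 × amplitude and pulls it 75% of the way toward
the closed-hand pattern, in *every* phase — the world's (oh, pose 1)
distribution is the shifted one, which the pose-pooled calibration model
then underrepresents. The mix weight sits past the point where the shifted
cluster is closer to the competing class mean than to its own pose-pooled
mean, yielding partial misclassification (low sensitivity) while the
samples it does catch remain correct (high precision) — exactly the
flagging signature. Load gains push familiarization samples of the shifted
cell back toward the open-hand side, which is why self-labeled augmentation
recovers it.

## What passing tests do and do not show

The test suite demonstrates internal consistency (formulas against
brute-force oracles, determinism, protocol arithmetic) and that the
adaptation loop recovers a planted, amplitude-level distribution shift in a
Gaussian world. It does not demonstrate performance on physiological EMG:
real limb-position effects include spectral changes, electrode lift and
skin-impedance drift that the generator does not model, and sudden domain
shifts (electrode displacement, donning/doffing) are explicitly outside the
method's reach — self-labeling can only track distributions the reference
model still partially recognizes.

## Problem sizes and numerical choices

Default experiment and test sizes are desk-scale by design: one synthetic
subject's calibration is 2106 windows; the end-to-end recovery property
uses 20 seeded replicates of the full three-phase loop with 8 s per load of
fresh evaluation data per replicate. Seeds derive from a single
`SeedSequence` per experiment and stay below 2³¹. Float comparisons in the
TAC dwell logic use a 1e-9 tolerance so tick-grid arithmetic cannot drop a
dwell by rounding.
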