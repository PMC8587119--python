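"""Synthetic EMG/IMU sessions with class-, pose- and load-dependent structure.

The generator emulates what the adaptive decoder assumes about real
recordings, not muscle physiology: per channel, EMG is zero-mean Gaussian
with a standard deviation set by the motion's channel activation pattern,
modulated multiplicatively by limb pose and external load, quantized to the
8-bit acquisition range.  Orientation streams place the Y (pitch) Euler
angle in one of three bands matching the limb poses, with smooth 0.5 s
transitions and small jitter; wrist rotations add a per-motion X offset.
*Shift overrides* rescale a designated (motion, pose) cell, producing
exactly the kind of underrepresented state the adaptive learner targets.

The module also provides the three protocol phases end to end: a dynamic
calibration session (10 s per motion repetition with pose commands every
2 s, middle 6 s retained, 3 repetitions x 6 motions = 18 s labeled data per
class), closed-loop familiarization TAC series over all nine pose x load
combinations, and paired baseline-vs-adapted testing series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    ACTIVE_MOTIONS,
    EMG_MAX,
    EMG_MIN,
    EMG_RATE,
    IMU_RATE,
    LOADS,
    MOTIONS,
    N_CHANNELS,
    POSES,
)
from .features import (
    FEATURE_COLUMNS,
    PoseThresholds,
    SegmentationConfig,
    euler_to_quaternion,
    extract_emg_features,
    pose_label,
    quaternion_to_euler,
)
from .streams import EmgStream, ImuStream, SessionRecord
from .tac import TacConfig, TacResult, TacTrial, simulate_trial

#: Per-motion channel activation amplitudes (8-bit counts).  Patterns are
#: distinct across motions; rest uses the noise floor only.
DEFAULT_SIGMA: dict[str, np.ndarray] = {
    "oh": np.array([5.0, 20.0, 24.0, 21.0, 8.0, 5.0, 4.0, 4.0]),
    "ch": np.array([6.0, 5.0, 6.0, 8.0, 20.0, 24.0, 23.0, 10.0]),
    "wp": np.array([23.0, 18.0, 6.0, 4.0, 6.0, 10.0, 21.0, 8.0]),
    "ws": np.array([8.0, 6.0, 10.0, 23.0, 21.0, 6.0, 5.0, 18.0]),
    "pg": np.array([12.0, 17.0, 10.0, 6.0, 14.0, 18.0, 8.0, 23.0]),
}

_CH_TILT = np.cos(2 * np.pi * np.arange(N_CHANNELS) / N_CHANNELS)

#: Pose modulation of muscle recruitment, mildly channel dependent.
DEFAULT_POSE_MOD: dict[int, np.ndarray] = {
    1: 0.90 + 0.03 * _CH_TILT,
    2: np.ones(N_CHANNELS),
    3: 1.15 - 0.03 * _CH_TILT,
}

#: External-load gains: added weight recruits more muscle, monotonically.
DEFAULT_LOAD_GAIN: dict[int, float] = {0: 1.0, 400: 1.25, 600: 1.4}

#: Forearm X-rotation offsets (radians) — wrist rotations turn the device.
DEFAULT_X_OFFSET: dict[str, float] = {
    "oh": 0.0, "ch": 0.0, "wp": 0.8, "ws": -0.8, "pg": 0.0, "r": 0.0,
}

#: Y-Euler band centers per pose, deep inside the +-pi/3 decision bands and
#: clear of the pitch-axis singularity at +-pi/2.
DEFAULT_POSE_CENTER: dict[int, float] = {1: -1.3, 2: 0.0, 3: 1.3}


@dataclass(frozen=True)
class ShiftOverride:
    """Distribution shift of one (motion, pose) cell.

    The cell's channel pattern becomes
    ``gain * ((1 - mix_weight) * pattern(motion) + mix_weight * pattern(mix_with))``
    — an overall attenuation/amplification plus a pull toward another
    motion's activation, the signature of the limb position effect.
    """

    gain: float = 1.0
    mix_with: str | None = None
    mix_weight: float = 0.0


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic world.

    ``shift_overrides`` maps (motion, pose) to a :class:`ShiftOverride`
    applied to that cell in every protocol phase — the world's distribution
    for the cell is the shifted one, which the pose-pooled calibration model
    then underrepresents.
    """

    sigma: dict[str, np.ndarray] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    pose_mod: dict[int, np.ndarray] = field(default_factory=lambda: dict(DEFAULT_POSE_MOD))
    load_gain: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LOAD_GAIN))
    x_offset: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_X_OFFSET))
    pose_center: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_POSE_CENTER))
    noise_floor: float = 3.0
    effort_jitter: float = 0.25
    """Lognormal sigma of the slowly varying voluntary-effort gain: muscle
    activation fluctuates around the commanded level from one moment to the
    next, so windowed amplitude features form clouds rather than points.
    Applied to active motions only; the rest-class floor is electronic."""
    effort_interval_s: float = 0.5
    transition_s: float = 0.5
    y_jitter: float = 0.02
    x_jitter: float = 0.03
    z_jitter: float = 0.05
    intent_noise: float = 0.03
    shift_overrides: dict[tuple[str, int], ShiftOverride] = field(default_factory=dict)

    def _pattern(self, motion: str) -> np.ndarray:
        if motion == "r":
            return np.full(N_CHANNELS, self.noise_floor)
        return self.sigma[motion]

    def channel_std(self, motion: str, pose: int, load: int) -> np.ndarray:
        """Per-channel EMG standard deviation for one state."""
        base = self._pattern(motion)
        over = self.shift_overrides.get((motion, pose))
        if over is not None:
            if over.mix_with is not None:
                base = (1 - over.mix_weight) * base + over.mix_weight * self._pattern(
                    over.mix_with
                )
            base = base * over.gain
        if motion == "r":
            return np.maximum(base, 1e-12)
        return base * self.pose_mod[pose] * self.load_gain[load]

    def with_shift(
        self, motion: str, pose: int, gain: float = 1.0,
        mix_with: str | None = None, mix_weight: float = 0.0,
    ) -> "GeneratorSpec":
        over = dict(self.shift_overrides)
        over[(motion, pose)] = ShiftOverride(gain, mix_with, mix_weight)
        return replace(self, shift_overrides=over)


def shifted_pose1_open_hand(mix_weight: float = 0.75, gain: float = 0.85) -> GeneratorSpec:
    """The underrepresentation scenario: in pose 1, the open-hand channel
    pattern is attenuated and pulled most of the way toward the closed-hand
    pattern, in every protocol phase, emulating a pose-specific recruitment
    change the pose-pooled calibration underrepresents."""
    return GeneratorSpec().with_shift("oh", 1, gain=gain, mix_with="ch", mix_weight=mix_weight)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_emg(
    spec: GeneratorSpec, motion: str, pose: int, load: int,
    duration: float, seed, start_time: float = 0.0,
) -> EmgStream:
    """One contiguous EMG block for a static (motion, pose, load) state."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    n = int(round(duration * EMG_RATE))
    base = spec.channel_std(motion, pose, load)
    # warn on commanded amplitudes hot enough to clip; transient effort
    # excursions beyond the range are clipped silently, as hardware would
    p_clip = float(np.mean(2.0 * stats.norm.sf((EMG_MAX + 0.5) / np.maximum(base, 1e-12))))
    if p_clip > 0.01:
        warnings.warn(
            f"commanded amplitudes clip {100 * p_clip:.1f}% of samples at the 8-bit range"
        )
    std = np.repeat(base[:, None], n, axis=1)
    if motion != "r" and spec.effort_jitter > 0:
        per_int = max(int(round(spec.effort_interval_s * EMG_RATE)), 1)
        n_int = -(-n // per_int)
        effort = np.exp(rng.normal(0.0, spec.effort_jitter, n_int))
        std = std * np.repeat(effort, per_int)[None, :n]
    raw = rng.normal(0.0, std, size=(N_CHANNELS, n))
    clipped = np.clip(np.rint(raw), EMG_MIN, EMG_MAX)
    return EmgStream(clipped.astype(np.int16), EMG_RATE, start_time=start_time)


def gen_imu(
    pose_trajectory: list[tuple[float, int]], motion: str, duration: float,
    seed, spec: GeneratorSpec | None = None, start_time: float = 0.0,
) -> ImuStream:
    """Orientation stream following a commanded pose trajectory.

    ``pose_trajectory`` lists (start_time_s, pose) breakpoints relative to
    the block start; the Y angle ramps between band centers with a smooth
    cosine transition over ``transition_s`` after each breakpoint.
    """
    spec = spec or GeneratorSpec()
    rng = _rng(seed)
    n = int(round(duration * IMU_RATE))
    t = np.arange(n) / IMU_RATE
    y = np.full(n, spec.pose_center[pose_trajectory[0][1]])
    for (tb, pose_new), prev in zip(pose_trajectory[1:],
                                    (p for _, p in pose_trajectory[:-1])):
        y0, y1 = spec.pose_center[prev], spec.pose_center[pose_new]
        ramp = (t >= tb) & (t < tb + spec.transition_s)
        y[ramp] = y0 + (y1 - y0) * 0.5 * (1 - np.cos(np.pi * (t[ramp] - tb) / spec.transition_s))
        y[t >= tb + spec.transition_s] = y1
    y = y + rng.normal(0, spec.y_jitter, n)
    x = spec.x_offset.get(motion, 0.0) + rng.normal(0, spec.x_jitter, n)
    z = rng.normal(0, spec.z_jitter, n)
    quats = euler_to_quaternion(np.column_stack([x, y, z]))
    return ImuStream(np.atleast_2d(quats), IMU_RATE, start_time=start_time)


#: Pose command slots of one 10 s calibration block (2 s each): pose 1 is
#: prepended and appended as reaction-time buffer around the 1-2-3 sweep.
CALIBRATION_POSE_SLOTS = (1, 1, 2, 3, 1)
CALIBRATION_SLOT_S = 2.0
CALIBRATION_BLOCK_S = 10.0
CALIBRATION_RETAIN = (2.0, 8.0)  # middle 60%: first/last 20% cut
CALIBRATION_REPS = 3


def gen_calibration_session(
    spec: GeneratorSpec, seed, n_reps: int = CALIBRATION_REPS, load: int = 0,
) -> list[SessionRecord]:
    """Generate the dynamic calibration phase.

    For every motion and repetition: a 10 s block whose pose command changes
    every 2 s (1-1-2-3-1), EMG modulated by the commanded pose, IMU ramping
    between pose bands; the retention window keeps the middle 6 s, so three
    repetitions yield 18 s of labeled data per class.
    """
    rng = _rng(seed)
    records = []
    t0 = 0.0
    slots = CALIBRATION_POSE_SLOTS
    for motion in MOTIONS:
        for rep in range(n_reps):
            chunks = [
                gen_emg(spec, motion, pose, load, CALIBRATION_SLOT_S, rng).samples
                for pose in slots
            ]
            emg = EmgStream(np.concatenate(chunks, axis=1), EMG_RATE, start_time=t0)
            traj = [(0.0, slots[0])] + [
                (i * CALIBRATION_SLOT_S, p)
                for i, p in enumerate(slots[1:], start=1)
                if p != slots[i - 1]
            ]
            imu = gen_imu(traj, motion, CALIBRATION_BLOCK_S, rng, spec, start_time=t0)
            records.append(
                SessionRecord(
                    emg=emg, imu=imu, motion=motion, load=load,
                    phase="calibration", retain=CALIBRATION_RETAIN,
                    meta={"rep": rep},
                )
            )
            t0 += CALIBRATION_BLOCK_S + 5.0  # 5 s inter-block rest (not recorded)
    return records


def virtual_user(
    targets: np.ndarray, positions: np.ndarray, cfg: TacConfig,
    rng: np.random.Generator | None = None, intent_noise: float = 0.0,
) -> str:
    """Scripted participant: intend the motion that reduces the largest DOF
    error beyond the allowance; rest when every DOF is within allowance.

    A DOF error with no mapped corrective motion (the pinch DOF has no
    antagonist) is skipped.  With probability ``intent_noise`` the intent is
    replaced by a uniformly random motion class (attention lapse).
    """
    if intent_noise > 0 and rng is not None and rng.random() < intent_noise:
        return str(rng.choice(MOTIONS))
    errors = targets - positions
    for dof in np.argsort(-np.abs(errors)):
        if abs(errors[dof]) <= cfg.allowance:
            break
        need = (int(dof), 1 if errors[dof] > 0 else -1)
        for motion, mapping in cfg.dof_map.items():
            if mapping == need:
                return motion
    return "r"


class ClosedLoopSimulator:
    """Couple the signal generator, a classifier and the virtual user.

    Per decision tick the virtual user picks an intent from the current DOF
    errors, the generator emits 50 ms of EMG/IMU for that intent at the
    session's pose and load, the decoder classifies the trailing 200 ms
    window, and the TAC physics move the virtual hand according to the
    *decoded* class.  Feature vectors and raw predictions are recorded for
    pool building.
    """

    def __init__(
        self, spec: GeneratorSpec, model, cfg: TacConfig | None = None,
        seg: SegmentationConfig | None = None,
        thresholds: PoseThresholds | None = None,
    ):
        self.spec = spec
        self.model = model
        self.cfg = cfg or TacConfig()
        self.seg = seg or SegmentationConfig()
        self.thresholds = thresholds or PoseThresholds()

    def run_trial(
        self, target_motion: str, pose: int, load: int, rng,
    ) -> tuple[TacResult, pd.DataFrame]:
        rng = _rng(rng)
        cfg = self.cfg
        trial = TacTrial(target_motion)
        targets = trial.targets(cfg)
        win, _ = self.seg.in_samples(EMG_RATE)
        chunk = int(round(EMG_RATE * cfg.decision_period))
        imu_per_tick = IMU_RATE * cfg.decision_period
        buf = np.zeros((N_CHANNELS, 0), dtype=np.int16)
        eul_hist: list[np.ndarray] = []  # per-IMU-sample (x, y) angles
        rows: list[np.ndarray] = []
        meta_rows: list[tuple] = []

        def decide(k: int, t: float, pos: np.ndarray) -> str:
            nonlocal buf
            intent = virtual_user(targets, pos, cfg, rng, self.spec.intent_noise)
            emg = gen_emg(self.spec, intent, pose, load, cfg.decision_period, rng)
            buf = np.concatenate([buf, emg.samples], axis=1)[:, -2 * win :]
            n_imu = int(np.floor((k + 1) * imu_per_tick) - np.floor(k * imu_per_tick))
            imu = gen_imu([(0.0, pose)], intent, n_imu / IMU_RATE, rng, self.spec)
            eul = np.atleast_2d(quaternion_to_euler(imu.quaternions))
            eul_hist.extend(eul[:, :2])
            if buf.shape[1] < win:
                return "r"  # decoder warm-up before the first full window
            feats = extract_emg_features(buf[:, -win:], self.seg.zc_ssc_threshold)
            recent = np.asarray(eul_hist[-int(np.ceil(IMU_RATE * self.seg.window_length / 1000)) :])
            ex = float(np.arctan2(np.mean(np.sin(recent[:, 0])), np.mean(np.cos(recent[:, 0]))))
            ey = float(np.arctan2(np.mean(np.sin(recent[:, 1])), np.mean(np.cos(recent[:, 1]))))
            vec = np.concatenate([feats, [ex]])
            label = str(np.atleast_1d(self.model.predict(vec[None, :]))[0])
            rows.append(vec)
            meta_rows.append((label, intent, pose_label(ey, self.thresholds), load, t))
            return label

        result = simulate_trial(decide, trial, cfg)
        df = pd.DataFrame(np.asarray(rows) if rows else np.empty((0, len(FEATURE_COLUMNS))),
                          columns=FEATURE_COLUMNS)
        meta = pd.DataFrame(
            meta_rows, columns=["predicted_raw", "intent", "pose", "load", "time"]
        )
        return result, pd.concat([df, meta], axis=1)


def run_familiarization(
    spec: GeneratorSpec, model, seed, cfg: TacConfig | None = None,
) -> tuple[pd.DataFrame, list[TacResult]]:
    """Familiarization phase: one closed-loop TAC series (5 active-motion
    targets, randomized order) for each of the nine pose x load
    combinations, decoded by the reference model.  Returns the recorded
    feature table (with decoded pose and load annotations) and all trial
    results."""
    rng = _rng(seed)
    sim = ClosedLoopSimulator(spec, model, cfg)
    frames, results = [], []
    for pose in POSES:
        for load in LOADS:
            for target in rng.permutation(ACTIVE_MOTIONS):
                res, df = sim.run_trial(str(target), pose, load, rng)
                df["series_pose"] = pose
                df["target"] = str(target)
                frames.append(df)
                results.append(res)
    features = pd.concat(frames, ignore_index=True)
    return features, results


def run_testing(
    spec: GeneratorSpec, models: dict[str, object], seed,
    cfg: TacConfig | None = None, n_pairs: int = 3,
) -> dict[str, list[TacResult]]:
    """Testing phase: ``n_pairs`` pairs of TAC series, the two classifiers
    alternating in randomized order, external load re-drawn per pair, limb
    pose varied per target within a series."""
    rng = _rng(seed)
    names = list(models)
    if len(names) != 2:
        raise ValueError("testing compares exactly two classifiers")
    load_order = rng.permutation(LOADS)
    out: dict[str, list[TacResult]] = {name: [] for name in names}
    for pair in range(n_pairs):
        load = int(load_order[pair % len(load_order)])
        order = list(rng.permutation(names))
        targets = list(rng.permutation(ACTIVE_MOTIONS))
        poses = list(np.tile(POSES, 2)[:len(targets)])
        rng.shuffle(poses)
        for name in order:
            sim = ClosedLoopSimulator(spec, models[name], cfg)
            for target, pose in zip(targets, poses):
                res, _ = sim.run_trial(str(target), int(pose), load, rng)
                out[name].append(res)
    return out


def gen_labeled_features(
    spec: GeneratorSpec, motion: str, pose: int, load: int, duration: float,
    seed, seg: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Fresh labeled feature windows for one static state (held-out
    evaluation data)."""
    from .features import fuse

    rng = _rng(seed)
    seg = seg or SegmentationConfig()
    emg = gen_emg(spec, motion, pose, load, duration, rng)
    imu = gen_imu([(0.0, pose)], motion, duration, rng, spec)
    return fuse(emg, imu, seg, motion=motion, load=load)
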