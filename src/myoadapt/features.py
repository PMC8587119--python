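"""Windowing, time-domain EMG features, orientation decoding and fusion.

The decoding front end segments each contiguous recording into overlapping
windows (200 ms length, 50 ms increment by default), computes the four
Hudgins time-domain features — mean absolute value (mav), zero crossings
(zc), slope sign changes (ssc) and waveform length (wl) — per channel, and
appends one kinematic feature: the absolute X Euler angle of the forearm,
averaged (circularly) over the IMU samples inside the window.  The windowed
Y Euler angle yields the limb-pose label (three sagittal-plane bands split
at ±π/3).

Euler angles follow the intrinsic Z-Y-X (yaw-pitch-roll) convention
throughout the package, so the Y (pitch) angle maps to summed shoulder +
elbow flexion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import MOTIONS, N_CHANNELS
from .streams import EmgStream, ImuStream, SessionRecord

EULER_ORDER = "ZYX"  # intrinsic yaw-pitch-roll; fixed package-wide

#: Column names of the 33-component fused feature vector, channel-major:
#: mav, zc, ssc, wl for channels 1..8, then the X Euler angle.
FEATURE_COLUMNS: list[str] = [
    f"ch{c + 1}_{name}" for c in range(N_CHANNELS) for name in ("mav", "zc", "ssc", "wl")
] + ["euler_x"]

ANNOTATION_COLUMNS = ["motion", "pose", "load", "time"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Sliding-window segmentation parameters (milliseconds)."""

    window_length: float = 200.0
    increment: float = 50.0
    zc_ssc_threshold: float = 0.0
    """Deadzone for zc/ssc counts; 0 suits integer-valued raw EMG where the
    quantization step already suppresses sub-LSB chatter.  Hardware users with
    analog front ends should raise it above their noise floor."""

    def __post_init__(self) -> None:
        if not 0 < self.increment <= self.window_length:
            raise ValueError("require 0 < increment <= window_length")

    def in_samples(self, sample_rate: float) -> tuple[int, int]:
        return (
            int(round(self.window_length * sample_rate / 1000.0)),
            int(round(self.increment * sample_rate / 1000.0)),
        )


@dataclass(frozen=True)
class PoseThresholds:
    """Y-Euler-angle band edges separating the three limb poses (radians)."""

    lower: float = -np.pi / 3
    upper: float = np.pi / 3

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("require lower < upper")


class StreamTooShortError(ValueError):
    """Raised when a recording is shorter than one analysis window."""


def segment_stream(emg: EmgStream, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Slice a contiguous EMG recording into overlapping windows.

    Returns an array of shape (n_windows, n_channels, window_samples);
    window k covers samples [k*inc, k*inc + win), so
    n_windows = floor((N - win) / inc) + 1.
    """
    cfg = cfg or SegmentationConfig()
    win, inc = cfg.in_samples(emg.sample_rate)
    n = emg.n_samples
    if n < win:
        raise StreamTooShortError(
            f"stream of {n} samples is too short for a {win}-sample window"
        )
    n_windows = (n - win) // inc + 1
    starts = np.arange(n_windows) * inc
    idx = starts[:, None] + np.arange(win)[None, :]
    return emg.samples[:, idx].transpose(1, 0, 2)


def extract_emg_features(window: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Hudgins time-domain features of one (n_channels x W) window.

    Per channel: mav = mean(|x|); zc counts sign changes whose amplitude step
    exceeds ``threshold``; ssc counts slope-sign changes exceeding it; wl is
    the summed absolute first difference.  Output is channel-major
    (mav, zc, ssc, wl per channel), length 4 * n_channels.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != N_CHANNELS:
        raise ValueError(f"window must be ({N_CHANNELS} x W), got {window.shape}")
    if window.shape[1] < 3:
        raise ValueError("window must hold at least 3 samples")
    d = np.diff(window, axis=1)
    mav = np.mean(np.abs(window), axis=1)
    wl = np.sum(np.abs(d), axis=1)
    zc = np.sum(
        (window[:, :-1] * window[:, 1:] < 0) & (np.abs(d) >= threshold), axis=1
    )
    # interior sample i: x_i - x_{i-1} = d[i-1], x_i - x_{i+1} = -d[i]
    ssc = np.sum(
        (d[:, :-1] * -d[:, 1:] > 0)
        & (np.maximum(np.abs(d[:, :-1]), np.abs(d[:, 1:])) >= threshold),
        axis=1,
    )
    return np.column_stack([mav, zc, ssc, wl]).ravel()


def quaternion_to_euler(q: np.ndarray) -> np.ndarray:
    """Convert unit quaternions (w, x, y, z) to intrinsic Z-Y-X Euler angles.

    Returns an array (..., 3) ordered (x, y, z) — roll, pitch, yaw.  Inputs
    off unit norm by more than 1e-6 are renormalized with a warning; a
    deviation above 1e-3 is an error.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    norms = np.linalg.norm(q, axis=1)
    dev = np.abs(norms - 1.0)
    if np.any(dev > 1e-3):
        raise ValueError("quaternion norm deviates from 1 by more than 1e-3")
    if np.any(dev > 1e-6):
        warnings.warn("non-unit quaternion normalized", stacklevel=2)
        q = q / norms[:, None]
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        zyx = Rotation.from_quat(q, scalar_first=True).as_euler(EULER_ORDER)
    xyz = zyx[:, ::-1]
    return xyz[0] if xyz.shape[0] == 1 else xyz


def euler_to_quaternion(euler_xyz: np.ndarray) -> np.ndarray:
    """Inverse of :func:`quaternion_to_euler`; angles ordered (x, y, z)."""
    e = np.atleast_2d(np.asarray(euler_xyz, dtype=float))
    q = Rotation.from_euler(EULER_ORDER, e[:, ::-1]).as_quat(scalar_first=True)
    return q[0] if q.shape[0] == 1 else q


def pose_label(y_angle, thresholds: PoseThresholds | None = None):
    """Map a Y (pitch) Euler angle to a limb-pose label.

    Pose 1 below ``lower``, pose 2 in [lower, upper), pose 3 at or above
    ``upper``.  Accepts scalars or arrays.
    """
    thr = thresholds or PoseThresholds()
    y = np.asarray(y_angle, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y angle must be finite")
    pose = np.where(y < thr.lower, 1, np.where(y < thr.upper, 2, 3))
    return int(pose) if pose.ndim == 0 else pose.astype(int)


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))


def fuse(
    emg: EmgStream,
    imu: ImuStream,
    cfg: SegmentationConfig | None = None,
    thresholds: PoseThresholds | None = None,
    *,
    motion: str | None = None,
    load: int | None = None,
    retain: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Fuse one contiguous EMG/IMU recording into 33-component feature rows.

    Each row holds the 32 EMG features of one window, the circular-mean X
    Euler angle of the IMU samples whose timestamps fall inside the
    half-open window interval, and annotations: the pose label decoded from
    the windowed mean Y angle, the instructed motion / load (if given) and
    the window start time.  Windows with no in-window IMU sample reuse the
    most recent earlier orientation; a window before the first IMU sample is
    an error.

    ``retain`` restricts windowing to the given time interval relative to
    the recording start (used for the calibration trim); windows never
    straddle the cut boundaries.
    """
    cfg = cfg or SegmentationConfig()
    if retain is not None:
        i0 = int(np.ceil(retain[0] * emg.sample_rate - 1e-9))
        i1 = int(np.floor(retain[1] * emg.sample_rate + 1e-9))
        sub = EmgStream(
            emg.samples[:, i0:i1],
            emg.sample_rate,
            start_time=emg.start_time + i0 / emg.sample_rate,
        )
        return fuse(sub, imu, cfg, thresholds, motion=motion, load=load)

    windows = segment_stream(emg, cfg)
    win, inc = cfg.in_samples(emg.sample_rate)
    start_times = emg.start_time + np.arange(windows.shape[0]) * inc / emg.sample_rate
    win_dur = win / emg.sample_rate

    euler = np.atleast_2d(quaternion_to_euler(imu.quaternions))
    t_imu = imu.timestamps

    rows = np.empty((windows.shape[0], len(FEATURE_COLUMNS)))
    poses = np.empty(windows.shape[0], dtype=int)
    for k in range(windows.shape[0]):
        rows[k, :-1] = extract_emg_features(windows[k], cfg.zc_ssc_threshold)
        lo = np.searchsorted(t_imu, start_times[k] - 1e-12, side="left")
        hi = np.searchsorted(t_imu, start_times[k] + win_dur - 1e-12, side="left")
        if hi > lo:
            sel = euler[lo:hi]
        elif lo > 0:  # carry the last known orientation forward
            sel = euler[lo - 1 : lo]
        else:
            raise ValueError("no IMU sample at or before the first window")
        rows[k, -1] = _circular_mean(sel[:, 0])
        poses[k] = pose_label(_circular_mean(sel[:, 1]), thresholds)

    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df["motion"] = motion if motion is None else pd.Categorical(
        [motion] * len(df), categories=MOTIONS
    )
    df["pose"] = poses
    df["load"] = load
    df["time"] = start_times
    return df


def fuse_records(
    records: list[SessionRecord],
    cfg: SegmentationConfig | None = None,
    thresholds: PoseThresholds | None = None,
) -> pd.DataFrame:
    """Fuse a list of recording blocks into one feature table."""
    parts = [
        fuse(r.emg, r.imu, cfg, thresholds, motion=r.motion, load=r.load, retain=r.retain)
        for r in records
    ]
    return pd.concat(parts, ignore_index=True)


def feature_matrix(df: pd.DataFrame) -> np.ndarray:
    """The (n, 33) numeric design matrix of a feature table."""
    return df[FEATURE_COLUMNS].to_numpy(dtype=float)
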