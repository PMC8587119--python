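"""Raw EMG / IMU stream containers and the on-disk session format.

A *session* is a directory holding ``meta.json`` plus two delimited text
streams, ``emg.csv`` (timestamp + 8 integer channels) and ``imu.csv``
(timestamp + 4 quaternion components, scalar first).  Streams are validated
on construction: EMG samples must fit the 8-bit acquisition range and
quaternions must be unit within tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import EMG_MAX, EMG_MIN, EMG_RATE, IMU_RATE, N_CHANNELS

QUAT_UNIT_TOL = 1e-6


@dataclass
class EmgStream:
    """Multi-channel surface-EMG recording.

    Parameters
    ----------
    samples : ndarray of shape (n_channels, n_samples)
        8-bit signed integer samples in [-128, 127].
    sample_rate : float
        Sampling frequency in Hz (200 for the modeled armband).
    start_time : float
        Timestamp of the first sample, seconds.
    """

    samples: np.ndarray
    sample_rate: float = EMG_RATE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x samples) array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.size and (
            self.samples.min() < EMG_MIN or self.samples.max() > EMG_MAX
        ):
            raise ValueError(
                f"EMG samples outside the acquisition range [{EMG_MIN}, {EMG_MAX}]"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class ImuStream:
    """Orientation stream of unit quaternions (w, x, y, z) against the
    space-fixed global frame."""

    quaternions: np.ndarray
    sample_rate: float = IMU_RATE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.ndim != 2 or self.quaternions.shape[1] != 4:
            raise ValueError("quaternions must have shape (n, 4)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        norms = np.linalg.norm(self.quaternions, axis=1)
        if self.quaternions.size and np.any(np.abs(norms - 1.0) > QUAT_UNIT_TOL):
            raise ValueError("quaternions must be unit norm within 1e-6")

    @property
    def n_samples(self) -> int:
        return self.quaternions.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


@dataclass
class SessionRecord:
    """One contiguous recording block with its annotations.

    ``retain`` is the half-open time interval (relative to the block start)
    kept for labeled processing; blocks trimmed by the calibration protocol
    keep only the middle 60%.
    """

    emg: EmgStream
    imu: ImuStream
    motion: str | None = None
    load: int | None = None
    phase: str = ""
    retain: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)


def write_session(path: str | Path, records: list[SessionRecord]) -> None:
    """Write a session directory (``meta.json`` + ``emg.csv`` + ``imu.csv``).

    Blocks are concatenated on a common timeline; per-block boundaries and
    annotations live in ``meta.json`` so readers can re-split the streams.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    emg_rows, imu_rows, meta_records = [], [], []
    for rec in records:
        te = rec.emg.timestamps
        emg_rows.append(
            pd.DataFrame(
                {"t": te, **{f"ch{c + 1}": rec.emg.samples[c] for c in range(rec.emg.n_channels)}}
            )
        )
        ti = rec.imu.timestamps
        imu_rows.append(
            pd.DataFrame({"t": ti, "qw": rec.imu.quaternions[:, 0],
                          "qx": rec.imu.quaternions[:, 1],
                          "qy": rec.imu.quaternions[:, 2],
                          "qz": rec.imu.quaternions[:, 3]})
        )
        meta_records.append(
            {
                "start": rec.emg.start_time,
                "duration": rec.emg.duration,
                "motion": rec.motion,
                "load": rec.load,
                "phase": rec.phase,
                "retain": list(rec.retain) if rec.retain is not None else None,
                "meta": rec.meta,
            }
        )
    meta = {
        "schema_version": 1,
        "emg_rate": records[0].emg.sample_rate if records else EMG_RATE,
        "imu_rate": records[0].imu.sample_rate if records else IMU_RATE,
        "n_channels": records[0].emg.n_channels if records else N_CHANNELS,
        "records": meta_records,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    pd.concat(emg_rows, ignore_index=True).to_csv(path / "emg.csv", index=False)
    pd.concat(imu_rows, ignore_index=True).to_csv(path / "imu.csv", index=False)


def read_session(path: str | Path) -> list[SessionRecord]:
    """Read a session directory written by :func:`write_session`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    emg = pd.read_csv(path / "emg.csv")
    imu = pd.read_csv(path / "imu.csv")
    n_ch = meta["n_channels"]
    ch_cols = [f"ch{c + 1}" for c in range(n_ch)]
    records = []
    for rec in meta["records"]:
        t0, t1 = rec["start"], rec["start"] + rec["duration"]
        # half-open selection; tolerance guards float round-trip at the edges
        e = emg[(emg["t"] >= t0 - 1e-9) & (emg["t"] < t1 - 1e-9)]
        i = imu[(imu["t"] >= t0 - 1e-9) & (imu["t"] < t1 - 1e-9)]
        records.append(
            SessionRecord(
                emg=EmgStream(
                    e[ch_cols].to_numpy().T, meta["emg_rate"], start_time=t0
                ),
                imu=ImuStream(
                    i[["qw", "qx", "qy", "qz"]].to_numpy(), meta["imu_rate"], start_time=t0
                ),
                motion=rec["motion"],
                load=rec["load"],
                phase=rec["phase"],
                retain=tuple(rec["retain"]) if rec["retain"] else None,
                meta=rec.get("meta", {}),
            )
        )
    return records
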