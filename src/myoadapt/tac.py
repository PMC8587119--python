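"""Target achievement control (TAC) test simulation.

A virtual hand with three degrees of freedom — aperture (oh/ch), wrist
rotation (wp/ws) and pinch (pg) — is driven by a stream of motion-class
decisions, one per decision period.  Each active decision moves its DOF at
a constant angular speed in the mapped direction; the rest class holds
still.  A trial displaces the target of exactly one DOF by the distance D;
it completes when every DOF has remained continuously within the allowance
W of its target for the dwell time, before the timeout.  Difficulty is
summarized by the Shannon index of difficulty log2(D/W + 1).

The instructed target posture coincides with the displaced DOF's end stop
(e.g. "fully open hand"), so sustained correct activation parks the hand at
the target; wrong-class excursions move other DOFs freely within the
physical range of ±180° and must be corrected by antagonist activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DOF_NAMES = ("aperture", "rotation", "pinch")

#: motion -> (dof index, direction); rest maps to no movement.
DEFAULT_DOF_MAP: dict[str, tuple[int, int] | None] = {
    "oh": (0, +1),
    "ch": (0, -1),
    "wp": (1, +1),
    "ws": (1, -1),
    "pg": (2, +1),
    "r": None,
}

PHYSICAL_RANGE = 180.0  # degrees, symmetric clip for free excursions


@dataclass(frozen=True)
class TacConfig:
    """TAC test parameters (degrees / seconds)."""

    distance: float = 60.0
    allowance: float = 8.0
    dwell: float = 1.0
    timeout: float = 15.0
    decision_period: float = 0.050
    dof_speed: float = 40.0
    dof_map: dict = field(default_factory=lambda: dict(DEFAULT_DOF_MAP))

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not 0 < self.allowance < self.distance:
            raise ValueError("require 0 < allowance < distance")
        if not self.dwell < self.timeout:
            raise ValueError("dwell must be shorter than timeout")

    @property
    def n_dofs(self) -> int:
        return 1 + max(d for v in self.dof_map.values() if v is not None for d in [v[0]])


@dataclass(frozen=True)
class TacTrial:
    """One virtual trial: a single DOF displaced to the target distance."""

    target_motion: str

    def targets(self, cfg: TacConfig) -> np.ndarray:
        mapping = cfg.dof_map.get(self.target_motion)
        if mapping is None:
            raise ValueError(f"{self.target_motion!r} maps to no DOF movement")
        t = np.zeros(cfg.n_dofs)
        t[mapping[0]] = mapping[1] * cfg.distance
        return t


@dataclass
class TacResult:
    """Outcome of one trial.

    completion_time includes the dwell period (time at which the dwell
    criterion is first satisfied); selection_time is the first instant the
    target motion is decided, whether or not the trial completes.
    """

    trial: TacTrial
    completed: bool
    completion_time: float | None
    selection_time: float | None
    times: np.ndarray
    decisions: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        if self.completed and self.completion_time is None:
            raise ValueError("completed trial needs a completion time")


def index_of_difficulty(distance: float, allowance: float) -> float:
    """Shannon-formulation index of difficulty, log2(D/W + 1)."""
    if allowance <= 0:
        raise ValueError("allowance must be positive")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return math.log2(distance / allowance + 1.0)


def simulate_trial(decide, trial: TacTrial, cfg: TacConfig | None = None) -> TacResult:
    """Drive one TAC trial from a decision callback.

    ``decide(k, t, positions)`` returns the motion label for tick k, given
    the tick's start time and the current DOF positions — this is the hook
    the closed-loop simulator uses to couple signal generation, the
    classifier and the virtual user.  Decision k takes effect during tick k;
    positions and the in-target check are evaluated at the tick's end,
    time (k + 1) * decision_period.
    """
    cfg = cfg or TacConfig()
    dt = cfg.decision_period
    n_ticks = int(round(cfg.timeout / dt))
    targets = trial.targets(cfg)
    active_map = cfg.dof_map[trial.target_motion]
    pos = np.zeros(cfg.n_dofs)
    step = cfg.dof_speed * dt

    times = np.empty(n_ticks)
    decisions = np.empty(n_ticks, dtype=object)
    positions = np.empty((n_ticks, cfg.n_dofs))
    selection_time = None
    completed = False
    completion_time = None
    in_band_since = None
    used = 0
    for k in range(n_ticks):
        label = decide(k, k * dt, pos.copy())
        if label not in cfg.dof_map:
            raise ValueError(f"unmapped motion label {label!r}")
        t = (k + 1) * dt
        mapping = cfg.dof_map[label]
        if mapping is not None:
            dof, direction = mapping
            new = pos[dof] + direction * step
            if (dof, direction) == active_map:
                # moving toward the instructed posture: end stop at the target
                tgt = targets[dof]
                new = min(new, tgt) if direction > 0 else max(new, tgt)
            pos[dof] = np.clip(new, -PHYSICAL_RANGE, PHYSICAL_RANGE)
        times[k] = t
        decisions[k] = label
        positions[k] = pos
        used = k + 1
        if selection_time is None and label == trial.target_motion:
            selection_time = t
        if np.all(np.abs(pos - targets) <= cfg.allowance):
            if in_band_since is None:
                in_band_since = t
            if t - in_band_since >= cfg.dwell - 1e-9:
                completed = True
                completion_time = t
                break
        else:
            in_band_since = None

    return TacResult(
        trial=trial,
        completed=completed,
        completion_time=completion_time,
        selection_time=selection_time,
        times=times[:used],
        decisions=decisions[:used],
        positions=positions[:used],
    )


def run_trial(decision_stream, trial: TacTrial, cfg: TacConfig | None = None) -> TacResult:
    """Replay a pre-recorded decision stream through one TAC trial.

    ``decision_stream`` supplies one motion label per decision period and
    must cover at least the timeout duration.
    """
    cfg = cfg or TacConfig()
    decisions = list(decision_stream)
    if len(decisions) < int(round(cfg.timeout / cfg.decision_period)):
        raise ValueError("decision stream must cover the timeout duration")
    return simulate_trial(lambda k, t, pos: decisions[k], trial, cfg)


def summarize(results: list[TacResult]) -> dict:
    """TAC evaluation measures over a batch of trials.

    Completion rate in percent; completion-time statistics over completed
    trials only; selection-time statistics over trials in which the target
    motion was ever decided.
    """
    if not results:
        raise ValueError("need at least one trial")
    n = len(results)
    ct = [r.completion_time for r in results if r.completed]
    st = [r.selection_time for r in results if r.selection_time is not None]

    def stats(vals):
        if not vals:
            return None
        v = np.asarray(vals, dtype=float)
        return {
            "median": float(np.median(v)),
            "mean": float(np.mean(v)),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        }

    return {
        "n_trials": n,
        "n_completed": len(ct),
        "completion_rate_pct": 100.0 * len(ct) / n,
        "completion_time_s": stats(ct),
        "selection_time_s": stats(st),
    }
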