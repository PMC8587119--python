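"""Per-state performance screening.

The classifier's held-out predictions are partitioned by limb pose; per
(motion, pose) *state* the confusion counts yield

    sensitivity = TP / (TP + FN)        (detection rate)
    precision   = TP / (TP + FP)        (label correctness)

A state is flagged as underrepresented when its sensitivity falls below the
minimum while its precision still meets it — the state is rarely detected,
but when it is, the label can be trusted, so self-labeled data from that
state are safe to adapt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .constants import MOTIONS, POSES


@dataclass(frozen=True)
class HyperParams:
    """Tunable thresholds of the adaptive learner.

    sens_min / prec_min : minimum per-state sensitivity and precision
        (fractions, default 0.90 — nine of ten executions correct).
    n_maj_voting : majority-vote window (odd, 2*m + 1 = 5 by default).
    delay_samples : m, decision samples inside the acceptable delay.
    max_delay_ms : acceptable command-actuation delay (250 ms at a 200 ms
        window sliding by 50 ms corresponds to m = 2).
    """

    sens_min: float = 0.90
    prec_min: float = 0.90
    n_maj_voting: int = 5
    delay_samples: int = 2
    max_delay_ms: float = 250.0

    def __post_init__(self) -> None:
        if not (0 < self.sens_min <= 1 and 0 < self.prec_min <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.n_maj_voting != 2 * self.delay_samples + 1 or self.n_maj_voting % 2 == 0:
            raise ValueError("n_maj_voting must equal 2*delay_samples + 1 (odd)")


@dataclass
class ConfusionMatrix:
    """Square confusion counts over the motion classes, tagged by pose
    ('overall' for the pose-pooled matrix).  Rows are true motions, columns
    predicted motions."""

    counts: np.ndarray
    pose: int | str = "overall"
    classes: tuple[str, ...] = MOTIONS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def normalized(self) -> np.ndarray:
        """Row-normalized matrix in percent (rows with no samples stay 0)."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, 100.0 * self.counts / sums, 0.0)
        return out

    def _index(self, motion: str) -> int:
        if motion not in self.classes:
            raise ValueError(f"unknown motion {motion!r}")
        return self.classes.index(motion)


def confusion_by_pose(y_true, y_pred, poses, classes=MOTIONS) -> dict:
    """Partition confusion counts by limb pose.

    Returns ``{pose: ConfusionMatrix, ..., 'overall': ConfusionMatrix}``;
    the overall matrix is the element-wise sum of the per-pose matrices.
    """
    y_true, y_pred, poses = map(np.asarray, (y_true, y_pred, poses))
    if not (len(y_true) == len(y_pred) == len(poses)):
        raise ValueError("label sequences must have equal length")
    for arr in (y_true, y_pred):
        bad = set(np.unique(arr)) - set(classes)
        if bad:
            raise ValueError(f"labels outside the motion set: {sorted(bad)}")
    out = {}
    k = len(classes)
    for p in POSES:
        mask = poses == p
        counts = (
            _sk_confusion(y_true[mask], y_pred[mask], labels=list(classes))
            if mask.any()
            else np.zeros((k, k), dtype=int)
        )
        out[p] = ConfusionMatrix(counts, pose=p, classes=tuple(classes))
    out["overall"] = ConfusionMatrix(
        sum(out[p].counts for p in POSES), pose="overall", classes=tuple(classes)
    )
    return out


def sensitivity(cm: ConfusionMatrix, motion: str) -> float | None:
    """TP / (TP + FN); ``None`` when the class has no true samples."""
    i = cm._index(motion)
    denom = cm.counts[i, :].sum()
    return None if denom == 0 else float(cm.counts[i, i] / denom)


def precision(cm: ConfusionMatrix, motion: str) -> float | None:
    """TP / (TP + FP); ``None`` when the class is never predicted."""
    i = cm._index(motion)
    denom = cm.counts[:, i].sum()
    return None if denom == 0 else float(cm.counts[i, i] / denom)


@dataclass(frozen=True)
class StatePerformance:
    motion: str
    pose: int
    sensitivity: float | None
    precision: float | None
    flagged: bool


def state_performance(
    y_true, y_pred, poses, hp: HyperParams | None = None, classes=MOTIONS
) -> list[StatePerformance]:
    """Sensitivity/precision per (motion, pose) state with the
    underrepresentation flag."""
    hp = hp or HyperParams()
    cms = confusion_by_pose(y_true, y_pred, poses, classes)
    out = []
    for p in POSES:
        for m in classes:
            s = sensitivity(cms[p], m)
            pr = precision(cms[p], m)
            flagged = s is not None and pr is not None and s < hp.sens_min and pr >= hp.prec_min
            out.append(StatePerformance(m, p, s, pr, flagged))
    return out


def identify_underrepresented(
    perfs: list[StatePerformance], hp: HyperParams | None = None
) -> set[tuple[str, int]]:
    """States with sensitivity < sens_min and precision >= prec_min.

    Undefined (zero-denominator) measures never flag a state.
    """
    hp = hp or HyperParams()
    return {
        (p.motion, p.pose)
        for p in perfs
        if p.sensitivity is not None
        and p.precision is not None
        and p.sensitivity < hp.sens_min
        and p.precision >= hp.prec_min
    }


def performance_table(perfs: list[StatePerformance]) -> pd.DataFrame:
    """Long-form table of per-state measures (percent), one row per state."""
    return pd.DataFrame(
        {
            "motion": [p.motion for p in perfs],
            "pose": [p.pose for p in perfs],
            "sensitivity_pct": [
                None if p.sensitivity is None else 100 * p.sensitivity for p in perfs
            ],
            "precision_pct": [
                None if p.precision is None else 100 * p.precision for p in perfs
            ],
            "flagged": [p.flagged for p in perfs],
        }
    )
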