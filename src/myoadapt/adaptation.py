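"""Self-training augmentation of the calibration set.

Unlabeled feature vectors recorded during familiarization are labeled by
the reference model, stabilized by a trailing majority vote over the last
n_maj_voting decisions, sorted into a (motion x pose) pool, and — for the
states flagged as underrepresented — appended to the calibration set before
retraining.  Samples whose raw prediction disagrees with the voted label
are discarded rather than relabeled, which suppresses transient
misclassifications around motion changes.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import MOTIONS, POSES
from .evaluation import HyperParams
from .lda import PooledCovarianceLDA, ReferenceSelector

log = logging.getLogger(__name__)


def majority_vote_filter(labels, n: int = 5) -> np.ndarray:
    """Trailing-window modal filter over a decision sequence.

    Output i is the most frequent label among the last ``n`` decisions
    ending at i (the available prefix for the first n-1 positions).  Ties
    resolve to the tied label seen most recently, which favors the user's
    current intent and bounds the actuation delay.
    """
    if n < 1 or n % 2 == 0:
        raise ValueError("n must be odd and >= 1")
    labels = list(labels)
    out = []
    for i in range(len(labels)):
        window = labels[max(0, i - n + 1) : i + 1]
        counts = Counter(window)
        top = max(counts.values())
        # scan backwards: first tied label encountered is the most recent
        for lab in reversed(window):
            if counts[lab] == top:
                out.append(lab)
                break
    return np.asarray(out)


@dataclass
class AdaptationPool:
    """Self-labeled familiarization samples sorted by (motion, pose).

    ``cells`` maps each (predicted motion, pose) state to the row indices of
    the retained samples in ``features``; labels are model predictions, no
    ground truth is stored.
    """

    features: pd.DataFrame
    cells: dict[tuple[str, int], np.ndarray]
    provenance: dict = field(default_factory=dict)

    def cell(self, motion: str, pose: int) -> pd.DataFrame:
        idx = self.cells.get((motion, pose), np.empty(0, dtype=int))
        return self.features.iloc[idx]

    def counts(self) -> pd.DataFrame:
        """Samples per (motion, pose) cell, motions as rows."""
        table = pd.DataFrame(0, index=list(MOTIONS), columns=list(POSES))
        for (m, p), idx in self.cells.items():
            table.loc[m, p] = len(idx)
        return table


def build_pool(
    features: pd.DataFrame,
    model: PooledCovarianceLDA | ReferenceSelector,
    hp: HyperParams | None = None,
    feature_columns: list[str] | None = None,
    provenance: dict | None = None,
) -> AdaptationPool:
    """Label a familiarization feature table and sort it into the pool.

    Each vector receives the model's raw prediction; the sequence of raw
    predictions is majority-vote filtered; a vector is retained only when
    its raw label equals the voted label (stable prediction) and is then
    filed under (voted label, pose annotation).
    """
    from .features import FEATURE_COLUMNS

    hp = hp or HyperParams()
    cols = feature_columns or FEATURE_COLUMNS
    X = features[cols].to_numpy(dtype=float)
    raw = np.asarray(model.predict(X))
    voted = majority_vote_filter(raw, hp.n_maj_voting)
    stable = raw == voted
    poses = features["pose"].to_numpy()
    out = features.copy()
    out["predicted"] = raw
    out["voted"] = voted
    out["stable"] = stable
    cells: dict[tuple[str, int], list[int]] = {}
    for i in np.flatnonzero(stable):
        cells.setdefault((str(voted[i]), int(poses[i])), []).append(i)
    return AdaptationPool(
        features=out,
        cells={k: np.asarray(v, dtype=int) for k, v in cells.items()},
        provenance=provenance or {},
    )


def adapt_and_retrain(
    calib_features: pd.DataFrame,
    calib_labels,
    pool: AdaptationPool,
    flagged: set[tuple[str, int]],
    trainer: ReferenceSelector | None = None,
    feature_columns: list[str] | None = None,
):
    """Append flagged pool cells to the calibration set and retrain.

    Returns ``(augmented_features, augmented_labels, refit_trainer)``.
    Original calibration rows are never removed or altered; exactly the
    flagged (motion, pose) cells are appended, each sample labeled with its
    voted prediction.  A flagged state with an empty pool cell is logged
    and skipped.  Retraining reuses the trainer's configuration and seed.
    """
    from .features import FEATURE_COLUMNS

    cols = feature_columns or FEATURE_COLUMNS
    calib_labels = np.asarray(calib_labels)
    added_frames, added_labels = [], []
    added_counts: dict[tuple[str, int], int] = {}
    for state in sorted(flagged):
        cell = pool.cell(*state)
        if cell.empty:
            log.info("flagged state %s has no pool samples; skipped", state)
            continue
        add = cell.reindex(columns=calib_features.columns)
        if "motion" in add.columns:
            # the voted self-label becomes ground truth; keep the dtype
            add["motion"] = pd.Series(
                [state[0]] * len(add), index=add.index
            ).astype(calib_features["motion"].dtype)
        added_frames.append(add)
        added_labels.append(np.full(len(cell), state[0], dtype=object))
        added_counts[state] = len(cell)

    if added_frames:
        aug_features = pd.concat(
            [calib_features, pd.concat(added_frames)], ignore_index=True
        )
        aug_labels = np.concatenate([calib_labels, np.concatenate(added_labels)])
    else:
        aug_features = calib_features.copy()
        aug_labels = calib_labels.copy()

    trainer = trainer or ReferenceSelector()
    refit = ReferenceSelector(**trainer.get_params()).fit(
        aug_features[cols].to_numpy(dtype=float),
        aug_labels,
        heldout={"pose": aug_features["pose"].to_numpy()},
    )
    refit.added_counts_ = added_counts
    return aug_features, aug_labels, refit


def adaptation_report(perfs, flagged, pool: AdaptationPool, added_counts) -> dict:
    """JSON-ready summary: per-state measures, flagged set, per-cell pool
    and appended counts, and pose/load tallies of the appended samples."""
    from .evaluation import performance_table

    added_idx = np.concatenate(
        [pool.cells[s] for s in sorted(added_counts)]
    ) if added_counts else np.empty(0, dtype=int)
    added = pool.features.iloc[added_idx]
    return {
        "states": performance_table(perfs).to_dict(orient="records"),
        "flagged": sorted([list(s) for s in flagged]),
        "pool_counts": {f"{m}/{p}": int(n) for (m, p), n in
                        ((k, len(v)) for k, v in pool.cells.items())},
        "added_counts": {f"{m}/{p}": int(n) for (m, p), n in added_counts.items()},
        "added_total": int(len(added)),
        "added_by_pose": {int(k): int(v) for k, v in
                          added["pose"].value_counts().items()} if len(added) else {},
        "added_by_load": {int(k): int(v) for k, v in
                          added["load"].value_counts().items()}
                         if len(added) and added["load"].notna().all() else {},
    }
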