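"""Three-phase experiment orchestration: calibrate, familiarize/adapt, test.

Runs the full protocol against the synthetic world: train and select the
reference model on a dynamic calibration session, screen per-state
performance on the winning split's held-out predictions, collect
self-labeled familiarization data in closed-loop TAC series, adapt and
retrain, then compare baseline and adapted classifiers in paired testing
series.  All randomness flows from one experiment seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adaptation import adapt_and_retrain, adaptation_report, build_pool
from .constants import MOTIONS
from .evaluation import HyperParams, identify_underrepresented, state_performance
from .features import SegmentationConfig, feature_matrix, fuse_records
from .lda import ReferenceSelector
from .synth import (
    GeneratorSpec,
    gen_calibration_session,
    run_familiarization,
    run_testing,
    shifted_pose1_open_hand,
)
from .tac import TacConfig, summarize

log = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Configuration of one synthetic-subject experiment."""

    seed: int = 0
    out_dir: str | None = None
    scenario: str = "default"  # or "shifted_pose1_open_hand"
    shift_mix_weight: float = 0.75
    shift_gain: float = 0.85
    hyperparams: HyperParams = field(default_factory=HyperParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    tac: TacConfig = field(default_factory=TacConfig)
    run_familiarization: bool = True
    run_testing: bool = True
    n_test_pairs: int = 3

    def generator_spec(self) -> GeneratorSpec:
        if self.scenario == "default":
            return GeneratorSpec()
        if self.scenario == "shifted_pose1_open_hand":
            return shifted_pose1_open_hand(
                mix_weight=self.shift_mix_weight, gain=self.shift_gain
            )
        raise ValueError(f"unknown scenario {self.scenario!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, typ in (
            ("hyperparams", HyperParams),
            ("segmentation", SegmentationConfig),
            ("tac", TacConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        return cls(**kwargs)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (< 2**31) from the experiment seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the protocol and return the report dictionary.

    When ``cfg.out_dir`` is set, the report (JSON), per-trial rows (CSV) and
    both serialized models are written there; partial outputs survive a
    failing later stage.
    """
    spec = cfg.generator_spec()
    seed_cal, seed_sel, seed_fam, seed_test = _spawn_seeds(cfg.seed, 4)
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_dict(cfg)}

    log.info("stage=calibration seed=%d", seed_cal)
    records = gen_calibration_session(spec, seed_cal)
    calib = fuse_records(records, cfg.segmentation)
    X = feature_matrix(calib)
    y = calib["motion"].astype(str).to_numpy()
    selector = ReferenceSelector(seed=seed_sel).fit(
        X, y, heldout={"pose": calib["pose"].to_numpy()}
    )
    perfs = state_performance(
        selector.heldout_true_, selector.heldout_pred_,
        selector.heldout_meta_["pose"], cfg.hyperparams,
    )
    flagged = identify_underrepresented(perfs, cfg.hyperparams)
    report["calibration"] = {
        "n_windows": int(len(calib)),
        "split_scores": selector.scores_,
        "reference_split": selector.best_split_,
        "flagged_states": sorted([list(s) for s in flagged]),
    }
    log.info("stage=calibration n=%d flagged=%s", len(calib), sorted(flagged))
    if out:
        selector.model_.to_json(out / "baseline_model.json")
        _dump(report, out)

    adapted = None
    if cfg.run_familiarization:
        log.info("stage=familiarization seed=%d", seed_fam)
        fam_features, fam_results = run_familiarization(
            spec, selector.model_, seed_fam, cfg.tac
        )
        pool = build_pool(
            fam_features, selector.model_, cfg.hyperparams,
            provenance={"phase": "familiarization"},
        )
        aug_X, aug_y, adapted = adapt_and_retrain(
            calib, y, pool, flagged, trainer=selector,
        )
        report["familiarization"] = {
            "tac": summarize(fam_results),
            "adaptation": adaptation_report(perfs, flagged, pool, adapted.added_counts_),
            "augmented_size": int(len(aug_y)),
        }
        log.info(
            "stage=familiarization added=%d augmented=%d",
            report["familiarization"]["adaptation"]["added_total"], len(aug_y),
        )
        if out:
            adapted.model_.to_json(out / "adapted_model.json")
            _dump(report, out)

    if cfg.run_testing and adapted is not None:
        log.info("stage=testing seed=%d", seed_test)
        results = run_testing(
            spec,
            {"baseline": selector.model_, "adapted": adapted.model_},
            seed_test, cfg.tac, n_pairs=cfg.n_test_pairs,
        )
        rows = []
        test_report = {}
        for name, res in results.items():
            test_report[name] = {
                "overall": summarize(res),
                "per_motion": {
                    m: summarize(sub)
                    for m in MOTIONS
                    if (sub := [r for r in res if r.trial.target_motion == m])
                },
            }
            rows.extend(
                {
                    "classifier": name,
                    "target": r.trial.target_motion,
                    "completed": r.completed,
                    "completion_time_s": r.completion_time,
                    "selection_time_s": r.selection_time,
                }
                for r in res
            )
        report["testing"] = test_report
        if out:
            pd.DataFrame(rows).to_csv(out / "trials.csv", index=False)
            _dump(report, out)
    return report


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["tac"]["dof_map"] = {k: list(v) if v else None for k, v in d["tac"]["dof_map"].items()}
    return d


def _dump(report: dict, out: Path) -> None:
    (out / "report.json").write_text(json.dumps(report, indent=1, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
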