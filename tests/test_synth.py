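"""Synthetic session generator: signal statistics, protocol structure and
the closed-loop virtual user."""

import numpy as np
import pytest

import myoadapt as ma
from myoadapt.constants import EMG_RATE, IMU_RATE, MOTIONS
from myoadapt.synth import (
    CALIBRATION_RETAIN,
    ClosedLoopSimulator,
    GeneratorSpec,
)
from myoadapt.tac import TacConfig, TacTrial


class TestGenEmg:
    def test_rest_mav_matches_folded_normal(self, default_spec):
        """Rest-class mean absolute value sits within 3 SE of the
        folded-normal expectation sqrt(2/pi) * sigma_floor."""
        emg = ma.gen_emg(default_spec, "r", 2, 0, duration=6.0, seed=3)
        sigma = default_spec.noise_floor
        expected = np.sqrt(2 / np.pi) * sigma
        n = emg.n_samples
        se = sigma * np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        mav = np.abs(emg.samples).mean(axis=1)
        assert np.all(np.abs(mav - expected) < 3 * se + 0.05)  # + quantization

    def test_load_monotonicity(self, default_spec):
        """More external load recruits more muscle: mav(600g) > mav(400g)."""
        mavs = {}
        for load in (400, 600):
            emg = ma.gen_emg(default_spec, "ch", 2, load, duration=10.0, seed=11)
            mavs[load] = np.abs(emg.samples).mean()
        assert mavs[600] > mavs[400]

    def test_identical_seed_reproducible(self, default_spec):
        a = ma.gen_emg(default_spec, "oh", 1, 0, 1.0, seed=5)
        b = ma.gen_emg(default_spec, "oh", 1, 0, 1.0, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_clip_warning_for_hot_amplitudes(self):
        spec = GeneratorSpec().with_shift("oh", 2, gain=4.0)
        with pytest.warns(UserWarning, match="clip"):
            ma.gen_emg(spec, "oh", 2, 600, 1.0, seed=1)

    def test_invalid_duration(self, default_spec):
        with pytest.raises(ValueError):
            ma.gen_emg(default_spec, "oh", 1, 0, 0.0, seed=1)

    def test_shift_override_attenuates(self, default_spec):
        shifted = default_spec.with_shift("oh", 1, gain=0.4)
        std_base = default_spec.channel_std("oh", 1, 0)
        std_shift = shifted.channel_std("oh", 1, 0)
        np.testing.assert_allclose(std_shift, 0.4 * std_base)
        # other cells untouched
        np.testing.assert_allclose(
            shifted.channel_std("oh", 2, 0), default_spec.channel_std("oh", 2, 0)
        )


class TestGenImu:
    def test_constant_pose_two(self, default_spec):
        imu = ma.gen_imu([(0.0, 2)], "oh", 2.0, seed=7, spec=default_spec)
        eul = ma.quaternion_to_euler(imu.quaternions)
        assert np.all(ma.pose_label(eul[:, 1]) == 2)

    def test_unit_norm(self, default_spec):
        imu = ma.gen_imu([(0.0, 1), (1.0, 3)], "wp", 3.0, seed=7, spec=default_spec)
        np.testing.assert_allclose(
            np.linalg.norm(imu.quaternions, axis=1), 1.0, atol=1e-9
        )

    def test_schedule_recovered_outside_transitions(self, default_spec):
        """Decoded pose labels match the commanded schedule away from the
        0.5 s transition ramps."""
        traj = [(0.0, 1), (2.0, 2), (4.0, 3), (6.0, 1)]
        imu = ma.gen_imu(traj, "oh", 8.0, seed=13, spec=default_spec)
        eul = ma.quaternion_to_euler(imu.quaternions)
        labels = ma.pose_label(eul[:, 1])
        t = imu.timestamps
        correct = total = 0
        bounds = [tb for tb, _ in traj[1:]]
        for i, ti in enumerate(t):
            if any(tb - 0.25 <= ti <= tb + 0.75 for tb in bounds):
                continue  # transition neighborhood
            commanded = [p for tb, p in traj if tb <= ti][-1]
            total += 1
            correct += labels[i] == commanded
        assert correct / total >= 0.99

    def test_wrist_rotation_offsets_x(self, default_spec):
        wp = ma.gen_imu([(0.0, 2)], "wp", 2.0, seed=3, spec=default_spec)
        ws = ma.gen_imu([(0.0, 2)], "ws", 2.0, seed=3, spec=default_spec)
        x_wp = ma.quaternion_to_euler(wp.quaternions)[:, 0].mean()
        x_ws = ma.quaternion_to_euler(ws.quaternions)[:, 0].mean()
        assert x_wp > 0.5 and x_ws < -0.5


class TestCalibrationSession:
    def test_protocol_structure(self, default_spec):
        records = ma.gen_calibration_session(default_spec, seed=21)
        assert len(records) == 18  # 6 motions x 3 repetitions
        per_class = {}
        for rec in records:
            assert rec.retain == CALIBRATION_RETAIN
            assert rec.emg.duration == pytest.approx(10.0)
            # retention mask cuts the first and last 20% of the block
            assert rec.retain[0] == pytest.approx(0.2 * rec.emg.duration)
            assert rec.retain[1] == pytest.approx(0.8 * rec.emg.duration)
            per_class.setdefault(rec.motion, 0.0)
            per_class[rec.motion] += rec.retain[1] - rec.retain[0]
        assert set(per_class) == set(MOTIONS)
        assert all(v == pytest.approx(18.0) for v in per_class.values())

    def test_window_yield(self, calib_features):
        # 18 s per class in 3 contiguous 6 s segments -> 117 windows each
        counts = calib_features.groupby("motion", observed=True).size()
        assert (counts == 351).all()
        assert len(calib_features) == 2106

    def test_reproducible(self, default_spec):
        a = ma.gen_calibration_session(default_spec, seed=33, n_reps=1)
        b = ma.gen_calibration_session(default_spec, seed=33, n_reps=1)
        np.testing.assert_array_equal(a[0].emg.samples, b[0].emg.samples)
        np.testing.assert_allclose(a[0].imu.quaternions, b[0].imu.quaternions)


class TestVirtualUser:
    CFG = TacConfig()

    def test_rest_when_on_target(self):
        targets = TacTrial("oh").targets(self.CFG)
        assert ma.virtual_user(targets, targets.copy(), self.CFG) == "r"

    def test_moves_toward_displaced_target(self):
        targets = TacTrial("oh").targets(self.CFG)
        assert ma.virtual_user(targets, np.zeros(3), self.CFG) == "oh"

    def test_antagonist_on_overshoot(self):
        targets = TacTrial("oh").targets(self.CFG)
        pos = np.array([80.0, 0.0, 0.0])  # aperture past the target
        assert ma.virtual_user(targets, pos, self.CFG) == "ch"

    def test_corrects_largest_error_first(self):
        targets = TacTrial("oh").targets(self.CFG)
        pos = np.array([0.0, -90.0, 0.0])  # big rotation excursion
        assert ma.virtual_user(targets, pos, self.CFG) == "wp"

    def test_uncorrectable_pinch_skipped(self):
        targets = TacTrial("oh").targets(self.CFG)
        pos = np.array([0.0, 0.0, 50.0])  # pinch has no antagonist
        assert ma.virtual_user(targets, pos, self.CFG) == "oh"


class _PerfectDecoder:
    """Classifies by nearest motion pattern (cheating oracle classifier)."""

    def __init__(self, spec):
        self.spec = spec

    def predict(self, X):
        X = np.atleast_2d(X)
        out = []
        for x in X:
            mav = x[0:32:4]
            best, best_d = None, np.inf
            for m in MOTIONS:
                ref = np.sqrt(2 / np.pi) * self.spec.channel_std(m, 2, 0)
                d = np.linalg.norm(mav - ref)
                if d < best_d:
                    best, best_d = m, d
            out.append(best)
        return np.asarray(out)


class TestClosedLoop:
    def test_perfect_classifier_zero_noise_completes(self, default_spec):
        """With no intent noise and a faithful decoder every trial completes."""
        from dataclasses import replace

        spec = replace(default_spec, intent_noise=0.0, effort_jitter=0.0)
        sim = ClosedLoopSimulator(spec, _PerfectDecoder(spec))
        for target in ("oh", "ch", "pg"):
            res, df = sim.run_trial(target, pose=2, load=0, rng=42)
            assert res.completed, target
            assert len(df) > 0

    def test_recorded_features_have_pose_and_load(self, default_spec, reference):
        sim = ClosedLoopSimulator(default_spec, reference.model_)
        res, df = sim.run_trial("ch", pose=3, load=400, rng=1)
        assert (df["load"] == 400).all()
        assert df["pose"].mode()[0] == 3

    def test_familiarization_schedule(self, default_spec, reference):
        feats, results = ma.run_familiarization(
            default_spec, reference.model_, seed=5
        )
        assert len(results) == 45  # 9 pose x load series of 5 targets
        assert set(zip(feats["series_pose"], feats["load"])) == {
            (p, l) for p in (1, 2, 3) for l in (0, 400, 600)
        }


class TestSelfConsistency:
    def test_reference_generalizes_to_fresh_session(self, default_spec, reference):
        """A model trained on one generated session decodes a fresh session
        from the same spec at >= 95% macro sensitivity."""
        from myoadapt.lda import macro_sensitivity

        fresh = ma.fuse_records(ma.gen_calibration_session(default_spec, seed=777))
        pred = reference.predict(ma.feature_matrix(fresh))
        sens = macro_sensitivity(fresh["motion"].astype(str).to_numpy(), pred)
        assert sens >= 0.95
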