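"""Kinematic squat simulator: trajectories, forward kinematics, rendering."""

import numpy as np
import pytest

from squatmon import quaternion as quat
from squatmon.imu_model import G, SENSOR_SITES, SquatLabel
from squatmon.squat_synth import (
    Anthropometry,
    JointTrajectories,
    SquatSimConfig,
    default_class_configs,
    forward_kinematics,
    joint_trajectories,
    make_benchmark,
    noise_free,
    render_imu,
    simulate_squat_trial,
)


class TestJointTrajectories:
    @pytest.mark.parametrize("label", list(SquatLabel))
    def test_zero_severity_reduces_to_correct_execution(self, label):
        base = joint_trajectories(SquatSimConfig(label=SquatLabel.CO, severity=0.0))
        other = joint_trajectories(SquatSimConfig(label=label, severity=0.0))
        for field in ("shank_pitch", "thigh_pitch", "trunk_pitch", "knee_frontal", "ankle_z"):
            np.testing.assert_allclose(getattr(other, field), getattr(base, field))

    def test_shallow_squat_depth_scaling(self):
        co = joint_trajectories(SquatSimConfig(label=SquatLabel.CO))
        sh = joint_trajectories(SquatSimConfig(label=SquatLabel.SH, severity=1.0))
        assert sh.knee_flexion.max() == pytest.approx(0.4 * co.knee_flexion.max())

    def test_cycle_count(self):
        angles = joint_trajectories(SquatSimConfig(n_reps=7))
        from scipy.signal import find_peaks

        maxima, _ = find_peaks(angles.knee_flexion, prominence=0.1)
        assert len(maxima) == 7
        assert len(angles.rep_bounds) == 7

    @pytest.mark.parametrize("label", [l for l in SquatLabel if l != SquatLabel.CO])
    def test_severity_monotone_deviation(self, label):
        base = joint_trajectories(SquatSimConfig(label=SquatLabel.CO))
        devs = []
        for sev in (0.0, 0.3, 0.6, 1.0):
            a = joint_trajectories(SquatSimConfig(label=label, severity=sev))
            d = sum(
                np.abs(getattr(a, f) - getattr(base, f)).mean()
                for f in ("shank_pitch", "thigh_pitch", "trunk_pitch",
                          "knee_frontal", "ankle_z")
            )
            devs.append(d)
        assert all(b >= a - 1e-12 for a, b in zip(devs, devs[1:]))


class TestForwardKinematics:
    def test_standing_pose_is_static(self):
        n = 200
        z = np.zeros(n)
        angles = JointTrajectories(
            t=np.arange(n) / 100.0, shank_pitch=z, thigh_pitch=z, pelvis_pitch=z,
            trunk_pitch=z, knee_frontal=z, ankle_z=z, rate=100.0,
        )
        kin = forward_kinematics(angles)
        for sid in SENSOR_SITES:
            acc = np.gradient(np.gradient(kin[sid].pos, 0.01, axis=0), 0.01, axis=0)
            assert np.abs(acc).max() < 1e-9
            np.testing.assert_allclose(
                kin[sid].quat, np.tile(quat.identity(), (n, 1)), atol=1e-12
            )

    def test_single_link_pendulum_closed_form(self):
        # only the shank rotates: mid-link acceleration = r(θ̈ t̂ − θ̇² r̂)
        rate, A, w = 100.0, 0.4, 2.0
        t = np.arange(1000) / rate
        th = A * np.sin(w * t)
        z = np.zeros_like(t)
        angles = JointTrajectories(
            t=t, shank_pitch=th, thigh_pitch=z, pelvis_pitch=z, trunk_pitch=z,
            knee_frontal=z, ankle_z=z, rate=rate,
        )
        anthro = Anthropometry()
        kin = forward_kinematics(angles, anthro)
        r = anthro.shank_sensor_frac * anthro.shank
        num = np.gradient(np.gradient(kin["shank_L"].pos, 1 / rate, axis=0),
                          1 / rate, axis=0)
        thd = A * w * np.cos(w * t)
        thdd = -A * w * w * np.sin(w * t)
        tang = np.column_stack([np.zeros_like(t), np.cos(th), -np.sin(th)])
        radial = np.column_stack([np.zeros_like(t), np.sin(th), np.cos(th)])
        closed = r * (thdd[:, None] * tang - thd[:, None] ** 2 * radial)
        scale = np.abs(closed).max()
        assert np.abs(num[5:-5] - closed[5:-5]).max() / scale < 1e-3

    def test_left_right_symmetry_without_valgus(self):
        angles = joint_trajectories(SquatSimConfig(label=SquatLabel.CO))
        kin = forward_kinematics(angles)
        np.testing.assert_allclose(kin["shank_L"].quat, kin["shank_R"].quat, atol=1e-12)
        # positions differ only by the constant lateral offset
        dx = kin["shank_R"].pos - kin["shank_L"].pos
        np.testing.assert_allclose(dx[:, 1:], 0.0, atol=1e-12)
        assert np.ptp(dx[:, 0]) < 1e-12

    def test_valgus_breaks_the_symmetry(self):
        angles = joint_trajectories(SquatSimConfig(label=SquatLabel.VK, severity=1.0))
        kin = forward_kinematics(angles)
        assert np.abs(kin["shank_L"].quat - kin["shank_R"].quat).max() > 1e-3


class TestRenderImu:
    def test_zero_motion_reads_exactly_gravity(self):
        n = 300
        z = np.zeros(n)
        angles = JointTrajectories(
            t=np.arange(n) / 100.0, shank_pitch=z, thigh_pitch=z, pelvis_pitch=z,
            trunk_pitch=z, knee_frontal=z, ankle_z=z, rate=100.0,
        )
        cfg = noise_free(SquatSimConfig())
        kin = forward_kinematics(angles)
        trial, truth = render_imu(kin, cfg, angles.t, [(0.0, 1.0)])
        for sid in SENSOR_SITES:
            norms = np.linalg.norm(trial.streams[sid].acc, axis=1)
            np.testing.assert_allclose(norms, G, atol=1e-9)
            np.testing.assert_allclose(truth.acc0g[sid], 0.0, atol=1e-9)

    def test_same_seed_bit_identical(self):
        cfg = SquatSimConfig(n_reps=3, seed=123)
        t1, _ = simulate_squat_trial(cfg)
        t2, _ = simulate_squat_trial(cfg)
        for sid in SENSOR_SITES:
            np.testing.assert_array_equal(t1.streams[sid].acc, t2.streams[sid].acc)
            np.testing.assert_array_equal(t1.streams[sid].gyro, t2.streams[sid].gyro)
            np.testing.assert_array_equal(t1.streams[sid].mag, t2.streams[sid].mag)

    def test_noise_free_trials_are_periodic(self):
        cfg = noise_free(SquatSimConfig(n_reps=4, rep_period=3.0))
        trial, truth = simulate_squat_trial(cfg)
        rate = int(cfg.rate)
        period = int(cfg.rep_period * rate)
        i0 = int(cfg.lead_in_s * rate)
        a = truth.acc0g["sacrum"]
        for k in range(1, 3):  # interior repetitions
            np.testing.assert_allclose(
                a[i0 + k * period: i0 + (k + 1) * period],
                a[i0 + period: i0 + 2 * period],
                atol=1e-9,
            )

    def test_vertical_velocity_integrates_to_zero_per_rep(self):
        cfg = noise_free(SquatSimConfig(n_reps=3))
        angles = joint_trajectories(cfg)
        kin = forward_kinematics(angles, cfg.anthropometry)
        vel = np.gradient(kin["sacrum"].pos[:, 2], 1 / cfg.rate)
        for lo, hi in angles.rep_bounds:
            disp = np.trapezoid(vel[int(lo * cfg.rate): int(hi * cfg.rate)],
                                dx=1 / cfg.rate)
            assert abs(disp) < 1e-3  # returns to standing height


class TestBenchmark:
    def test_counting(self, mini_bench):
        assert len(mini_bench.trials) == 12  # 6 classes × 2 subjects
        assert sum(len(t.rep_bounds) for t in mini_bench.truths) == 60
        assert len(mini_bench.manifest) == 12

    def test_manifest_round_trips_through_trial_io(self, tmp_path):
        from squatmon.imu_model import read_trial

        bench = make_benchmark(
            default_class_configs(n_reps=2), n_subjects=1, seed=5, out_dir=tmp_path
        )
        import pandas as pd

        manifest = pd.read_csv(tmp_path / "manifest.csv")
        assert len(manifest) == 6
        back = read_trial(manifest["path"][0])
        assert back.label == SquatLabel[manifest["label"][0]]
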