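"""Synthetic six-sensor squat trials with analytic ground truth.

An articulated sagittal chain (foot → shank → thigh → pelvis → trunk, with
one frontal-plane degree of freedom at the knee for valgus) performs
raised-cosine squat cycles. Sensor sites mirror the standard montage: mid
shank and mid thigh bilaterally, sacrum, sternum. For each site the model
yields position and orientation over time; the rendered IMU reads

* accelerometer  = Rᵀ (a_kin + g·ẑ)   (specific force, sensor frame),
* gyroscope      = body angular velocity from the orientation track,
* magnetometer   = Rᵀ m_earth          (fixed field direction, 60° dip),

plus white Gaussian channel noise and a constant per-sensor gyro bias drawn
under the config seed. Ground truth carries the exact orientation
quaternions, the analytic gravity-free acceleration, and the repetition
boundary times — the independent oracle for the processing pipeline.

Technique-error classes perturb the base kinematics:

=====  =============================================================
CO     base pattern
KOT    extra shank (ankle dorsiflexion) pitch, severity × 0.3 rad
VK     frontal-plane knee collapse, severity × 0.25 rad, mirrored L/R
RB     extra trunk pitch, severity × 0.5 rad
RH     shank pitch offset + heel-rise vertical excursion at the bottom
SH     knee-flexion depth scaled by (1 − 0.6 × severity)
=====  =============================================================

Severity 0 of any class reduces exactly to CO.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import quaternion as quat
from .errors import ParameterError
from .imu_model import (
    G,
    SENSOR_SITES,
    SensorStream,
    SquatLabel,
    TrialRecording,
    write_trial,
)

# Earth magnetic field direction in ENU: horizontal component due north,
# dipping below the horizon by the inclination angle.
MAG_INCLINATION_RAD = np.deg2rad(60.0)


@dataclass
class Anthropometry:
    shank: float = 0.43   # m
    thigh: float = 0.42   # m
    trunk: float = 0.50   # m
    hip_width: float = 0.30  # m, lateral ankle spacing
    shank_sensor_frac: float = 0.5
    thigh_sensor_frac: float = 0.5
    sternum_frac: float = 0.75  # fraction of trunk length above the pelvis


@dataclass
class SquatSimConfig:
    """Study conditions for one simulated trial."""

    n_reps: int = 10
    rep_period: float = 3.0          # s per repetition
    depth: float = 1.5               # peak knee flexion, rad
    trunk_lean: float = 0.35         # peak trunk pitch, rad
    label: SquatLabel = SquatLabel.CO
    severity: float = 0.8            # error-mode magnitude in [0, 1]
    subject_jitter: float = 0.0      # fractional SD on kinematic parameters
    acc_noise_sd: float = 0.10       # m/s² per channel
    gyro_noise_sd: float = 0.01      # rad/s per channel
    mag_noise_sd: float = 0.005      # unitless per channel
    gyro_bias_sd: float = 0.005      # rad/s, constant per trial & sensor
    rate: float = 100.0              # Hz
    seed: int = 0
    lead_in_s: float = 6.0           # standing rest before the first rep
    tail_s: float = 3.0              # standing rest after the last rep
    anthropometry: Anthropometry = field(default_factory=Anthropometry)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ParameterError("n_reps must be ≥ 1")
        if self.rep_period <= 0:
            raise ParameterError("rep_period must be positive")
        if not (0.0 <= self.severity <= 1.0):
            raise ParameterError("severity must lie in [0, 1]")
        if not (0.0 < self.depth <= np.pi / 2):
            raise ParameterError("depth must lie in (0, π/2]")


def noise_free(config: SquatSimConfig) -> SquatSimConfig:
    """Copy of `config` with every stochastic term switched off."""
    return replace(
        config, acc_noise_sd=0.0, gyro_noise_sd=0.0, mag_noise_sd=0.0,
        gyro_bias_sd=0.0, subject_jitter=0.0,
    )


@dataclass
class JointTrajectories:
    """Sagittal joint-angle time series (rad) on a uniform grid."""

    t: np.ndarray
    shank_pitch: np.ndarray   # forward lean of the shank from vertical
    thigh_pitch: np.ndarray   # backward lean of the thigh (knee→hip)
    pelvis_pitch: np.ndarray
    trunk_pitch: np.ndarray
    knee_frontal: np.ndarray  # valgus collapse magnitude (mirrored L/R)
    ankle_z: np.ndarray       # heel-rise vertical excursion, m
    rate: float
    rep_bounds: list[tuple[float, float]] = field(default_factory=list)

    @property
    def knee_flexion(self) -> np.ndarray:
        return self.shank_pitch + self.thigh_pitch


@dataclass
class SiteKinematics:
    pos: np.ndarray    # (n, 3) Earth frame, m
    quat: np.ndarray   # (n, 4) sensor→Earth


@dataclass
class GroundTruth:
    """Per-sensor exact orientation and gravity-free acceleration."""

    quats: dict[str, np.ndarray]
    acc0g: dict[str, np.ndarray]          # sensor frame, m/s²
    rep_bounds: list[tuple[float, float]]
    label: SquatLabel

    def __post_init__(self) -> None:
        starts = [b[0] for b in self.rep_bounds]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ParameterError("repetition boundaries must be strictly increasing")


def joint_trajectories(config: SquatSimConfig) -> JointTrajectories:
    """Raised-cosine squat cycles with class-specific perturbations (C¹)."""
    total = config.lead_in_s + config.n_reps * config.rep_period + config.tail_s
    n = int(round(total * config.rate)) + 1
    t = np.arange(n) / config.rate

    # activation c(t) ∈ [0, 1]: zero at standing, one at the bottom
    c = np.zeros(n)
    phase = (t - config.lead_in_s) / config.rep_period
    active = (phase >= 0) & (phase <= config.n_reps)
    c[active] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[active]))

    sev = config.severity
    lab = config.label
    depth = config.depth * (1.0 - 0.6 * sev if lab == SquatLabel.SH else 1.0)

    knee = depth * c
    shank = 0.35 * knee
    if lab == SquatLabel.KOT:
        shank = shank + sev * 0.3 * c
    if lab == SquatLabel.RH:
        shank = shank + sev * 0.15 * c
    thigh = knee - 0.35 * knee  # thigh pitch closes the knee-flexion angle
    if lab == SquatLabel.KOT or lab == SquatLabel.RH:
        thigh = knee - shank  # keep flexion depth, redistribute to the shank
        thigh = np.clip(thigh, 0.0, None)

    trunk = config.trunk_lean * c
    if lab == SquatLabel.RB:
        trunk = trunk + sev * 0.5 * c
    pelvis = 0.5 * trunk

    frontal = sev * 0.25 * c if lab == SquatLabel.VK else np.zeros(n)
    ankle_z = sev * 0.05 * c**2 if lab == SquatLabel.RH else np.zeros(n)

    bounds = [
        (config.lead_in_s + k * config.rep_period,
         config.lead_in_s + (k + 1) * config.rep_period)
        for k in range(config.n_reps)
    ]
    return JointTrajectories(
        t=t, shank_pitch=shank, thigh_pitch=thigh, pelvis_pitch=pelvis,
        trunk_pitch=trunk, knee_frontal=frontal, ankle_z=ankle_z,
        rate=config.rate, rep_bounds=bounds,
    )


def _pitch_matrix(theta: np.ndarray) -> np.ndarray:
    """Rotation tilting +z forward (toward +y / north) by theta; (n,3,3)."""
    n = len(theta)
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros((n, 3, 3))
    R[:, 0, 0] = 1.0
    R[:, 1, 1] = c
    R[:, 1, 2] = s
    R[:, 2, 1] = -s
    R[:, 2, 2] = c
    return R


def _roll_matrix(phi: np.ndarray) -> np.ndarray:
    """Rotation about +y (north) tilting +z toward +x (east); (n,3,3)."""
    n = len(phi)
    c, s = np.cos(phi), np.sin(phi)
    R = np.zeros((n, 3, 3))
    R[:, 1, 1] = 1.0
    R[:, 0, 0] = c
    R[:, 0, 2] = s
    R[:, 2, 0] = -s
    R[:, 2, 2] = c
    return R


def forward_kinematics(
    angles: JointTrajectories, anthro: Anthropometry | None = None
) -> dict[str, SiteKinematics]:
    """Sensor-site positions and orientations from joint angles.

    Planar chain with a foot-fixed ankle origin; the frontal-plane knee
    angle rotates shank and thigh out of the sagittal plane with mirrored
    sign on the two legs (valgus = knees collapsing medially).
    """
    a = anthro or Anthropometry()
    if min(a.shank, a.thigh, a.trunk) <= 0:
        raise ParameterError("segment lengths must be positive")
    n = len(angles.t)
    e_z = np.array([0.0, 0.0, 1.0])

    out: dict[str, SiteKinematics] = {}
    hips = {}
    for side, sgn in (("L", 1.0), ("R", -1.0)):
        ankle = np.zeros((n, 3))
        ankle[:, 0] = -sgn * a.hip_width / 2.0  # left leg at −x (west/east=+x)
        ankle[:, 2] = angles.ankle_z

        R_shank = _roll_matrix(sgn * angles.knee_frontal) @ _pitch_matrix(angles.shank_pitch)
        d_shank = R_shank @ e_z
        knee = ankle + a.shank * d_shank
        out[f"shank_{side}"] = SiteKinematics(
            pos=ankle + a.shank_sensor_frac * a.shank * d_shank,
            quat=quat.from_matrix(R_shank),
        )

        R_thigh = _roll_matrix(-sgn * angles.knee_frontal) @ _pitch_matrix(-angles.thigh_pitch)
        d_thigh = R_thigh @ e_z
        hips[side] = knee + a.thigh * d_thigh
        out[f"thigh_{side}"] = SiteKinematics(
            pos=knee + a.thigh_sensor_frac * a.thigh * d_thigh,
            quat=quat.from_matrix(R_thigh),
        )

    pelvis = 0.5 * (hips["L"] + hips["R"])
    R_pelvis = _pitch_matrix(angles.pelvis_pitch)
    out["sacrum"] = SiteKinematics(pos=pelvis, quat=quat.from_matrix(R_pelvis))

    R_trunk = _pitch_matrix(angles.trunk_pitch)
    d_trunk = R_trunk @ e_z
    out["sternum"] = SiteKinematics(
        pos=pelvis + a.sternum_frac * a.trunk * d_trunk,
        quat=quat.from_matrix(R_trunk),
    )
    return out


def _angular_velocity_body(q: np.ndarray, rate: float) -> np.ndarray:
    """Body-frame angular velocity from a quaternion track: ω = 2 vec(q* ⊗ q̇)."""
    qdot = np.gradient(q, 1.0 / rate, axis=0, edge_order=2)
    return 2.0 * quat.qmul(quat.qconj(q), qdot)[:, 1:]


def render_imu(
    kinematics: dict[str, SiteKinematics],
    config: SquatSimConfig,
    t: np.ndarray,
    rep_bounds: list[tuple[float, float]],
) -> tuple[TrialRecording, GroundTruth]:
    """Turn site kinematics into a noisy 9-axis trial plus exact ground truth."""
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.rate
    m_earth = np.array(
        [0.0, np.cos(MAG_INCLINATION_RAD), -np.sin(MAG_INCLINATION_RAD)]
    )
    g_vec = np.array([0.0, 0.0, G])

    streams: dict[str, SensorStream] = {}
    truth_q: dict[str, np.ndarray] = {}
    truth_a: dict[str, np.ndarray] = {}
    for sid in SENSOR_SITES:
        kin = kinematics[sid]
        vel = np.gradient(kin.pos, dt, axis=0, edge_order=2)
        a_kin = np.gradient(vel, dt, axis=0, edge_order=2)
        q = kin.quat
        f_sensor = quat.qrotate_inv(q, a_kin + g_vec)   # specific force
        w_sensor = _angular_velocity_body(q, config.rate)
        m_sensor = quat.qrotate_inv(q, np.broadcast_to(m_earth, (len(t), 3)))

        acc = f_sensor + rng.normal(0.0, config.acc_noise_sd, f_sensor.shape)
        bias = rng.normal(0.0, config.gyro_bias_sd, 3)
        gyro = w_sensor + bias + rng.normal(0.0, config.gyro_noise_sd, w_sensor.shape)
        mag = m_sensor + rng.normal(0.0, config.mag_noise_sd, m_sensor.shape)
        mag = mag / np.linalg.norm(mag, axis=1, keepdims=True)

        streams[sid] = SensorStream(sid, config.rate, t.copy(), acc, gyro, mag)
        truth_q[sid] = q
        truth_a[sid] = quat.qrotate_inv(q, a_kin)

    trial = TrialRecording(
        streams=streams,
        label=config.label,
        meta={"session": "synthetic", "n_reps": config.n_reps,
              "rep_period": config.rep_period, "seed": config.seed},
    )
    truth = GroundTruth(quats=truth_q, acc0g=truth_a, rep_bounds=list(rep_bounds),
                        label=config.label)
    return trial, truth


def simulate_squat_trial(config: SquatSimConfig) -> tuple[TrialRecording, GroundTruth]:
    """Full generator: joint trajectories → forward kinematics → IMU rendering."""
    angles = joint_trajectories(config)
    kin = forward_kinematics(angles, config.anthropometry)
    return render_imu(kin, config, angles.t, angles.rep_bounds)


def default_class_configs(
    n_reps: int = 10, seed: int = 0, **overrides
) -> dict[SquatLabel, SquatSimConfig]:
    """One per-class config at the default study conditions."""
    return {
        lab: SquatSimConfig(label=lab, n_reps=n_reps, seed=seed, **overrides)
        for lab in SquatLabel
    }


@dataclass
class Benchmark:
    trials: list[TrialRecording]
    truths: list[GroundTruth]
    manifest: pd.DataFrame


def make_benchmark(
    configs: Optional[dict[SquatLabel, SquatSimConfig]] = None,
    n_subjects: int = 5,
    seed: int = 0,
    subject_jitter: float = 0.05,
    out_dir: str | Path | None = None,
) -> Benchmark:
    """Labeled trial collection emulating the study design.

    Per subject and class, one trial whose kinematic parameters (depth,
    repetition period, trunk lean) are jittered multiplicatively by the
    subject-level fractional SD; seeds are derived from `seed` so the whole
    collection is reproducible bit-for-bit.
    """
    configs = configs or default_class_configs()
    rng = np.random.default_rng(seed)
    trials, truths, rows = [], [], []
    for subj in range(n_subjects):
        mult = np.clip(1.0 + subject_jitter * rng.normal(size=3), 0.6, 1.4)
        for lab in SquatLabel:
            cfg = replace(
                configs[lab],
                depth=min(configs[lab].depth * mult[0], np.pi / 2),
                rep_period=configs[lab].rep_period * mult[1],
                trunk_lean=configs[lab].trunk_lean * mult[2],
                subject_jitter=subject_jitter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            trial, truth = simulate_squat_trial(cfg)
            trial.meta["subject"] = f"S{subj:02d}"
            trials.append(trial)
            truths.append(truth)
            rows.append(
                {"subject": f"S{subj:02d}", "label": lab.name,
                 "n_reps": cfg.n_reps, "seed": cfg.seed}
            )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for trial, row in zip(trials, manifest.itertuples()):
            p = out_dir / f"trial_{row.subject}_{row.label}.csv"
            write_trial(trial, p)
            paths.append(str(p))
        manifest = manifest.assign(path=paths)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return Benchmark(trials=trials, truths=truths, manifest=manifest)
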