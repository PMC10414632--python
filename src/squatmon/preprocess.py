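"""Low-pass filtering, Mahony attitude estimation and gravity removal.

The batch pipeline mirrors the acquisition chain of a body-worn IMU system:
each sensor's nine channels are low-pass filtered at 20 Hz, a Mahony
complementary filter fuses gyroscope integration with accelerometer (and
optionally magnetometer) direction corrections to track orientation, and the
gravitational component is removed by projecting the specific force into the
Earth frame, subtracting (0, 0, g), and expressing the result back in the
sensor frame. The outcome is the 36-signal gravity-free ("0g") trial: three
0g acceleration and three angular-velocity channels for each of six sensors.

The accelerometer correction is gated on the accelerometer norm: the weight
tapers linearly to zero as |‖a‖ − g| approaches ``gate_width_g × g``, so the
filter coasts on the gyroscope during strongly dynamic phases instead of
chasing a direction that no longer points along gravity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from . import quaternion as quat
from .errors import AlignmentError, ParameterError
from .imu_model import G, SENSOR_SITES, SensorStream, SquatLabel, TrialRecording

logger = logging.getLogger(__name__)


@dataclass
class MahonyGains:
    """Proportional/integral feedback gains of the complementary filter."""

    kp: float = 2.0   # 1/s
    ki: float = 0.1   # 1/s²
    mode: str = "9-axis"  # "6-axis" (acc only) or "9-axis" (acc + mag)
    gate_width_g: float = 0.3  # acc-norm validity gate half-width, in g
    integral_limit: float = 0.2  # rad/s anti-windup clamp on the integral term

    def __post_init__(self) -> None:
        if self.kp <= 0:
            raise ParameterError("kp must be > 0")
        if self.ki < 0:
            raise ParameterError("ki must be ≥ 0")
        if self.mode not in ("6-axis", "9-axis"):
            raise ParameterError(f"unknown mode {self.mode!r}")


@dataclass
class OrientationTrack:
    """Per-sample sensor→Earth quaternions aligned to a stream."""

    quats: np.ndarray       # (n, 4)
    converged: np.ndarray   # (n,) bool
    rate: float

    def __len__(self) -> int:
        return len(self.quats)


@dataclass
class ZeroGTrial:
    """The 36-signal gravity-free dataset: per sensor, 0g acceleration and
    angular velocity (both sensor frame), plus the orientation tracks."""

    t: np.ndarray
    rate: float
    acc0g: dict[str, np.ndarray]
    gyro: dict[str, np.ndarray]
    tracks: dict[str, OrientationTrack]
    label: SquatLabel | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.acc0g.values()}
        lengths |= {len(v) for v in self.gyro.values()}
        if len(lengths) != 1:
            raise AlignmentError("0g channel lengths differ across sensors")
        if set(self.acc0g) != set(SENSOR_SITES):
            raise AlignmentError("expected exactly the six standard sensors")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def earth_vertical_acc(self, sensor_id: str) -> np.ndarray:
        """Earth-frame vertical (+up) component of a sensor's 0g acceleration."""
        return quat.qrotate(self.tracks[sensor_id].quats, self.acc0g[sensor_id])[:, 2]


def lowpass(stream: SensorStream, cutoff: float, order: int = 6) -> SensorStream:
    """Zero-phase Butterworth low-pass over all nine channels (DC gain 1)."""
    nyq = stream.rate / 2.0
    if cutoff >= nyq:
        raise ParameterError(f"cutoff {cutoff} Hz ≥ Nyquist {nyq} Hz")
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if len(stream) <= 3 * order:
        raise ParameterError(f"stream too short ({len(stream)}) for order {order}")
    sos = sps.butter(order, cutoff, btype="low", fs=stream.rate, output="sos")

    def f(x: np.ndarray) -> np.ndarray:
        return sps.sosfiltfilt(sos, x, axis=0)

    return stream.replace(
        acc=f(stream.acc), gyro=f(stream.gyro),
        mag=f(stream.mag) if stream.mag is not None else None,
    )


def lowpass_array(x: np.ndarray, rate: float, cutoff: float, order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth on a bare array (axis 0)."""
    if cutoff >= rate / 2.0:
        raise ParameterError(f"cutoff {cutoff} Hz ≥ Nyquist {rate / 2.0} Hz")
    sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0)


class MahonyFilter:
    """Stateful Mahony attitude estimator (one step per sample).

    Shared by the batch path and the causal real-time path; the convergence
    flag latches once the attitude innovation has stayed below
    ``innovation_threshold`` for a full second.
    """

    def __init__(
        self,
        gains: MahonyGains,
        rate: float,
        q0: np.ndarray | None = None,
        g: float = G,
        innovation_threshold: float = 0.035,  # ≈ sin(2°)
    ):
        self.gains = gains
        self.dt = 1.0 / rate
        self.g = g
        self.q = np.array([1.0, 0.0, 0.0, 0.0]) if q0 is None else quat.qnormalize(q0)
        self.integral = np.zeros(3)
        self.innovation_threshold = innovation_threshold
        self._quiet_samples = 0
        self._quiet_needed = int(round(rate))
        self.converged = False

    def step(self, gyro: np.ndarray, acc: np.ndarray, mag: np.ndarray | None = None) -> np.ndarray:
        # scalar arithmetic throughout: this runs once per sample per sensor
        qw, qx, qy, qz = self.q
        ax, ay, az = float(acc[0]), float(acc[1]), float(acc[2])
        ex = ey = ez = 0.0
        a_norm = (ax * ax + ay * ay + az * az) ** 0.5
        if a_norm > 1e-12:
            # predicted gravity direction in the sensor frame = third row of R
            vx = 2.0 * (qx * qz - qw * qy)
            vy = 2.0 * (qy * qz + qw * qx)
            vz = 1.0 - 2.0 * (qx * qx + qy * qy)
            w = 1.0 - abs(a_norm - self.g) / (self.gains.gate_width_g * self.g)
            if w > 0.0:
                w /= a_norm
                ex = w * (ay * vz - az * vy)
                ey = w * (az * vx - ax * vz)
                ez = w * (ax * vy - ay * vx)
        else:
            logger.warning("zero-norm accelerometer sample: gyro-only propagation")
        if mag is not None and self.gains.mode == "9-axis":
            mx, my, mz = float(mag[0]), float(mag[1]), float(mag[2])
            m_norm = (mx * mx + my * my + mz * mz) ** 0.5
            if m_norm > 1e-12:
                mx, my, mz = mx / m_norm, my / m_norm, mz / m_norm
                h = quat.qrotate(self.q, np.array([mx, my, mz]))
                b = np.array([0.0, float(np.hypot(h[0], h[1])), float(h[2])])
                vm = quat.qrotate_inv(self.q, b)
                ex += my * vm[2] - mz * vm[1]
                ey += mz * vm[0] - mx * vm[2]
                ez += mx * vm[1] - my * vm[0]

        ix, iy, iz = self.integral
        e_mag = (ex * ex + ey * ey + ez * ez) ** 0.5
        # integrate only near equilibrium: the integral tracks slow gyro
        # bias, and accumulating it during large transients (windup) leaves
        # a long-lived attitude offset that kp must fight
        if self.gains.ki > 0 and e_mag < 0.3:
            kidt = self.gains.ki * self.dt
            ix += kidt * ex
            iy += kidt * ey
            iz += kidt * ez
            lim = self.gains.integral_limit
            mag_i = (ix * ix + iy * iy + iz * iz) ** 0.5
            if mag_i > lim:  # anti-windup
                s = lim / mag_i
                ix, iy, iz = ix * s, iy * s, iz * s
            self.integral = np.array([ix, iy, iz])
        kp = self.gains.kp
        ox = float(gyro[0]) + kp * ex + ix
        oy = float(gyro[1]) + kp * ey + iy
        oz = float(gyro[2]) + kp * ez + iz

        hdt = 0.5 * self.dt
        nw = qw - hdt * (qx * ox + qy * oy + qz * oz)
        nx = qx + hdt * (qw * ox + qy * oz - qz * oy)
        ny = qy + hdt * (qw * oy - qx * oz + qz * ox)
        nz = qz + hdt * (qw * oz + qx * oy - qy * ox)
        inv = 1.0 / (nw * nw + nx * nx + ny * ny + nz * nz) ** 0.5
        self.q = np.array([nw * inv, nx * inv, ny * inv, nz * inv])

        if e_mag < self.innovation_threshold:
            self._quiet_samples += 1
            if self._quiet_samples >= self._quiet_needed:
                self.converged = True
        else:
            self._quiet_samples = 0
        return self.q


def attitude_from_acc_mag(acc_mean: np.ndarray, mag_mean: np.ndarray) -> np.ndarray:
    """TRIAD attitude from mean specific force and magnetic field direction.

    Gravity fixes roll/pitch; the horizontal magnetic component fixes yaw
    (ENU: horizontal field points north). Falls back to the gravity-only
    attitude when either vector is degenerate or they are near-collinear.
    """
    a = np.asarray(acc_mean, dtype=float)
    m = np.asarray(mag_mean, dtype=float)
    na, nm = np.linalg.norm(a), np.linalg.norm(m)
    if na < 1e-12 or nm < 1e-12:
        return attitude_from_gravity(a)
    up_s = a / na
    north_s = m / nm - np.dot(m / nm, up_s) * up_s
    nn = np.linalg.norm(north_s)
    if nn < 1e-6:
        return attitude_from_gravity(a)
    north_s /= nn
    east_s = np.cross(north_s, up_s)
    # rows of R map sensor coordinates onto (east, north, up)
    R = np.vstack([east_s, north_s, up_s])
    return quat.from_matrix(R)


def attitude_from_gravity(acc_mean: np.ndarray) -> np.ndarray:
    """Roll/pitch quaternion (yaw 0) aligning a mean specific force with +z up."""
    n = float(np.linalg.norm(acc_mean))
    if n < 1e-12:
        return quat.identity()
    a = acc_mean / n
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.clip(np.dot(a, z), -1.0, 1.0))
    axis = np.cross(a, z)
    s = float(np.linalg.norm(axis))
    if s < 1e-12:
        return quat.identity() if c > 0 else quat.from_axis_angle([1.0, 0.0, 0.0], np.pi)
    return quat.from_axis_angle(axis / s, float(np.arctan2(s, c)))


def estimate_orientation(
    stream: SensorStream,
    gains: MahonyGains | None = None,
    init: np.ndarray | str = "auto",
) -> OrientationTrack:
    """Run the Mahony filter over a uniform-rate stream.

    ``init="auto"`` seeds roll/pitch from the first 0.5 s accelerometer mean
    (yaw 0); 9-axis mode silently degrades to 6-axis when the stream has no
    magnetometer (a warning is logged).
    """
    gains = gains or MahonyGains()
    if gains.mode == "9-axis" and not stream.has_mag:
        logger.warning("%s: magnetometer absent, falling back to 6-axis mode", stream.sensor_id)
        gains = MahonyGains(kp=gains.kp, ki=gains.ki, mode="6-axis",
                            gate_width_g=gains.gate_width_g,
                            integral_limit=gains.integral_limit)
    if isinstance(init, str):
        if init != "auto":
            raise ParameterError(f"unknown init {init!r}")
        n0 = max(1, min(len(stream), int(round(0.5 * stream.rate))))
        if gains.mode == "9-axis" and stream.has_mag:
            q0 = attitude_from_acc_mag(
                stream.acc[:n0].mean(axis=0), stream.mag[:n0].mean(axis=0)
            )
        else:
            q0 = attitude_from_gravity(stream.acc[:n0].mean(axis=0))
    else:
        q0 = np.asarray(init, dtype=float)

    mf = MahonyFilter(gains, stream.rate, q0=q0)
    n = len(stream)
    quats = np.empty((n, 4))
    converged = np.empty(n, dtype=bool)
    use_mag = stream.mag if gains.mode == "9-axis" else None
    for i in range(n):
        quats[i] = mf.step(
            stream.gyro[i], stream.acc[i],
            use_mag[i] if use_mag is not None else None,
        )
        converged[i] = mf.converged
    return OrientationTrack(quats=quats, converged=converged, rate=stream.rate)


def remove_gravity(stream: SensorStream, track: OrientationTrack) -> np.ndarray:
    """Gravity-free acceleration in the sensor frame (m/s²).

    Per sample: rotate the specific force into the Earth frame, subtract
    (0, 0, g), rotate the remainder back. Exact orientation ⇒ exact zeros
    for a static sensor, at any attitude.
    """
    if len(track) != len(stream):
        raise AlignmentError(
            f"track length {len(track)} ≠ stream length {len(stream)}"
        )
    a_earth = quat.qrotate(track.quats, stream.acc)
    a_earth[:, 2] -= G
    return quat.qrotate_inv(track.quats, a_earth)


@dataclass
class PreprocessConfig:
    lowpass_cutoff_hz: float = 20.0
    lowpass_order: int = 6
    gains: MahonyGains = field(default_factory=MahonyGains)
    warmup_s: float = 5.0
    g_mps2: float = G


def simulate_microgravity(
    trial: TrialRecording,
    gains: MahonyGains | None = None,
    config: Optional[PreprocessConfig] = None,
) -> ZeroGTrial:
    """20 Hz low-pass → orientation estimation → gravity removal, per sensor.

    Gyroscope channels pass through filtered only; the result is the
    36-signal gravity-free trial with one orientation track per sensor.
    """
    cfg = config or PreprocessConfig()
    if gains is not None:
        cfg = PreprocessConfig(
            lowpass_cutoff_hz=cfg.lowpass_cutoff_hz, lowpass_order=cfg.lowpass_order,
            gains=gains, warmup_s=cfg.warmup_s, g_mps2=cfg.g_mps2,
        )
    if not trial.aligned():
        raise AlignmentError("trial streams have unequal sample counts; resample first")

    acc0g: dict[str, np.ndarray] = {}
    gyros: dict[str, np.ndarray] = {}
    tracks: dict[str, OrientationTrack] = {}
    t = None
    for sid in SENSOR_SITES:
        filt = lowpass(trial.streams[sid], cfg.lowpass_cutoff_hz, cfg.lowpass_order)
        track = estimate_orientation(filt, cfg.gains)
        acc0g[sid] = remove_gravity(filt, track)
        gyros[sid] = filt.gyro
        tracks[sid] = track
        t = filt.t
    return ZeroGTrial(
        t=t, rate=trial.rate, acc0g=acc0g, gyro=gyros, tracks=tracks,
        label=trial.label, meta={**trial.meta, "warmup_s": cfg.warmup_s},
    )
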