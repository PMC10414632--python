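"""Simulated real-time monitoring: streamed samples → online segmentation →
per-repetition classification with corrective feedback.

The online path mirrors the batch pipeline but is strictly causal: single-
pass (not zero-phase) low-pass filters, an incrementally updated Mahony
attitude per sensor, a leaky-integrated vertical-velocity driver, and a
hysteresis state machine that confirms a valley→peak cycle only after its
trailing zero-crossing plus a short guard interval. Each confirmed cycle is
featurized, scaled and classified with the supplied model bundle, emitting
one MonitorEvent; no event's window ever extends beyond the samples already
streamed when it is emitted.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import signal as sps

from .classify import TrainedModel, predict_report
from .errors import ContractError
from .features import FeatureInventory, default_inventory, extract_features
from .imu_model import SENSOR_SITES, SquatLabel, TrialRecording
from .preprocess import (
    G,
    MahonyFilter,
    MahonyGains,
    attitude_from_acc_mag,
    attitude_from_gravity,
)
from . import quaternion as quat
from .segmentation import RepetitionSegment

logger = logging.getLogger(__name__)

ADVICE_TEXT = {
    "KOT": "sit back: keep knees behind the toes",
    "VK": "push the knees outward",
    "RB": "brace and keep the back neutral",
    "RH": "keep the heels on the floor",
    "SH": "squat deeper: reach parallel",
}


@dataclass
class MonitorEvent:
    rep_index: int
    start_s: float
    end_s: float
    label: SquatLabel
    probs: np.ndarray
    advice: list[str]
    latency_ms: float

    def to_json_dict(self) -> dict:
        return {
            "rep": self.rep_index,
            "span_s": [round(self.start_s, 3), round(self.end_s, 3)],
            "label": self.label.name,
            "probs": {SquatLabel(i).name: round(float(p), 4) for i, p in enumerate(self.probs)},
            "advice": [f"{c}: {ADVICE_TEXT.get(c, c)}" for c in self.advice],
            "latency_ms": round(self.latency_ms, 2),
        }


def stream(trial: TrialRecording, speed: float = np.inf) -> Iterator[dict]:
    """Yield per-timestep six-sensor sample bundles in order.

    Each bundle is ``{"t": float, sensor_id: {"acc": …, "gyro": …, "mag": …}}``.
    A finite speed multiplier sleeps between samples (1.0 = wall-clock rate).
    """
    n = trial.n_samples
    dt = 1.0 / trial.rate
    tref = next(iter(trial.streams.values())).t
    for i in range(n):
        bundle: dict = {"t": float(tref[i])}
        for sid in SENSOR_SITES:
            s = trial.streams[sid]
            bundle[sid] = {
                "acc": s.acc[i], "gyro": s.gyro[i],
                "mag": s.mag[i] if s.mag is not None else None,
            }
        yield bundle
        if np.isfinite(speed) and speed > 0:
            time.sleep(dt / speed)


@dataclass
class OnlineConfig:
    rate: float = 100.0
    lowpass_cutoff_hz: float = 20.0
    lowpass_order: int = 6
    smooth_cutoff_hz: float = 2.0
    driver_sensor: str = "sacrum"
    hp_corner_hz: float = 0.15        # leaky-integrator drift corner
    warmup_s: float = 5.0
    hysteresis: float = 0.08          # driver units (m/s) to confirm extrema
    guard_s: float = 0.25             # post-zero-crossing confirmation delay
    min_rep_s: float = 1.0
    max_rep_s: float = 10.0
    gains: MahonyGains = field(default_factory=MahonyGains)
    inventory: FeatureInventory | None = None


class _CausalLowpass:
    """Stateful multi-channel single-pass Butterworth."""

    def __init__(self, order: int, cutoff: float, rate: float, x0: np.ndarray):
        self.sos = sps.butter(order, cutoff, btype="low", fs=rate, output="sos")
        zi = sps.sosfilt_zi(self.sos)  # (nsect, 2)
        self.zi = zi[:, :, None] * np.asarray(x0, dtype=float)[None, None, :]

    def step(self, x: np.ndarray) -> np.ndarray:
        y, self.zi = sps.sosfilt(self.sos, np.asarray(x, dtype=float)[None, :],
                                 axis=0, zi=self.zi)
        return y[0]


class _SensorState:
    def __init__(self, cfg: OnlineConfig, first: dict):
        self.lp = _CausalLowpass(cfg.lowpass_order, cfg.lowpass_cutoff_hz, cfg.rate,
                                 np.concatenate([first["acc"], first["gyro"]]))
        gains = cfg.gains
        if first["mag"] is None and gains.mode == "9-axis":
            gains = MahonyGains(kp=gains.kp, ki=gains.ki, mode="6-axis",
                                gate_width_g=gains.gate_width_g,
                                integral_limit=gains.integral_limit)
        self.gains = gains
        if gains.mode == "9-axis" and first["mag"] is not None:
            q0 = attitude_from_acc_mag(first["acc"], first["mag"])
        else:
            q0 = attitude_from_gravity(first["acc"])
        self.mahony = MahonyFilter(gains, cfg.rate, q0=q0)
        self.acc0g: list[np.ndarray] = []
        self.gyro: list[np.ndarray] = []
        self.quats: list[np.ndarray] = []

    def step(self, sample: dict) -> None:
        y = self.lp.step(np.concatenate([sample["acc"], sample["gyro"]]))
        acc, gyro = y[:3], y[3:]
        mag = sample["mag"] if self.gains.mode == "9-axis" else None
        q = self.mahony.step(gyro, acc, mag)
        a_e = quat.qrotate(q, acc)
        a_e[2] -= G
        self.acc0g.append(quat.qrotate_inv(q, a_e))
        self.gyro.append(gyro)
        self.quats.append(q)


def online_monitor(
    samples: Iterable[dict],
    model: TrainedModel,
    config: OnlineConfig | None = None,
) -> list[MonitorEvent]:
    """Consume a sample stream and emit one event per confirmed repetition."""
    cfg = config or OnlineConfig()
    inv = cfg.inventory or default_inventory()
    if model.scaler is None:
        raise ContractError("model bundle lacks a fitted scaler")
    unknown = set(model.feature_names) - set(inv.names)
    if unknown:
        raise ContractError(
            f"model features absent from the inventory: {sorted(unknown)[:5]}"
        )

    states: dict[str, _SensorState] = {}
    drv_lp: _CausalLowpass | None = None
    driver: list[float] = []
    vel = 0.0
    alpha = float(np.exp(-2.0 * np.pi * cfg.hp_corner_hz / cfg.rate))
    dt = 1.0 / cfg.rate

    events: list[MonitorEvent] = []
    mode = "seek_valley"
    run_idx = 0
    run_val = np.inf
    valley_idx = peak_idx = -1
    last_zcs: list[int] = []
    pending_zc = -1
    seg_start = None
    warm = int(round(cfg.warmup_s * cfg.rate))
    i = -1

    for bundle in samples:
        i += 1
        if not states:
            for sid in SENSOR_SITES:
                states[sid] = _SensorState(cfg, bundle[sid])
        for sid in SENSOR_SITES:
            states[sid].step(bundle[sid])

        st = states[cfg.driver_sensor]
        a_v = float(quat.qrotate(st.quats[-1], st.acc0g[-1])[2])
        if drv_lp is None:
            drv_lp = _CausalLowpass(6, cfg.smooth_cutoff_hz, cfg.rate, np.array([a_v]))
        a_v = float(drv_lp.step(np.array([a_v]))[0])
        vel = alpha * vel + a_v * dt
        driver.append(vel)
        if i < warm:
            continue

        if len(driver) >= 2 and driver[-2] * driver[-1] < 0:
            last_zcs.append(i)
            if len(last_zcs) > 8:
                last_zcs.pop(0)

        if mode == "seek_valley":
            if vel < run_val:
                run_val, run_idx = vel, i
            if vel >= run_val + cfg.hysteresis:
                valley_idx = run_idx
                before = [z for z in last_zcs if z <= valley_idx]
                seg_start = before[-1] if before else max(warm, valley_idx - int(cfg.max_rep_s * cfg.rate))
                mode, run_val, run_idx = "seek_peak", -np.inf, i
        elif mode == "seek_peak":
            if vel > run_val:
                run_val, run_idx = vel, i
            if vel <= run_val - cfg.hysteresis:
                peak_idx = run_idx
                mode, pending_zc = "await_zc", -1
        elif mode == "await_zc":
            if pending_zc < 0:
                if len(driver) >= 2 and driver[-2] * driver[-1] < 0 and i > peak_idx:
                    pending_zc = i
            elif i - pending_zc >= int(cfg.guard_s * cfg.rate):
                start, end = int(seg_start), int(pending_zc)
                dur = (end - start) / cfg.rate
                if cfg.min_rep_s <= dur <= cfg.max_rep_s:
                    t0 = time.perf_counter()
                    seg = RepetitionSegment(
                        start_idx=start, end_idx=end,
                        acc0g={s: np.vstack(states[s].acc0g[start:end]) for s in SENSOR_SITES},
                        gyro={s: np.vstack(states[s].gyro[start:end]) for s in SENSOR_SITES},
                        rate=cfg.rate, driver_extrema=(valley_idx, peak_idx),
                    )
                    raw = extract_features(seg, inv)
                    scaled = (raw - model.scaler.center) / model.scaler.scale
                    row = pd.Series(scaled, index=model.scaler.feature_names)
                    label, probs, advice = predict_report(model, row)
                    events.append(
                        MonitorEvent(
                            rep_index=len(events), start_s=start / cfg.rate,
                            end_s=end / cfg.rate, label=label, probs=probs,
                            advice=advice,
                            latency_ms=(time.perf_counter() - t0) * 1e3,
                        )
                    )
                else:
                    logger.info("rejected cycle of %.2f s at sample %d", dur, end)
                mode, run_val, run_idx = "seek_valley", np.inf, i
    return events
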