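"""Domain types, unit conventions and file I/O for multi-sensor IMU trials.

Conventions
-----------
* Accelerometer channels are specific force in m/s² expressed in the sensor
  frame: a stationary, level sensor reads ``(0, 0, +g)`` with
  ``g = 9.80665 m/s²``.
* Gyroscope channels are angular velocity in rad/s, sensor frame.
* Magnetometer channels are normalized to unit length on read — orientation
  estimation uses the field *direction* only, which removes device-specific
  scale factors.
* Earth frame is ENU (+x east, +y north, +z up).

The canonical interchange format is a single long-format CSV with header
``sensor_id,t,ax,ay,az,gx,gy,gz,mx,my,mz`` (one row per sample per sensor)
plus a YAML sidecar carrying ``label``, ``subject``, ``session``, ``rate_hz``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, DataError, FormatError, ParameterError

G = 9.80665  # m/s², standard gravity

SENSOR_SITES = ("shank_L", "shank_R", "thigh_L", "thigh_R", "sacrum", "sternum")

CSV_COLUMNS = ["sensor_id", "t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]


class SquatLabel(enum.IntEnum):
    """Execution classes: correct plus the five common technique errors."""

    CO = 0  # correct execution
    KOT = 1  # knees overcoming toes
    VK = 2  # valgus knees
    RB = 3  # rounded back
    RH = 4  # raised heels
    SH = 5  # shallow squat


LABEL_NAMES = tuple(l.name for l in SquatLabel)


class ImuSample(NamedTuple):
    t: float
    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray | None


@dataclass
class SensorStream:
    """One sensor's 9-axis time series (magnetometer optional).

    Channel arrays are ``(n, 3)`` float arrays; ``t`` is seconds. Timestamps
    must be strictly increasing and every channel value finite.
    """

    sensor_id: str
    rate: float
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.mag is not None:
            self.mag = np.asarray(self.mag, dtype=float)
        if self.rate <= 0:
            raise ParameterError(f"rate must be positive, got {self.rate}")
        if len(self.t) and self.t[0] < 0:
            raise DataError(f"{self.sensor_id}: negative timestamp at row 0")
        if len(self.t) > 1:
            bad = np.flatnonzero(np.diff(self.t) <= 0)
            if bad.size:
                raise DataError(
                    f"{self.sensor_id}: non-monotone timestamp at row {bad[0] + 1}"
                )
        for name in ("t", "acc", "gyro"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise DataError(f"{self.sensor_id}: non-finite values in {name}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def has_mag(self) -> bool:
        return self.mag is not None

    def samples(self) -> Iterator[ImuSample]:
        for i in range(len(self.t)):
            yield ImuSample(
                float(self.t[i]),
                self.acc[i],
                self.gyro[i],
                self.mag[i] if self.mag is not None else None,
            )

    def replace(self, **kw) -> "SensorStream":
        d = dict(
            sensor_id=self.sensor_id, rate=self.rate, t=self.t,
            acc=self.acc, gyro=self.gyro, mag=self.mag,
        )
        d.update(kw)
        return SensorStream(**d)


@dataclass
class TrialRecording:
    """Six synchronized sensor streams plus label and free-form metadata."""

    streams: dict[str, SensorStream]
    label: SquatLabel | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in SENSOR_SITES if s not in self.streams]
        if missing:
            raise DataError(f"trial missing sensor streams: {missing}")
        rates = {s.rate for s in self.streams.values()}
        if len(rates) > 1:
            raise DataError(f"streams disagree on rate: {sorted(rates)}")

    @property
    def rate(self) -> float:
        return next(iter(self.streams.values())).rate

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.streams.values())))

    def aligned(self) -> bool:
        ns = {len(s) for s in self.streams.values()}
        return len(ns) == 1


@dataclass
class SensorLayout:
    """Mapping sensor id → body-site description and axis-convention note.

    The axis convention is carried as free text; field practice varies and
    the pipeline itself only assumes right-handed sensor frames.
    """

    sites: dict[str, str]
    axis_note: str = "right-handed; +z proximal along segment, +y anterior at standing"

    def __post_init__(self) -> None:
        if sorted(self.sites) != sorted(SENSOR_SITES):
            raise DataError(f"layout must define exactly the sites {SENSOR_SITES}")


def default_layout() -> SensorLayout:
    return SensorLayout(
        sites={
            "shank_L": "left shank, midpoint lateral malleolus–femoral condyle",
            "shank_R": "right shank, midpoint lateral malleolus–femoral condyle",
            "thigh_L": "left thigh, midpoint femoral condyle–greater trochanter",
            "thigh_R": "right thigh, midpoint femoral condyle–greater trochanter",
            "sacrum": "sacrum, between the posterior superior iliac spines",
            "sternum": "mid sternum",
        }
    )


def _normalize_mag(mag: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(mag, axis=1, keepdims=True)
    out = np.array(mag, dtype=float)
    nz = norms[:, 0] > 0
    out[nz] = mag[nz] / norms[nz]
    return out


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def _plain(value):
    """Coerce numpy scalars (recursively) into YAML-safe built-ins."""
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    return value


def write_trial(trial: TrialRecording, path: str | Path) -> Path:
    """Serialize a trial to the long-format CSV plus its YAML sidecar."""
    path = Path(path)
    frames = []
    for sid in SENSOR_SITES:
        s = trial.streams[sid]
        mag = s.mag if s.mag is not None else np.full_like(s.acc, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "sensor_id": sid,
                    "t": s.t,
                    "ax": s.acc[:, 0], "ay": s.acc[:, 1], "az": s.acc[:, 2],
                    "gx": s.gyro[:, 0], "gy": s.gyro[:, 1], "gz": s.gyro[:, 2],
                    "mx": mag[:, 0], "my": mag[:, 1], "mz": mag[:, 2],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "label": trial.label.name if trial.label is not None else None,
        "subject": trial.meta.get("subject"),
        "session": trial.meta.get("session"),
        "rate_hz": float(trial.rate),
    }
    extra = {k: v for k, v in trial.meta.items() if k not in ("subject", "session")}
    if extra:
        meta["extra"] = extra
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(_plain(meta), fh)
    return path


def read_trial(path: str | Path, layout: SensorLayout | None = None) -> TrialRecording:
    """Read a trial CSV (and sidecar, when present) back into memory.

    Magnetometer columns that are absent or entirely NaN for a sensor yield a
    mag-absent stream; present magnetometer rows are normalized to unit
    direction.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = [c for c in CSV_COLUMNS if c not in ("mx", "my", "mz")]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    has_mag_cols = all(c in df.columns for c in ("mx", "my", "mz"))

    meta: dict = {}
    label = None
    rate_hz = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            side = yaml.safe_load(fh) or {}
        if side.get("label"):
            label = SquatLabel[side["label"]]
        rate_hz = side.get("rate_hz")
        meta = {k: side[k] for k in ("subject", "session") if side.get(k) is not None}
        meta.update(side.get("extra") or {})

    streams: dict[str, SensorStream] = {}
    for sid, block in df.groupby("sensor_id", sort=False):
        t = block["t"].to_numpy(float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            row = int(block.index[bad[0] + 1]) + 1  # 1-based data-row number
            raise DataError(f"{path}: non-monotone timestamp for {sid} at data row {row}")
        rate = float(rate_hz) if rate_hz else (
            float(1.0 / np.median(np.diff(t))) if len(t) > 1 else 100.0
        )
        acc = block[["ax", "ay", "az"]].to_numpy(float)
        gyro = block[["gx", "gy", "gz"]].to_numpy(float)
        mag = None
        if has_mag_cols:
            m = block[["mx", "my", "mz"]].to_numpy(float)
            if np.isfinite(m).all() and len(m):
                mag = _normalize_mag(m)
        streams[str(sid)] = SensorStream(str(sid), rate, t, acc, gyro, mag)

    if layout is not None:
        unknown = set(streams) - set(layout.sites)
        if unknown:
            raise DataError(f"{path}: sensor ids not in layout: {sorted(unknown)}")
    return TrialRecording(streams=streams, label=label, meta=meta)


def resample_align(trial: TrialRecording, rate: float) -> TrialRecording:
    """Linearly interpolate all streams onto one uniform grid at `rate` Hz.

    The grid spans the overlap of the streams' time ranges and never
    extrapolates. Each stream needs at least two samples.
    """
    if rate <= 0:
        raise ParameterError(f"rate must be positive, got {rate}")
    t0 = max(s.t[0] for s in trial.streams.values())
    t1 = min(s.t[-1] for s in trial.streams.values())
    if t1 <= t0:
        raise AlignmentError(
            f"streams have no temporal overlap (max start {t0:.6g} ≥ min end {t1:.6g})"
        )
    for s in trial.streams.values():
        if len(s) < 2:
            raise AlignmentError(f"{s.sensor_id}: need ≥ 2 samples to resample")
    n = int(np.floor((t1 - t0) * rate)) + 1
    grid = t0 + np.arange(n) / rate

    out: dict[str, SensorStream] = {}
    for sid, s in trial.streams.items():
        def interp3(arr: np.ndarray) -> np.ndarray:
            return np.column_stack([np.interp(grid, s.t, arr[:, k]) for k in range(3)])

        mag = None
        if s.mag is not None:
            mag = _normalize_mag(interp3(s.mag))
        out[sid] = SensorStream(sid, float(rate), grid.copy(), interp3(s.acc), interp3(s.gyro), mag)
    return TrialRecording(streams=out, label=trial.label, meta=dict(trial.meta))
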