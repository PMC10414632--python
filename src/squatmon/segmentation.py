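"""Repetition extraction from the gravity-free trial.

A driver signal summarizing whole-body vertical motion is scanned for
alternating valleys and peaks; each valley-then-peak pair is one repetition
cycle, delimited by the last zero-crossing before the valley and the first
zero-crossing after the peak.

The default driver is the sacrum sensor's Earth-frame vertical 0g
acceleration smoothed at 2 Hz and *integrated once* to a drift-corrected
vertical velocity (0.15 Hz high-pass). On velocity the valley/peak are the
instants of fastest descent and ascent and the zero crossings are the
standing turn-points, so segment boundaries coincide with the motion-cycle
boundaries; on raw acceleration the zero crossings fall mid-descent and
mid-ascent, a quarter period away from them. The raw-acceleration driver
remains available via ``SegmentationParams.driver``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .preprocess import ZeroGTrial, lowpass_array

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    sensor_id: str = "sacrum"
    driver: str = "vertical_velocity"  # or "vertical_acceleration"
    smooth_cutoff_hz: float = 2.0
    detrend_cutoff_hz: float = 0.0     # optional high-pass for very drifty data
    baseline_median_s: float = 4.0     # rolling-median baseline window (0 = off)
    min_prominence: float = 0.5        # fraction of the driver's IQR
    min_separation: float = 1.0        # s, between any two retained extrema
    zero_band: float = 0.05            # driver units, zero-crossing fallback
    warmup_s: float = 5.0              # filter convergence window to exclude

    def __post_init__(self) -> None:
        if self.min_prominence <= 0:
            raise ParameterError("min_prominence must be > 0")
        if self.min_separation <= 0:
            raise ParameterError("min_separation must be > 0")


@dataclass
class RepetitionSegment:
    """One repetition: half-open sample interval plus its 36-signal window."""

    start_idx: int
    end_idx: int
    acc0g: dict[str, np.ndarray]
    gyro: dict[str, np.ndarray]
    rate: float
    driver_extrema: tuple[int, int] = (0, 0)  # (valley idx, peak idx)

    def __post_init__(self) -> None:
        if not self.start_idx < self.end_idx:
            raise ParameterError("segment requires start_idx < end_idx")

    def __len__(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate


def driver_signal(
    trial: ZeroGTrial, params: SegmentationParams, period_s: float | None = None
) -> np.ndarray:
    """Build the detection driver from a gravity-free trial.

    When a repetition-period estimate is available the rolling-median
    baseline window is locked to two periods, which zeroes the median of
    the periodic part exactly instead of beating against it.
    """
    acc_v = trial.earth_vertical_acc(params.sensor_id)
    acc_v = lowpass_array(acc_v, trial.rate, params.smooth_cutoff_hz, order=6)
    if params.driver == "vertical_acceleration":
        return acc_v
    if params.driver != "vertical_velocity":
        raise ParameterError(f"unknown driver {params.driver!r}")
    vel = np.cumsum(acc_v) / trial.rate
    if params.detrend_cutoff_hz > 0:
        sos = sps.butter(2, params.detrend_cutoff_hz, btype="high",
                         fs=trial.rate, output="sos")
        vel = sps.sosfiltfilt(sos, vel)
    window_s = 2.0 * period_s if period_s else params.baseline_median_s
    if window_s > 0:
        # integration drift is slowly varying; a centered rolling median
        # pins the standing-rest baseline back onto zero
        from scipy.ndimage import median_filter

        win = int(round(window_s * trial.rate)) | 1
        vel = vel - median_filter(vel, size=min(win, len(vel)), mode="nearest")
    return vel


def detect_extrema(
    x: np.ndarray, params: SegmentationParams, rate: float = 100.0
) -> list[tuple[int, str]]:
    """Ordered local extrema with prominence ≥ min_prominence × IQR.

    min_separation is enforced within each kind (peak-to-peak and
    valley-to-valley); a valley and the following peak of the same movement
    cycle are legitimately closer than that for fast repetitions, so across
    kinds only alternation is enforced — runs of same-kind extrema collapse
    to the most prominent one.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ParameterError("signal too short for extremum detection")
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return []
    prom = params.min_prominence * iqr
    dist = max(1, int(round(params.min_separation * rate)))
    peaks, pprops = sps.find_peaks(x, prominence=prom, distance=dist)
    valleys, vprops = sps.find_peaks(-x, prominence=prom, distance=dist)

    cands = sorted(
        [(int(i), "peak", p) for i, p in zip(peaks, pprops["prominences"])]
        + [(int(i), "valley", p) for i, p in zip(valleys, vprops["prominences"])]
    )
    kept: list[tuple[int, str, float]] = []
    for c in cands:
        if kept and c[1] == kept[-1][1]:
            if c[2] > kept[-1][2]:
                kept[-1] = c
        else:
            kept.append(c)
    return [(i, kind) for i, kind, _ in kept]


def _zero_crossing_before(x: np.ndarray, idx: int, lo: int, band: float) -> int:
    lo = max(lo, 0)
    for j in range(idx - 1, lo - 1, -1):
        if x[j] == 0.0 or x[j] * x[j + 1] < 0:
            return j + 1
    # offset drift: latest sample still inside the zero band
    seg = np.abs(x[lo:idx])
    small = np.flatnonzero(seg < band)
    if small.size:
        return lo + int(small[-1])
    return -1


def _zero_crossing_after(x: np.ndarray, idx: int, hi: int, band: float) -> int:
    hi = min(hi, len(x))
    for j in range(idx, hi - 1):
        if x[j + 1] == 0.0 or x[j] * x[j + 1] < 0:
            return j + 1
    seg = np.abs(x[idx:hi])
    small = np.flatnonzero(seg < band)
    if small.size:
        return idx + int(small[0])
    return -1


def segment_repetitions(
    trial: ZeroGTrial, params: SegmentationParams | None = None
) -> list[RepetitionSegment]:
    """Valley-then-peak cycles of the driver → non-overlapping repetition
    windows bounded by zero crossings (with banded/midpoint fallbacks)."""
    params = params or SegmentationParams()
    x = driver_signal(trial, params)
    extrema = detect_extrema(x, params, rate=trial.rate)
    valleys = [i for i, k in extrema if k == "valley"]
    if len(valleys) >= 2:
        # second pass with the baseline window locked to the rep period
        period = float(np.median(np.diff(valleys))) / trial.rate
        x = driver_signal(trial, params, period_s=period)
        extrema = detect_extrema(x, params, rate=trial.rate)
    skip = int(round(params.warmup_s * trial.rate))
    extrema = [(i, k) for i, k in extrema if i >= skip]
    if not extrema:
        logger.warning("no driver extrema found; returning no segments")
        return []

    # zero-crossing search window: a quarter cycle plus slack, so an offset
    # baseline far from the extremum can never masquerade as a boundary
    spacing = np.diff([i for i, _ in extrema])
    half_cycle = int(np.median(spacing)) if spacing.size else int(
        round(params.min_separation * trial.rate)
    )
    reach = max(int(round(params.min_separation * trial.rate)),
                int(1.2 * half_cycle))

    segs: list[RepetitionSegment] = []
    prev_end = skip
    for a, b in zip(extrema, extrema[1:]):
        if a[1] != "valley" or b[1] != "peak":
            continue
        v_idx, p_idx = a[0], b[0]
        start = _zero_crossing_before(x, v_idx, max(prev_end, v_idx - reach),
                                      params.zero_band)
        if start < 0:  # no crossing and nothing within the zero band
            start = (max(prev_end, v_idx - reach) + v_idx) // 2
            logger.info("segment start fallback to midpoint at %d", start)
        nxt = next((i for i, _ in extrema if i > p_idx), len(x) - 1)
        end = _zero_crossing_after(x, p_idx, min(nxt, p_idx + reach),
                                   params.zero_band)
        if end < 0:
            end = (p_idx + min(nxt, p_idx + reach)) // 2
            logger.info("segment end fallback to midpoint at %d", end)
        if end <= start:
            continue
        segs.append(
            RepetitionSegment(
                start_idx=int(start), end_idx=int(end),
                acc0g={s: a0[start:end] for s, a0 in trial.acc0g.items()},
                gyro={s: g0[start:end] for s, g0 in trial.gyro.items()},
                rate=trial.rate, driver_extrema=(v_idx, p_idx),
            )
        )
        prev_end = end
    if not segs:
        logger.warning("driver extrema found but no complete valley→peak cycles")
    return segs


def segments_to_frame(segs: list[RepetitionSegment], rate: float):
    """Index table `rep_id,start_idx,end_idx,start_s,end_s` for serialization."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rep_id": np.arange(len(segs)),
            "start_idx": [s.start_idx for s in segs],
            "end_idx": [s.end_idx for s in segs],
            "start_s": [s.start_idx / rate for s in segs],
            "end_s": [s.end_idx / rate for s in segs],
        }
    )
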