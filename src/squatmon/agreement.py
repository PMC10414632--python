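"""Paired-sensor agreement statistics for co-located IMU streams.

When two sensor systems are worn superimposed on the same body sites, their
streams should tell the same story. Agreement is quantified per channel by
the time-domain Pearson correlation R and the frequency-domain magnitude
squared coherence, MSC(f) = |P_ab|² / (P_aa P_bb), estimated with Welch
cross-spectra and summarized as the mean over the band where squat energy
lives (0.1–5 Hz by default). MSC is invariant under per-stream linear
filtering and scaling, which makes it the right lens for comparing devices
with different internal filtering chains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .errors import ParameterError
from .imu_model import SENSOR_SITES, SensorStream, TrialRecording

logger = logging.getLogger(__name__)

MSC_REPORT_THRESHOLD = 0.5  # flag, not a hard failure


def align_pair(
    a: SensorStream, b: SensorStream, driver_channel: tuple[str, int] = ("acc", 2)
) -> tuple[SensorStream, SensorStream, int]:
    """Lag-correct stream b against a by maximizing normalized
    cross-correlation of the driver channel; returns the trimmed pair and
    the integer-sample lag applied (positive = b starts later)."""
    if a.rate != b.rate:
        raise ParameterError("resample both streams to a common rate first")
    if min(len(a), len(b)) < 2 * a.rate:
        raise ParameterError("need ≥ 2 s of overlap for alignment")
    xa = getattr(a, driver_channel[0])[:, driver_channel[1]].astype(float)
    xb = getattr(b, driver_channel[0])[:, driver_channel[1]].astype(float)
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    cc = sps.correlate(xa, xb, mode="full")
    norm = np.sqrt(np.sum(xa**2) * np.sum(xb**2))
    lags = sps.correlation_lags(len(xa), len(xb), mode="full")
    if norm > 0:
        peak = float(cc.max() / norm)
        # b[k] = a[k − d] peaks at correlation lag −d; report d
        lag = -int(lags[int(np.argmax(cc))])
    else:
        peak, lag = 0.0, 0
    if peak < 0.2:
        logger.warning("alignment peak %.3f < 0.2; using zero lag", peak)
        lag = 0

    def crop(s: SensorStream, lo: int, hi: int) -> SensorStream:
        return s.replace(
            t=s.t[lo:hi] - s.t[lo], acc=s.acc[lo:hi], gyro=s.gyro[lo:hi],
            mag=s.mag[lo:hi] if s.mag is not None else None,
        )

    # lag > 0: b starts `lag` samples later than a → pair a[k] with b[k+lag]
    if lag >= 0:
        n = min(len(a), len(b) - lag)
        a2, b2 = crop(a, 0, n), crop(b, lag, lag + n)
    else:
        n = min(len(a) + lag, len(b))
        a2, b2 = crop(a, -lag, -lag + n), crop(b, 0, n)
    return a2, b2, lag


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ParameterError("need equal-length series of ≥ 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ParameterError("correlation undefined for a constant series")
    return float(spstats.pearsonr(a, b)[0])


def msc(
    a: np.ndarray,
    b: np.ndarray,
    rate: float,
    window_s: float = 2.0,
    overlap: float = 0.5,
    band: tuple[float, float] = (0.1, 5.0),
) -> tuple[float, np.ndarray, np.ndarray]:
    """Welch magnitude squared coherence.

    Returns (band-mean MSC, per-frequency curve, frequency axis). Hann
    windows of `window_s` seconds at the given fractional overlap; at least
    two windows are required (a single window is identically 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    nper = int(round(window_s * rate))
    noverlap = int(round(nper * overlap))
    if len(a) < nper + (nper - noverlap):
        raise ParameterError(
            f"series of {len(a)} samples gives < 2 Welch windows of {nper}"
        )
    f, c = sps.coherence(a, b, fs=rate, window="hann", nperseg=nper, noverlap=noverlap)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any():
        raise ParameterError(f"no frequency bins inside band {band}")
    return float(np.mean(c[sel])), c, f


@dataclass
class AgreementResult:
    """Per-family summary of a paired-trial comparison."""

    per_channel: pd.DataFrame    # sensor, family, axis, R, MSC
    summary: dict[str, dict[str, float]]  # family → {"R": …, "MSC": …}
    lags: dict[str, int]

    def coherent(self, threshold: float = MSC_REPORT_THRESHOLD) -> dict[str, bool]:
        return {fam: v["MSC"] >= threshold for fam, v in self.summary.items()}


def compare_trials(
    trial_a: TrialRecording,
    trial_b: TrialRecording,
    zerog_a: dict[str, np.ndarray] | None = None,
    zerog_b: dict[str, np.ndarray] | None = None,
    window_s: float = 2.0,
    band: tuple[float, float] = (0.1, 5.0),
) -> AgreementResult:
    """Channel-wise R and band-averaged MSC between two co-located trials.

    Signal families: raw acceleration, angular velocity and (when supplied)
    gravity-free acceleration. The summary averages channels and sensors
    within each family, mirroring a per-subject validation report row.
    """
    rows = []
    lags: dict[str, int] = {}
    for sid in SENSOR_SITES:
        a2, b2, lag = align_pair(trial_a.streams[sid], trial_b.streams[sid])
        lags[sid] = lag
        families: dict[str, tuple[np.ndarray, np.ndarray]] = {
            "acc": (a2.acc, b2.acc),
            "gyro": (a2.gyro, b2.gyro),
        }
        if zerog_a is not None and zerog_b is not None:
            n = len(a2)
            # zero-g arrays are aligned to the original streams; apply the lag
            za, zb = zerog_a[sid], zerog_b[sid]
            if lag >= 0:
                families["acc0g"] = (za[:n], zb[lag:lag + n])
            else:
                families["acc0g"] = (za[-lag:-lag + n], zb[:n])
        for fam, (xa, xb) in families.items():
            for ax, axname in enumerate("xyz"):
                r = pearson_r(xa[:, ax], xb[:, ax])
                m, _, _ = msc(xa[:, ax], xb[:, ax], a2.rate, window_s=window_s, band=band)
                rows.append({"sensor": sid, "family": fam, "axis": axname,
                             "R": r, "MSC": m})
    per_channel = pd.DataFrame(rows)
    summary = {
        fam: {
            "R": float(g["R"].mean()),
            "MSC": float(g["MSC"].mean()),
        }
        for fam, g in per_channel.groupby("family")
    }
    return AgreementResult(per_channel=per_channel, summary=summary, lags=lags)


def report_frame(results: dict[str, AgreementResult]) -> pd.DataFrame:
    """Validation-report table: one row per subject, R and MSC per family,
    plus a mean ± SD row across subjects."""
    rows = []
    for subject, res in results.items():
        s = res.summary
        rows.append(
            {
                "subject": subject,
                "R_acc": s.get("acc", {}).get("R", np.nan),
                "R_0g": s.get("acc0g", {}).get("R", np.nan),
                "R_gyro": s.get("gyro", {}).get("R", np.nan),
                "MSC_acc": s.get("acc", {}).get("MSC", np.nan),
                "MSC_0g": s.get("acc0g", {}).get("MSC", np.nan),
                "MSC_gyro": s.get("gyro", {}).get("MSC", np.nan),
            }
        )
    df = pd.DataFrame(rows)
    mean = df.drop(columns="subject").mean()
    sd = df.drop(columns="subject").std(ddof=1)
    df.loc[len(df)] = {"subject": "mean", **mean.to_dict()}
    df.loc[len(df)] = {"subject": "sd", **sd.to_dict()}
    return df
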