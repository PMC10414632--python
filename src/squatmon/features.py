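"""Per-repetition feature extraction, robust scaling and RFE selection.

Each repetition window yields, per sensor, a family of derived signals:

* time domain (2 Hz smoothed): triaxial 0g acceleration, angular velocity,
  and their jerks (scaled first differences), plus the Euclidean magnitude
  of each;
* frequency domain (one-sided amplitude spectra of the 20 Hz signals):
  triaxial spectra of 0g acceleration, acceleration jerk and angular
  velocity, plus the spectra of all four magnitude signals.

The shipped registry applies the classical activity-recognition statistic
bank to these signals — mean, SD, median absolute deviation, max, min,
signal magnitude area, energy, IQR and entropy in both domains;
fourth-order Burg autoregressive coefficients and axis-pair Pearson
correlations in time; spectral-peak frequency (maxInds), power-weighted
mean frequency, skewness and kurtosis in frequency — for 375 features per
sensor and 2250 over the six-sensor montage. Every statistic is
length-invariant (means rather than sums; spectral amplitudes normalized by
window length), so repetitions of different durations are comparable
without resampling.

Statistic definitions that the name alone does not pin down:

* energy: mean of squares;
* SMA: mean over samples of the across-axis sum of absolute values (plain
  mean absolute value for scalar signals);
* time entropy: Shannon entropy of a 16-bin histogram on the segment's own
  range; frequency entropy: entropy of the power-normalized spectrum;
* maxInds: frequency (Hz) of the largest spectral-amplitude bin;
* spectral skewness/kurtosis: moments of the amplitude values.

Any non-finite statistic (e.g. moments of a degenerate spectrum) is set to
0 with a logged diagnostic, so downstream tables never carry missing
values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.feature_selection import RFE
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import LinearSVC
from statsmodels.regression.linear_model import burg

from .errors import ParameterError
from .imu_model import SENSOR_SITES, SquatLabel
from .preprocess import lowpass_array
from .segmentation import RepetitionSegment

logger = logging.getLogger(__name__)

AR_ORDER = 4
TIME_ENTROPY_BINS = 16
DEFAULT_RFE_COUNT = 769  # default selection size out of 2250

_AXES = ("x", "y", "z")
_PAIRS = ("xy", "xz", "yz")
_T_AX_STATS = ("mean", "std", "mad", "max", "min", "energy", "iqr", "entropy")
_F_AX_STATS = _T_AX_STATS + ("maxInds", "meanFreq", "skewness", "kurtosis")

# (name, triaxial?) in registry order
_TIME_SIGNALS = [("tAcc", True), ("tGyro", True), ("tAccJerk", True), ("tGyroJerk", True),
                 ("tAccMag", False), ("tGyroMag", False),
                 ("tAccJerkMag", False), ("tGyroJerkMag", False)]
_FREQ_SIGNALS = [("fAcc", True), ("fAccJerk", True), ("fGyro", True),
                 ("fAccMag", False), ("fAccJerkMag", False),
                 ("fGyroMag", False), ("fGyroJerkMag", False)]


@dataclass
class FeatureInventory:
    """Ordered registry of (sensor, signal, statistic, axis) features."""

    entries: pd.DataFrame  # columns: sensor, signal, statistic, axis

    @property
    def names(self) -> list[str]:
        return [
            f"{r.sensor}.{r.signal}.{r.statistic}" + (f".{r.axis}" if r.axis else "")
            for r in self.entries.itertuples()
        ]

    @property
    def per_sensor_count(self) -> int:
        return int((self.entries["sensor"] == SENSOR_SITES[0]).sum())

    def __len__(self) -> int:
        return len(self.entries)

    def to_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.entries.copy()
        out.insert(0, "index", np.arange(len(out)))
        out.to_csv(path, sep="\t", index=False)
        return path


def _per_sensor_entries() -> list[tuple[str, str, str]]:
    rows: list[tuple[str, str, str]] = []
    for sig, triax in _TIME_SIGNALS:
        if triax:
            for st in _T_AX_STATS[:5]:
                rows += [(sig, st, ax) for ax in _AXES]
            rows.append((sig, "sma", ""))
            for st in _T_AX_STATS[5:]:
                rows += [(sig, st, ax) for ax in _AXES]
            rows += [(sig, f"arCoeff{k+1}", ax) for ax in _AXES for k in range(AR_ORDER)]
            rows += [(sig, "correlation", p) for p in _PAIRS]
        else:
            rows += [(sig, st, "") for st in _T_AX_STATS[:5]]
            rows.append((sig, "sma", ""))
            rows += [(sig, st, "") for st in _T_AX_STATS[5:]]
            rows += [(sig, f"arCoeff{k+1}", "") for k in range(AR_ORDER)]
    for sig, triax in _FREQ_SIGNALS:
        if triax:
            for st in _F_AX_STATS[:5]:
                rows += [(sig, st, ax) for ax in _AXES]
            rows.append((sig, "sma", ""))
            for st in _F_AX_STATS[5:]:
                rows += [(sig, st, ax) for ax in _AXES]
        else:
            rows += [(sig, st, "") for st in _F_AX_STATS[:5]]
            rows.append((sig, "sma", ""))
            rows += [(sig, st, "") for st in _F_AX_STATS[5:]]
    return rows


def default_inventory() -> FeatureInventory:
    per_sensor = _per_sensor_entries()
    rows = [
        {"sensor": sid, "signal": sig, "statistic": st, "axis": ax}
        for sid in SENSOR_SITES
        for sig, st, ax in per_sensor
    ]
    inv = FeatureInventory(entries=pd.DataFrame(rows))
    names = inv.names
    if len(set(names)) != len(names):
        raise ParameterError("inventory names are not unique")
    return inv


# ---------------------------------------------------------------------------
# derived signals


def _spectrum(x: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum (2|X|/n) and its frequency axis."""
    n = len(x)
    S = np.abs(np.fft.rfft(x, axis=0)) * (2.0 / n)
    f = np.fft.rfftfreq(n, 1.0 / rate)
    return S, f


def derive_signals(
    segment: RepetitionSegment, time_cutoff_hz: float = 2.0
) -> dict[str, dict[str, np.ndarray]]:
    """Named time- and frequency-domain signal set per sensor.

    Time-domain statistics are computed on 2 Hz-smoothed signals (squat
    kinematics live well below 2 Hz); spectra are taken from the 20 Hz
    versions so the frequency statistics retain usable bandwidth.
    """
    n = len(segment)
    if n < 8:
        raise ParameterError(f"segment of {n} samples is too short for features")
    rate = segment.rate
    out: dict[str, dict[str, np.ndarray]] = {}
    for sid in SENSOR_SITES:
        acc20, gyr20 = segment.acc0g[sid], segment.gyro[sid]
        padlen = min(21, n - 2)
        try:
            from scipy.signal import butter, sosfiltfilt

            sos = butter(6, time_cutoff_hz, btype="low", fs=rate, output="sos")
            acc2 = sosfiltfilt(sos, acc20, axis=0, padlen=padlen)
            gyr2 = sosfiltfilt(sos, gyr20, axis=0, padlen=padlen)
        except ValueError:  # pathologically short window: keep the 20 Hz data
            acc2, gyr2 = acc20, gyr20

        def mag(X: np.ndarray) -> np.ndarray:
            return np.linalg.norm(X, axis=1)

        jerk2a = np.diff(acc2, axis=0) * rate
        jerk2g = np.diff(gyr2, axis=0) * rate
        jerk20a = np.diff(acc20, axis=0) * rate
        jerk20g = np.diff(gyr20, axis=0) * rate

        sigs: dict[str, np.ndarray] = {
            "tAcc": acc2, "tGyro": gyr2, "tAccJerk": jerk2a, "tGyroJerk": jerk2g,
            "tAccMag": mag(acc2), "tGyroMag": mag(gyr2),
            "tAccJerkMag": mag(jerk2a), "tGyroJerkMag": mag(jerk2g),
        }
        for name, src in (
            ("fAcc", acc20), ("fAccJerk", jerk20a), ("fGyro", gyr20),
            ("fAccMag", mag(acc20)), ("fAccJerkMag", mag(jerk20a)),
            ("fGyroMag", mag(gyr20)), ("fGyroJerkMag", mag(jerk20g)),
        ):
            S, f = _spectrum(src, rate)
            sigs[name] = S
            sigs[name + "@freqs"] = f
        out[sid] = sigs
    return out


# ---------------------------------------------------------------------------
# statistics


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return float(q75 - q25)


def _time_entropy(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=TIME_ENTROPY_BINS)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def _spectral_entropy(S: np.ndarray) -> float:
    P = S**2
    tot = P.sum()
    if tot <= 0:
        return 0.0
    p = P[P > 0] / tot
    return float(-np.sum(p * np.log(p)))


def _ar_coeffs(x: np.ndarray) -> np.ndarray:
    if np.ptp(x) == 0 or len(x) <= AR_ORDER + 1:
        return np.zeros(AR_ORDER)
    try:
        rho, _ = burg(np.asarray(x, dtype=float), order=AR_ORDER, demean=True)
        return np.asarray(rho, dtype=float)
    except Exception:
        return np.zeros(AR_ORDER)


def _basic_stats(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(x)), "std": float(np.std(x)), "mad": _mad(x),
        "max": float(np.max(x)), "min": float(np.min(x)),
        "energy": float(np.mean(x**2)), "iqr": _iqr(x),
    }


def _time_block(X: np.ndarray, triaxial: bool) -> list[float]:
    vals: list[float] = []
    if triaxial:
        cols = [X[:, k] for k in range(3)]
        for st in _T_AX_STATS[:5]:
            vals += [_basic_stats(c)[st] for c in cols]
        vals.append(float(np.mean(np.sum(np.abs(X), axis=1))))  # sma
        for st in _T_AX_STATS[5:]:
            if st == "entropy":
                vals += [_time_entropy(c) for c in cols]
            else:
                vals += [_basic_stats(c)[st] for c in cols]
        for c in cols:
            vals += list(_ar_coeffs(c))
        with np.errstate(invalid="ignore"):
            for i, j in ((0, 1), (0, 2), (1, 2)):
                sd = np.std(cols[i]) * np.std(cols[j])
                r = float(np.corrcoef(cols[i], cols[j])[0, 1]) if sd > 0 else np.nan
                vals.append(r)
    else:
        b = _basic_stats(X)
        vals += [b[st] for st in _T_AX_STATS[:5]]
        vals.append(float(np.mean(np.abs(X))))  # sma
        vals += [b["energy"], b["iqr"], _time_entropy(X)]
        vals += list(_ar_coeffs(X))
    return vals


def _freq_axis_stats(S: np.ndarray, f: np.ndarray) -> dict[str, float]:
    b = _basic_stats(S)
    P = S**2
    tot = P.sum()
    b["entropy"] = _spectral_entropy(S)
    b["maxInds"] = float(f[int(np.argmax(S))])
    b["meanFreq"] = float(np.sum(f * P) / tot) if tot > 0 else 0.0
    b["skewness"] = float(spstats.skew(S))
    b["kurtosis"] = float(spstats.kurtosis(S))
    return b


def _freq_block(S: np.ndarray, f: np.ndarray, triaxial: bool) -> list[float]:
    vals: list[float] = []
    if triaxial:
        stats = [_freq_axis_stats(S[:, k], f) for k in range(3)]
        for st in _F_AX_STATS[:5]:
            vals += [s[st] for s in stats]
        vals.append(float(np.mean(np.sum(np.abs(S), axis=1))))  # sma
        for st in _F_AX_STATS[5:]:
            vals += [s[st] for s in stats]
    else:
        s = _freq_axis_stats(S, f)
        vals += [s[st] for st in _F_AX_STATS[:5]]
        vals.append(float(np.mean(np.abs(S))))
        vals += [s[st] for st in _F_AX_STATS[5:]]
    return vals


def extract_features(
    segment: RepetitionSegment, inventory: FeatureInventory | None = None
) -> np.ndarray:
    """One feature row (length = inventory size) for a repetition segment."""
    inv = inventory or default_inventory()
    sigs = derive_signals(segment)
    row: list[float] = []
    for sid in SENSOR_SITES:
        s = sigs[sid]
        for name, triax in _TIME_SIGNALS:
            row += _time_block(s[name], triax)
        for name, triax in _FREQ_SIGNALS:
            row += _freq_block(s[name], s[name + "@freqs"], triax)
    out = np.asarray(row, dtype=float)
    if len(out) != len(inv):
        raise ParameterError(
            f"extracted {len(out)} features but inventory declares {len(inv)}"
        )
    bad = ~np.isfinite(out)
    if bad.any():
        names = np.asarray(inv.names, dtype=object)[bad]
        logger.debug("non-finite features set to 0: %s", list(names[:5]))
        out[bad] = 0.0
    return out


# ---------------------------------------------------------------------------
# table assembly, scaling, selection


@dataclass
class FeatureTable:
    """Repetitions × features matrix with labels and provenance."""

    values: pd.DataFrame                 # columns = feature names
    labels: np.ndarray | None = None     # SquatLabel integer codes
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ParameterError("feature table contains missing values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.values):
                raise ParameterError("labels length ≠ table rows")

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path) -> Path:
        df = self.values.copy()
        if self.labels is not None:
            df["label"] = [SquatLabel(l).name for l in self.labels]
        df.to_csv(path, index=False)
        return Path(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        labels = None
        if "label" in df.columns:
            labels = np.array([SquatLabel[v].value for v in df.pop("label")])
        return cls(values=df, labels=labels)


def build_feature_table(
    segments: Sequence[RepetitionSegment],
    labels: Sequence[int] | None = None,
    inventory: FeatureInventory | None = None,
    provenance: pd.DataFrame | None = None,
) -> FeatureTable:
    inv = inventory or default_inventory()
    rows = [extract_features(s, inv) for s in segments]
    values = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, len(inv))),
                          columns=inv.names)
    return FeatureTable(
        values=values,
        labels=None if labels is None else np.asarray(labels, dtype=int),
        provenance=provenance,
    )


@dataclass
class ScalerParams:
    """Robust scaler: per-feature median center and IQR scale (train rows only)."""

    center: np.ndarray
    scale: np.ndarray
    constant: np.ndarray  # features with zero IQR (scale forced to 1)
    feature_names: list[str]


def fit_scaler(table: FeatureTable, train_rows: np.ndarray | None = None) -> ScalerParams:
    mask = np.ones(table.n_rows, dtype=bool) if train_rows is None else np.asarray(train_rows)
    if mask.dtype != bool:
        m = np.zeros(table.n_rows, dtype=bool)
        m[mask] = True
        mask = m
    if mask.sum() < 2:
        raise ParameterError("need at least 2 training rows to fit the scaler")
    X = table.values.to_numpy(float)[mask]
    center = np.median(X, axis=0)
    q75, q25 = np.percentile(X, [75, 25], axis=0)
    scale = q75 - q25
    constant = scale <= 0
    scale = np.where(constant, 1.0, scale)
    return ScalerParams(center=center, scale=scale, constant=constant,
                        feature_names=list(table.values.columns))


def apply_scaler(table: FeatureTable, params: ScalerParams) -> FeatureTable:
    if list(table.values.columns) != params.feature_names:
        raise ParameterError("feature names do not match the fitted scaler")
    X = (table.values.to_numpy(float) - params.center) / params.scale
    return FeatureTable(
        values=pd.DataFrame(X, columns=params.feature_names),
        labels=table.labels, provenance=table.provenance,
    )


def inverse_scale(table: FeatureTable, params: ScalerParams) -> FeatureTable:
    X = table.values.to_numpy(float) * params.scale + params.center
    return FeatureTable(values=pd.DataFrame(X, columns=params.feature_names),
                        labels=table.labels, provenance=table.provenance)


@dataclass
class SelectedFeatureSet:
    names: list[str]
    target_count: int
    ranking: np.ndarray | None = None  # RFE rank per inventory feature (1 = kept)
    cv_scores: dict[int, float] | None = None


def _rfe_estimator(seed: int) -> LinearSVC:
    # linear maximal-margin base estimator; coefficient magnitudes rank features
    return LinearSVC(C=1.0, dual=False, max_iter=5000, random_state=seed)


def select_features_rfe(
    table: FeatureTable,
    labels: np.ndarray | None = None,
    target_count: int | Sequence[int] = DEFAULT_RFE_COUNT,
    seed: int = 0,
    step: float = 0.05,
    cv: int = 5,
) -> SelectedFeatureSet:
    """Recursive feature elimination on a scaled table.

    With a sweep list, each candidate count is evaluated by stratified CV
    accuracy of the base estimator on the selected columns and the best
    count wins (ties → fewer features).
    """
    y = table.labels if labels is None else np.asarray(labels, dtype=int)
    if y is None:
        raise ParameterError("labels are required for supervised selection")
    X = table.values.to_numpy(float)
    n_feat = X.shape[1]
    counts = [target_count] if np.isscalar(target_count) else list(target_count)
    if any(c > n_feat or c < 1 for c in counts):
        raise ParameterError(f"target_count out of range 1..{n_feat}: {counts}")

    def run(count: int) -> tuple[list[str], np.ndarray]:
        if count == n_feat:
            return list(table.values.columns), np.ones(n_feat, dtype=int)
        rfe = RFE(_rfe_estimator(seed), n_features_to_select=count, step=step)
        rfe.fit(X, y)
        names = [c for c, keep in zip(table.values.columns, rfe.support_) if keep]
        return names, rfe.ranking_

    if len(counts) == 1:
        names, ranking = run(int(counts[0]))
        return SelectedFeatureSet(names=names, target_count=int(counts[0]), ranking=ranking)

    scores: dict[int, float] = {}
    best: tuple[float, int] | None = None
    results: dict[int, tuple[list[str], np.ndarray]] = {}
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    for count in sorted(int(c) for c in counts):
        names, ranking = run(count)
        idx = [table.values.columns.get_loc(nm) for nm in names]
        acc = float(np.mean(cross_val_score(_rfe_estimator(seed), X[:, idx], y, cv=skf)))
        scores[count] = acc
        results[count] = (names, ranking)
        if best is None or acc > best[0]:
            best = (acc, count)
    names, ranking = results[best[1]]
    return SelectedFeatureSet(names=names, target_count=best[1], ranking=ranking,
                              cv_scores=scores)


def screen_rows(
    table: FeatureTable,
    raw: pd.DataFrame | None = None,
    min_duration_s: float = 1.0,
    max_duration_s: float = 10.0,
    max_bad_frac: float = 0.01,
) -> np.ndarray:
    """Optional outlier screen (disabled by default in the pipeline):
    keep rows whose raw feature vector is < `max_bad_frac` non-finite and
    whose segment duration lies in [min, max] seconds. Returns a keep-mask."""
    keep = np.ones(table.n_rows, dtype=bool)
    if raw is not None:
        frac = (~np.isfinite(raw.to_numpy(float))).mean(axis=1)
        keep &= frac <= max_bad_frac
    if table.provenance is not None and "duration_s" in table.provenance:
        d = table.provenance["duration_s"].to_numpy(float)
        keep &= (d >= min_duration_s) & (d <= max_duration_s)
    return keep
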