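"""Feature inventory, extraction statistics, scaling and RFE."""

import numpy as np
import pandas as pd
import pytest

from squatmon.errors import ParameterError
from squatmon.features import (
    FeatureTable,
    apply_scaler,
    build_feature_table,
    default_inventory,
    derive_signals,
    extract_features,
    fit_scaler,
    inverse_scale,
    select_features_rfe,
)
from squatmon.imu_model import SENSOR_SITES
from squatmon.segmentation import RepetitionSegment


def _segment(acc_fn, gyro_fn=None, n=300, rate=100.0):
    t = np.arange(n) / rate
    acc = acc_fn(t)
    gyro = gyro_fn(t) if gyro_fn else np.zeros((n, 3))
    return RepetitionSegment(
        start_idx=0, end_idx=n,
        acc0g={sid: acc.copy() for sid in SENSOR_SITES},
        gyro={sid: gyro.copy() for sid in SENSOR_SITES},
        rate=rate,
    )


class TestInventory:
    def test_declared_counts(self):
        inv = default_inventory()
        assert len(inv) == 2250
        assert inv.per_sensor_count == 375
        assert len(set(inv.names)) == 2250

    def test_manifest_round_trip(self, tmp_path):
        inv = default_inventory()
        p = inv.to_manifest(tmp_path / "feature_manifest.tsv")
        back = pd.read_csv(p, sep="\t")
        assert list(back.columns) == ["index", "sensor", "signal", "statistic", "axis"]
        assert len(back) == 2250


class TestDeriveSignals:
    def test_constant_acc_gives_zero_jerk(self):
        seg = _segment(lambda t: np.full((len(t), 3), 1.7))
        sigs = derive_signals(seg)
        assert np.abs(sigs["sacrum"]["tAccJerk"]).max() < 1e-9

    def test_sine_jerk_amplitude(self):
        f0 = 1.0
        seg = _segment(
            lambda t: np.column_stack([np.sin(2 * np.pi * f0 * t)] * 3), n=1000
        )
        sigs = derive_signals(seg, time_cutoff_hz=2.0)
        amp = np.abs(sigs["sacrum"]["tAccJerk"][:, 0]).max()
        assert abs(amp - 2 * np.pi * f0) / (2 * np.pi * f0) < 0.02

    def test_magnitude_of_constant_vector(self):
        seg = _segment(lambda t: np.tile([3.0, 4.0, 0.0], (len(t), 1)))
        sigs = derive_signals(seg)
        np.testing.assert_allclose(sigs["sacrum"]["tAccMag"], 5.0, atol=1e-9)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ParameterError):
            derive_signals(_segment(lambda t: np.zeros((len(t), 3)), n=5))


class TestExtractFeatures:
    def test_row_length_is_2250(self, zerog_noisy):
        from squatmon.segmentation import segment_repetitions

        zg, _ = zerog_noisy
        seg = segment_repetitions(zg)[0]
        row = extract_features(seg, default_inventory())
        assert row.shape == (2250,)
        assert np.isfinite(row).all()

    def test_constant_signal_statistics(self):
        c = 2.0
        seg = _segment(lambda t: np.full((len(t), 3), c))
        inv = default_inventory()
        row = pd.Series(extract_features(seg, inv), index=inv.names)
        assert row["sacrum.tAcc.mean.x"] == pytest.approx(c)
        assert row["sacrum.tAcc.std.x"] == pytest.approx(0.0, abs=1e-9)
        assert row["sacrum.tAcc.mad.x"] == pytest.approx(0.0, abs=1e-9)
        assert row["sacrum.tAcc.max.x"] == pytest.approx(c)
        assert row["sacrum.tAcc.min.x"] == pytest.approx(c)
        assert row["sacrum.tAcc.energy.x"] == pytest.approx(c**2)
        assert row["sacrum.tAcc.iqr.x"] == pytest.approx(0.0, abs=1e-9)
        assert row["sacrum.tAcc.sma"] == pytest.approx(3 * c)

    def test_single_tone_spectral_statistics(self):
        f0 = 0.5
        seg = _segment(
            lambda t: np.column_stack([np.sin(2 * np.pi * f0 * t)] * 3), n=1000
        )
        inv = default_inventory()
        row = pd.Series(extract_features(seg, inv), index=inv.names)
        assert abs(row["sacrum.fAcc.meanFreq.x"] - f0) < 0.1
        assert row["sacrum.fAcc.maxInds.x"] == pytest.approx(f0, abs=0.051)

    def test_sensor_permutation_equivariance(self, zerog_noisy):
        from squatmon.segmentation import segment_repetitions

        zg, _ = zerog_noisy
        seg = segment_repetitions(zg)[0]
        inv = default_inventory()
        row = extract_features(seg, inv)
        # swap two sensors' data: the corresponding feature blocks swap
        import copy

        seg2 = copy.copy(seg)
        seg2.acc0g = dict(seg.acc0g)
        seg2.gyro = dict(seg.gyro)
        seg2.acc0g["shank_L"], seg2.acc0g["thigh_R"] = seg.acc0g["thigh_R"], seg.acc0g["shank_L"]
        seg2.gyro["shank_L"], seg2.gyro["thigh_R"] = seg.gyro["thigh_R"], seg.gyro["shank_L"]
        row2 = extract_features(seg2, inv)
        sens = np.array(inv.entries["sensor"])
        np.testing.assert_allclose(row2[sens == "shank_L"], row[sens == "thigh_R"])
        np.testing.assert_allclose(row2[sens == "sacrum"], row[sens == "sacrum"])


class TestScaler:
    def _table(self, X):
        return FeatureTable(values=pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])]))

    def test_hand_computed_median_iqr(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        table = self._table(X)
        params = fit_scaler(table)
        assert params.center[0] == 3.0 and params.scale[0] == 2.0
        scaled = apply_scaler(table, params)
        assert scaled.values.iloc[4, 0] == pytest.approx(1.0)

    def test_constant_feature_scales_to_zero(self):
        X = np.column_stack([np.full(6, 7.0), np.arange(6.0)])
        table = self._table(X)
        params = fit_scaler(table)
        assert params.constant[0] and not params.constant[1]
        scaled = apply_scaler(table, params)
        np.testing.assert_allclose(scaled.values.iloc[:, 0], 0.0)

    def test_no_test_row_leakage(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        table = self._table(X)
        train = np.zeros(20, bool)
        train[:10] = True
        p_train = fit_scaler(table, train)
        p_all = fit_scaler(table)
        assert not np.allclose(p_train.center, p_all.center)

    def test_scale_then_inverse_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        table = self._table(X)
        params = fit_scaler(table)
        back = inverse_scale(apply_scaler(table, params), params)
        np.testing.assert_allclose(back.values.to_numpy(), X, atol=1e-12)

    def test_empty_training_mask_rejected(self):
        with pytest.raises(ParameterError):
            fit_scaler(self._table(np.zeros((4, 2))), np.zeros(4, bool))


class TestRFE:
    def _planted(self, n=240, n_feat=100, n_inf=10, seed=0):
        rng = np.random.default_rng(seed)
        y = np.repeat(np.arange(6), n // 6)
        X = rng.normal(size=(n, n_feat))
        centers = rng.normal(scale=3.0, size=(6, n_inf))
        X[:, :n_inf] += centers[y]
        cols = [f"inf{i}" for i in range(n_inf)] + [f"noise{i}" for i in range(n_feat - n_inf)]
        return FeatureTable(values=pd.DataFrame(X, columns=cols), labels=y)

    def test_recovers_planted_informative_features(self):
        table = self._planted()
        sel = select_features_rfe(table, target_count=10, seed=0)
        hits = sum(1 for n in sel.names if n.startswith("inf"))
        assert hits >= 8

    def test_identity_selection_at_full_count(self):
        table = self._planted(n_feat=20, n_inf=5)
        sel = select_features_rfe(table, target_count=20, seed=0)
        assert sel.names == list(table.values.columns)

    def test_target_above_feature_count_rejected(self):
        table = self._planted(n_feat=20, n_inf=5)
        with pytest.raises(ParameterError):
            select_features_rfe(table, target_count=21)

    def test_sweep_returns_scores(self):
        table = self._planted()
        sel = select_features_rfe(table, target_count=[5, 10, 50], seed=0, cv=3)
        assert sel.cv_scores is not None and sel.target_count in (5, 10, 50)
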