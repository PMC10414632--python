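"""Shared fixtures: synthetic trials, gravity-free pipelines, small benchmark."""

from __future__ import annotations

import numpy as np
import pytest

from squatmon import quaternion as quat
from squatmon.imu_model import G, SENSOR_SITES, SensorStream, SquatLabel, TrialRecording
from squatmon.pipeline import benchmark_to_dataset, fit_model
from squatmon.preprocess import simulate_microgravity
from squatmon.squat_synth import (
    MAG_INCLINATION_RAD,
    SquatSimConfig,
    make_benchmark,
    noise_free,
    simulate_squat_trial,
)


def static_trial(
    quats: dict[str, np.ndarray] | None = None,
    duration_s: float = 10.0,
    rate: float = 100.0,
    rng: np.random.Generator | None = None,
) -> TrialRecording:
    """Six stationary sensors at fixed orientations reading pure specific force."""
    n = int(duration_s * rate)
    t = np.arange(n) / rate
    g_vec = np.array([0.0, 0.0, G])
    m_earth = np.array([0.0, np.cos(MAG_INCLINATION_RAD), -np.sin(MAG_INCLINATION_RAD)])
    rng = rng or np.random.default_rng(0)
    streams = {}
    for sid in SENSOR_SITES:
        q = quats[sid] if quats else quat.identity()
        acc = np.tile(quat.qrotate_inv(q, g_vec), (n, 1))
        mag = np.tile(quat.qrotate_inv(q, m_earth), (n, 1))
        streams[sid] = SensorStream(sid, rate, t.copy(), acc, np.zeros((n, 3)), mag)
    return TrialRecording(streams=streams, label=None, meta={})


def random_unit_quaternions(n: int, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


@pytest.fixture(scope="session")
def clean_trial():
    cfg = noise_free(SquatSimConfig(n_reps=10, seed=7))
    return simulate_squat_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial():
    return simulate_squat_trial(SquatSimConfig(n_reps=10, seed=7))


@pytest.fixture(scope="session")
def zerog_clean(clean_trial):
    trial, truth = clean_trial
    return simulate_microgravity(trial), truth


@pytest.fixture(scope="session")
def zerog_noisy(noisy_trial):
    trial, truth = noisy_trial
    return simulate_microgravity(trial), truth


@pytest.fixture(scope="session")
def mini_bench():
    """Small labeled benchmark: 6 classes × 2 subjects × 5 reps."""
    from squatmon.squat_synth import default_class_configs

    return make_benchmark(default_class_configs(n_reps=5), n_subjects=2, seed=11)


@pytest.fixture(scope="session")
def mini_dataset(mini_bench):
    return benchmark_to_dataset(mini_bench)


@pytest.fixture(scope="session")
def mini_model(mini_dataset):
    return fit_model(mini_dataset, algo="MLP", seed=11)
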