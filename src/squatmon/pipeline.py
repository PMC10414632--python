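"""End-to-end batch pipeline helpers: trial → segments → features → model."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import TrainedModel, train
from .features import (
    FeatureInventory,
    FeatureTable,
    apply_scaler,
    build_feature_table,
    default_inventory,
    fit_scaler,
)
from .imu_model import TrialRecording
from .preprocess import MahonyGains, PreprocessConfig, ZeroGTrial, simulate_microgravity
from .segmentation import RepetitionSegment, SegmentationParams, segment_repetitions
from .squat_synth import Benchmark

logger = logging.getLogger(__name__)


def trial_to_segments(
    trial: TrialRecording,
    pre: PreprocessConfig | None = None,
    seg: SegmentationParams | None = None,
) -> tuple[ZeroGTrial, list[RepetitionSegment]]:
    zg = simulate_microgravity(trial, config=pre)
    return zg, segment_repetitions(zg, seg)


@dataclass
class Dataset:
    """Assembled repetitions × features dataset with provenance."""

    table: FeatureTable
    inventory: FeatureInventory


def benchmark_to_dataset(
    bench: Benchmark,
    pre: PreprocessConfig | None = None,
    seg: SegmentationParams | None = None,
    inventory: FeatureInventory | None = None,
) -> Dataset:
    """Run every benchmark trial through the batch pipeline and stack rows."""
    inv = inventory or default_inventory()
    segments: list[RepetitionSegment] = []
    labels: list[int] = []
    prov_rows = []
    for ti, trial in enumerate(bench.trials):
        _, segs = trial_to_segments(trial, pre, seg)
        if not segs:
            logger.warning("trial %d produced no segments", ti)
        for ri, s in enumerate(segs):
            segments.append(s)
            labels.append(int(trial.label))
            prov_rows.append(
                {"trial": ti, "rep": ri, "subject": trial.meta.get("subject"),
                 "duration_s": s.duration_s}
            )
    table = build_feature_table(
        segments, labels, inv, provenance=pd.DataFrame(prov_rows)
    )
    return Dataset(table=table, inventory=inv)


def fit_model(
    dataset: Dataset,
    algo: str = "MLP",
    seed: int = 0,
    select_count: int | None = None,
) -> TrainedModel:
    """Scale (train rows only), optionally RFE-select, and train one model."""
    from sklearn.model_selection import train_test_split

    from .features import select_features_rfe

    y = dataset.table.labels
    idx = np.arange(dataset.table.n_rows)
    tr, _ = train_test_split(idx, test_size=0.3, stratify=y, random_state=seed)
    mask = np.zeros(len(idx), dtype=bool)
    mask[tr] = True
    scaler = fit_scaler(dataset.table, mask)
    scaled = apply_scaler(dataset.table, scaler)
    fset = None
    if select_count is not None:
        fset = select_features_rfe(scaled, y, target_count=select_count, seed=seed)
    model = train(scaled, y, algo=algo, seed=seed, scaler=scaler, feature_set=fset)
    return model
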