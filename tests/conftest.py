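"""Shared fixtures: small hand-built epoch sets, norms and designs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from contextrsa import EpochSet, FeatureNorms


def make_trials(conditions: list[str], keep: list[bool] | None = None) -> pd.DataFrame:
    n = len(conditions)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n),
            "scene_id": [f"scene_{i:04d}" for i in range(n)],
            "object_label": [f"concept_{i:04d}" for i in range(n)],
            "condition": conditions,
            "keep": keep if keep is not None else [True] * n,
        }
    )


def make_epochs(
    data: np.ndarray,
    conditions: list[str] | None = None,
    tstep: float = 5.0,
    tmin: float = -20.0,
    subject_id: str = "sub-001",
    keep: list[bool] | None = None,
) -> EpochSet:
    n_trials, n_channels, n_times = data.shape
    if conditions is None:
        conditions = ["congruent" if i % 2 == 0 else "incongruent" for i in range(n_trials)]
    times = tmin + tstep * np.arange(n_times)
    return EpochSet(
        subject_id=subject_id,
        data=np.asarray(data, dtype=float),
        times=times,
        channel_names=[f"EEG{c + 1:03d}" for c in range(n_channels)],
        sfreq=1000.0 / tstep,
        trials=make_trials(conditions, keep),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_epochs(rng) -> EpochSet:
    """12 trials × 8 channels × 25 timepoints of white noise, −20..100 ms."""
    return make_epochs(rng.standard_normal((12, 8, 25)))


@pytest.fixture
def small_norms() -> FeatureNorms:
    concepts = ["zebra", "car", "apple", "piano"]
    features = ["has_stripes", "eats_grass", "has_wheels", "is_edible", "makes_sound"]
    values = np.array(
        [
            [1, 1, 0, 0, 1],
            [0, 0, 1, 0, 1],
            [0, 0, 0, 1, 0],
            [0, 0, 0, 0, 1],
        ],
        dtype=float,
    )
    return FeatureNorms(concepts, features, values)
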