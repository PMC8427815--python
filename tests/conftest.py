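"""Shared fixtures: small synthetic studies and hand-built feature tables."""

import numpy as np
import pandas as pd
import pytest

from hfdeeg import (
    HfdConfig,
    SynthConfig,
    extract_features,
    generate_dataset,
    load_montage,
)

TEST_CHANNELS = ["FCz", "CPz", "F2", "Oz", "C3", "P4"]


@pytest.fixture(scope="session")
def small_montage():
    return load_montage("dataset2").subset(TEST_CHANNELS)


@pytest.fixture(scope="session")
def effect_dataset(small_montage):
    """Two groups with a complexity increase (Hurst drop) at FCz and CPz."""
    cfg = SynthConfig(
        montage=small_montage,
        n_groups=2,
        group_labels=("pain", "nopain"),
        participants_per_group=4,
        trials_per_task=10,
        tasks=("LH",),
        sampling_rate=250.0,
        group_effect={"pain": {"FCz": -0.15, "CPz": -0.15}},
        participant_sd=0.01,
        seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def effect_features(effect_dataset):
    return extract_features(effect_dataset, HfdConfig())


def synthetic_feature_table(
    n_participants_per_group=3,
    n_trials=10,
    channels=("A", "B", "C"),
    informative=(),
    effect=1.0,
    tasks=("LH",),
    offsets=(0.0,),
    noise_sd=1.0,
    seed=0,
):
    """Gaussian feature table built directly (no EEG synthesis): channels in
    ``informative`` carry a group mean shift of ``effect`` for group 'a'."""
    rng = np.random.default_rng(seed)
    rows = []
    for group in ("a", "b"):
        for p in range(n_participants_per_group):
            pid = f"{group}{p}"
            for trial in range(n_trials):
                for task in tasks:
                    for ch in channels:
                        for off in offsets:
                            mu = effect if (group == "a" and ch in informative) else 0.0
                            rows.append(
                                (group, pid, trial, task, ch, off,
                                 mu + noise_sd * rng.standard_normal())
                            )
    return pd.DataFrame(
        rows,
        columns=["group", "participant", "trial", "task", "channel",
                 "window_offset", "hfd"],
    )
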