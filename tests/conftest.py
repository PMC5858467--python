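import numpy as np
import pandas as pd
import pytest

import neuroad as na
from neuroad.preprocessing import TABLE_COLUMNS


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale cohort: 6 subjects x 8 trials, short ads."""
    return na.SyntheticConfig(
        n_subjects=6,
        trials_per_subject=8,
        total_trials=None,
        trial_duration_range=(15.0, 16.0),
        effect_size=1.5,
        label_noise=0.1,
        rejection_rate=0.05,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    recs, labels, _ = na.generate_cohort(small_config, keep_abnormal=True)
    return na.build_dataset(recs, labels)


@pytest.fixture(scope="session")
def strong_config():
    """Study-sized cohort with strong EEG-emotion coupling and low noise."""
    return na.SyntheticConfig(effect_size=2.0, label_noise=0.05, seed=7)


@pytest.fixture(scope="session")
def strong_dataset(strong_config):
    recs, labels, _ = na.generate_cohort(strong_config)
    return na.build_dataset(recs, labels)


@pytest.fixture(scope="session")
def null_config():
    """Decoupled cohort: EEG carries no information about the answers."""
    return na.SyntheticConfig(effect_size=0.0, label_noise=0.1, seed=11)


@pytest.fixture(scope="session")
def null_dataset(null_config):
    recs, labels, _ = na.generate_cohort(null_config)
    return na.build_dataset(recs, labels)


def make_series(
    n_timestamps,
    subject="S01",
    ad="car_01",
    category="car",
    seed=0,
    band_values=None,
):
    """Dummy per-timestamp feature records for structural tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(0.0, index=range(n_timestamps), columns=TABLE_COLUMNS)
    df["TimeStamp"] = np.arange(n_timestamps)
    df["Attention"] = 50.0
    df["Meditation"] = 50.0
    for col in TABLE_COLUMNS[5:]:
        df[col] = band_values if band_values is not None else rng.uniform(0, 10, n_timestamps)
    return na.BandFeatureSeries(subject, ad, category, df)
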