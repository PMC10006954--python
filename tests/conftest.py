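import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cowfeed import (
    CNNClassifier,
    WindowStore,
    generate_file_set,
    windows_from_recording,
)
from cowfeed.augment import augment_training_set
from cowfeed.synthetic import SyntheticConfig, source_profile_config

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: desk-scale study conditions shared by the slower tests: 10 s windows with
#: 50% overlap on 20-minute cow-day recordings.  Mean bout durations are
#: scaled down with the file length so each cow-day file still holds a
#: realistic mix of ~15 bouts (a full day holds on the order of 80).
WINDOW_S = 10.0
OVERLAP = 0.5
FILE_DURATION_S = 1200.0
SCALED_BOUT_MEANS = (90.0, 95.0, 70.0)


def scaled_cfg(**kw) -> SyntheticConfig:
    kw.setdefault("mean_bout_durations", SCALED_BOUT_MEANS)
    return SyntheticConfig(**kw)


def scaled_source_cfg(**kw) -> SyntheticConfig:
    kw.setdefault("mean_bout_durations", SCALED_BOUT_MEANS)
    return source_profile_config(**kw)


def build_store(cfg: SyntheticConfig) -> WindowStore:
    return WindowStore.concat(
        [
            windows_from_recording(rec, bouts, WINDOW_S, OVERLAP)
            for rec, bouts in generate_file_set(cfg, duration_s=FILE_DURATION_S)
        ]
    )


@pytest.fixture(scope="session")
def target12_store() -> WindowStore:
    """12 cow-day files of the lossy 25 Hz collar profile."""
    return build_store(scaled_cfg(n_cows=12, days_per_cow=1, rng_seed=3))


@pytest.fixture(scope="session")
def source_store() -> WindowStore:
    """8 cow-day files of the lossless 10 Hz profile, resampled to 25 Hz."""
    return build_store(scaled_source_cfg(n_cows=8, days_per_cow=1, rng_seed=101))


@pytest.fixture(scope="session")
def pretrained_cnn2(source_store) -> CNNClassifier:
    """Source-profile CNN2 used as the transfer-learning base."""
    rng = np.random.default_rng(1)
    train = augment_training_set(source_store, rng)
    return CNNClassifier(
        architecture="cnn2", conv_filters=(16, 16), epochs=20, random_state=0
    ).fit(train.X, train.y)


@pytest.fixture(scope="session")
def pretrained_cnn2_ensemble(source_store) -> list[CNNClassifier]:
    """Independently pretrained source models, one per experiment seed, so
    transfer results average over the pretraining draw as well."""
    models = []
    for s in range(5):
        rng = np.random.default_rng(100 + s)
        train = augment_training_set(source_store, rng)
        models.append(
            CNNClassifier(
                architecture="cnn2", conv_filters=(16, 16), epochs=20, random_state=s
            ).fit(train.X, train.y)
        )
    return models


@pytest.fixture()
def toy_windows():
    """Three linearly separable constant-signal classes, 64-sample windows."""
    rng = np.random.default_rng(42)
    levels = np.array([[0.8, 0.8, 0.8], [-0.5, 0.3, -0.2], [0.0, -0.6, 0.4]])
    X, y = [], []
    for k in range(3):
        for _ in range(30):
            w = np.tile(levels[k], (64, 1)) + rng.normal(0, 0.05, (64, 3))
            X.append(w)
            y.append(k)
    return np.array(X, dtype=np.float32), np.array(y)
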