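import numpy as np
import pytest

import wristemg as w

# Desk-scale study conditions: one 3.15 s recording per movement at the
# default 0.2 s / 0.05 s windowing yields exactly 60 windows per class.
DESK_DURATION = 3.15
DESK_SEED = 11
TRAIN_SEED = 7
TRAIN_ITERATIONS = 5000


@pytest.fixture(scope="session")
def desk_recordings():
    config = w.GeneratorConfig(duration=DESK_DURATION, seed=DESK_SEED)
    return w.generate_dataset(1, config=config)


@pytest.fixture(scope="session")
def desk_features(desk_recordings):
    return w.extract_dataset(desk_recordings)


@pytest.fixture(scope="session")
def desk_selected(desk_features):
    weights = w.relieff_weights(desk_features)
    return w.select_top_per_channel(weights, per_channel=2)


@pytest.fixture(scope="session")
def desk_trained(desk_features, desk_selected):
    """Model + report trained at the study conditions: 16 selected
    features, lr 0.001, full-batch, 80/20 stratified split."""
    fm16 = w.project_features(desk_features, desk_selected)
    model, report = w.train(
        fm16,
        w.TrainConfig(iterations=TRAIN_ITERATIONS, seed=TRAIN_SEED),
    )
    return model, report


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
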