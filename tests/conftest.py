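import warnings

import numpy as np
import pytest

from eegindex import (
    LabeledFeatures,
    PipelineConfig,
    SyntheticConfig,
    generate_session,
)
from eegindex.pipeline import preprocess_and_features


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig(seed=7)


@pytest.fixture(scope="session")
def planted_features(default_config):
    """Neutral and happiness feature matrices from one planted subject.

    Generated once per test session: 40 s calibration sessions (160
    quarter-second windows each) with the default happiness effects at
    multiplier 2.5.
    """
    cfg = SyntheticConfig(session_length=40.0, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        neutral = preprocess_and_features(
            generate_session(cfg, "neutral"), default_config
        )
        happiness = preprocess_and_features(
            generate_session(cfg, "happiness"), default_config
        )
    return neutral, happiness


@pytest.fixture(scope="session")
def planted_labeled(planted_features):
    neutral, happiness = planted_features
    return LabeledFeatures.from_sessions(neutral, happiness)
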