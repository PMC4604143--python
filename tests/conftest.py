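import numpy as np
import pytest

from beatclass import FeatureTableSpec, SyntheticSpec, gen_ecg_stream, gen_feature_table


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free stream with planted PVCs (fixed seed)."""
    return gen_ecg_stream(SyntheticSpec(duration=120, pvc_rate=0.1,
                                        noise_rms=0.0, seed=1))


@pytest.fixture(scope="session")
def small_table():
    """Small labeled feature table (300/class) for classifier tests."""
    X, y, basic = gen_feature_table(FeatureTableSpec(n_per_class=300, seed=7))
    return X, y, basic


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
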