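import numpy as np
import pytest

from figlipase.synth import SimConfig, default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def neutral_ref(panel):
    return next(r for r in panel if r.family == "neutral")


@pytest.fixture(scope="session")
def acid_ref(panel):
    return next(r for r in panel if r.family == "acid")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_config():
    return SimConfig(seed=42)
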