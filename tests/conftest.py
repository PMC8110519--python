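import numpy as np
import pytest

from freezeloop.synth import SyntheticConfig, generate_session


@pytest.fixture(scope="session")
def short_session():
    """One 300 s synthetic session shared by the heavier analysis tests."""
    cfg = SyntheticConfig(seed=42, session_duration=300.0)
    return generate_session(cfg, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
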