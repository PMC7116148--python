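import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import infermap as im


@pytest.fixture(scope="session")
def small_cfg():
    """A quick 2-day session config with all planted effects."""
    return im.make_demo_config(0, n_days=2)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return im.generate_session(small_cfg)


@pytest.fixture(scope="session")
def demo_session():
    """The full 8-day demo session (shared; do not mutate)."""
    cfg = im.make_demo_config(0)
    return cfg, *im.generate_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
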