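import logging

import numpy as np
import pytest

from drgrade import SynthConfig, builtin_ruleset, generate_dataset

# polygon-outside-frame and zero-count-ratio warnings are expected in
# adversarial tests; keep the output readable
logging.getLogger("drgrade").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def ruleset():
    return builtin_ruleset()


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory):
    """Small rendered dataset shared by io/pipeline tests."""
    out = tmp_path_factory.mktemp("synthds")
    cfg = SynthConfig(n_per_class=3, image_size=512, seed=7)
    manifest = generate_dataset(cfg, out)
    return out, cfg, manifest
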