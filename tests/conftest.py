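import logging

import numpy as np
import pytest

from ccistiff.cli_io import RunConfig, run_pipeline
from ccistiff.synthetic_data import GeneratorConfig, make_gait_trial, make_subject

logging.getLogger("ccistiff").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def subject(gen_config):
    return make_subject(gen_config, seed=7)


@pytest.fixture(scope="session")
def small_trial(subject, gen_config):
    """3-cycle coupled trial with ground truth (shared across tests)."""
    return make_gait_trial(subject, 3, "coupled", seed=7, config=gen_config)


@pytest.fixture(scope="session")
def pipeline_dir(tmp_path_factory):
    """One full (small) pipeline run on disk, shared across io tests."""
    out = tmp_path_factory.mktemp("pipe")
    cfg = RunConfig(seed=11, n_cycles=3, out_dir=str(out))
    run_pipeline(cfg, out)
    return out, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
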