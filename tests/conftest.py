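import numpy as np
import pytest

from rtcit import DesignSpec, RunConfig, run_pipeline, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_design():
    return DesignSpec()


@pytest.fixture(scope="session")
def small_cohort():
    """20 participants, full design; shared across read-only tests."""
    return simulate_cohort(20, seed=202)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-size pipeline run, shared across tests."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(seed=7, output_dir=str(out))
    summary = run_pipeline(cfg)
    return cfg, summary, out
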