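import numpy as np
import pytest

from soilvirome.pipeline import PipelineConfig, run_pipeline
from soilvirome.simulate import SimulationConfig, generate_community

# the stated default world: 20 hosts, 50 viruses, 3 habitats x 10 samples
DEFAULT_SEED = 7


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def community(default_config):
    """Default synthetic community shared by the recovery tests."""
    return generate_community(default_config)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full end-to-end pipeline run on the default community."""
    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    config = PipelineConfig(outdir=str(outdir), seed=DEFAULT_SEED)
    manifest = run_pipeline(config)
    return outdir, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
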