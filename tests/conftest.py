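import numpy as np
import pytest

from glibind import RunConfig, run_pipeline
from glibind.simulate import simulate_study

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study():
    """One synthetic study, shared across tests (deterministic)."""
    return simulate_study(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A full pipeline run on the default synthetic study."""
    outdir = tmp_path_factory.mktemp("pipeline")
    report = run_pipeline(RunConfig(seed=STUDY_SEED), outdir)
    return report, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
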