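import numpy as np
import pytest
from hypothesis import settings

from diverseq.pipeline import (
    default_toy_config,
    run_pipeline,
    snp_recovery_config,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """The default end-to-end toy pipeline run (20 transcripts, 7 samples,
    5k reads per sample); shared across tests because it is the expensive
    fixture."""
    outdir = tmp_path_factory.mktemp("toy_run")
    cfg = default_toy_config(outdir=str(outdir), seed=0)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """The planted-variant recovery experiment run."""
    outdir = tmp_path_factory.mktemp("recovery_run")
    return run_pipeline(snp_recovery_config(outdir=str(outdir), seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
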