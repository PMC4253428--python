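import pytest

from surfscan.config import SimConfig
from surfscan.simulate import generate_reference, spike_variants


SMALL = SimConfig(n_cell_lines=4, n_genes=12, mean_cds_length=300, seed=7)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SMALL


@pytest.fixture(scope="session")
def small_panel(small_config):
    """(reference, models, truth) for a small deterministic panel."""
    reference, models = generate_reference(small_config)
    truth = spike_variants(reference, models, small_config)
    return reference, models, truth


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, small_config):
    """A complete pipeline run directory shared across report/CLI tests."""
    from surfscan.pipeline import run_pipeline
    out = tmp_path_factory.mktemp("run")
    run_pipeline(small_config, out)
    return out
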