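import pytest

from lignopipe.synth import enrichment_scenario, hul_panel, write_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """Inoculum + one 3-transfer series at reduced depth, error rate 0.01."""
    return enrichment_scenario(seed=7, n_reads_per_sample=6000, error_rate=0.01, series=("W",))


@pytest.fixture(scope="session")
def scenario_dir(small_scenario, tmp_path_factory):
    """The small scenario materialized as pipeline-ready files."""
    d = tmp_path_factory.mktemp("scenario")
    config = write_scenario(small_scenario, d, seed=7)
    return d, config


@pytest.fixture(scope="session")
def contig_panel():
    """Planted 30-contig panel spanning the HUL rule boundaries."""
    return hul_panel(seed=11)
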