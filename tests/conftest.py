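import pytest

from dinet import PipelineConfig, run_synthetic_end_to_end, simulate_truth
from dinet.synthetic_data import simulate_sequences


@pytest.fixture()
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_truth():
    """The default study conditions with a fixed seed."""
    return simulate_truth(seed=0)


@pytest.fixture(scope="session")
def default_run(default_truth):
    """Full pipeline run on the default seeded dataset."""
    return run_synthetic_end_to_end(default_truth)


@pytest.fixture(scope="session")
def small_truth():
    """A small planted dataset for sequence/motif tests."""
    return simulate_truth(seed=3, n_genes=40, n_variants=20)


@pytest.fixture(scope="session")
def small_sequences(small_truth):
    genome, pwms, marks = simulate_sequences(small_truth)
    return genome, pwms, marks
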