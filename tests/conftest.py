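import pytest

from riboqc import (
    DigestionParams,
    footprints_from_truth,
    generate_transcriptome,
    simulate_footprints,
)


@pytest.fixture(scope="session")
def transcriptome():
    """Small heterogeneous transcriptome shared across tests."""
    return generate_transcriptome(50, seed=11)


@pytest.fixture(scope="session")
def complete_sample(transcriptome):
    """A completely digested sample: reads, truth and footprints."""
    params = DigestionParams(completeness=1.0, seed=23)
    reads, truth = simulate_footprints(transcriptome, params, 10_000)
    return reads, truth, footprints_from_truth(truth, transcriptome)


@pytest.fixture(scope="session")
def incomplete_sample(transcriptome):
    """An incompletely digested sample (completeness 0.3)."""
    params = DigestionParams(completeness=0.3, seed=23)
    reads, truth = simulate_footprints(transcriptome, params, 10_000)
    return reads, truth, footprints_from_truth(truth, transcriptome)
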