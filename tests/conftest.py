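import pytest

from capkit import capture_qc, synthetic_data as sd


@pytest.fixture(scope="session")
def panel_metrics():
    """Published 43-specimen capture-panel sequencing metrics."""
    return capture_qc.load_panel_metrics()


@pytest.fixture(scope="session")
def small_transcriptome():
    """A mixed-copy-number transcriptome shared across selection tests."""
    return sd.make_transcriptome(
        n_transcripts=300,
        length_range=(200, 1000),
        copy_number_weights={1: 0.8, 10: 0.2},
        seed=11,
    )
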