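import pytest

from apa3seq import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest simulated experiment shared by read-level tests."""
    cfg = SimulationConfig(n_transcripts=30, depth_per_transcript=150, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_evidence(small_dataset):
    from apa3seq import cs_discovery

    return cs_discovery.detect_tails(
        small_dataset.all_reads(), small_dataset.accessor
    )
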