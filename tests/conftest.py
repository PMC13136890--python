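import pytest

from poremod import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_bundle():
    """Paired dataset under default modification effects (deletion-dominant
    error elevation, 3-SD mean shift, SD inflation, offset dwell slowdown)."""
    cfg = SimConfig(seed=11, n_reads_control=200, n_reads_modified=200)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_bundle():
    """Paired dataset with every modification effect disabled — the modified
    label is exchangeable with the control label."""
    cfg = SimConfig.null(seed=5, n_reads_control=150, n_reads_modified=150)
    return simulate_dataset(cfg)
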