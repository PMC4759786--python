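import pytest

from phasetox.synthgen import CohortConfig, generate_cohort
from phasetox.traceclass import ClassifierThresholds


@pytest.fixture(scope="session")
def noiseless_config() -> CohortConfig:
    return CohortConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def thresholds() -> ClassifierThresholds:
    return ClassifierThresholds()


@pytest.fixture(scope="session")
def big_cohort():
    """10 000 cells (100 cultures x 100) for law-of-large-numbers checks."""
    cfg = CohortConfig(n_cultures=100, cells_per_culture=100, seed=20260901)
    return generate_cohort(cfg)
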