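import numpy as np
import pytest

from radfusion.synthetic import SimulationConfig, generate_cohort, records_to_frame


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample cohort with modest bank widths, shared across tests."""
    cfg = SimulationConfig.pdac_like(n_samples=60, seed=42,
                                     n_features_bankR=80, block_sizes=(4, 5))
    bank_r, bank_t, records = generate_cohort(cfg)
    return bank_r, bank_t, records_to_frame(records)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
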