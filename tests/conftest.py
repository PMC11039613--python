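import numpy as np
import pytest

from stasis_scan.config import SimulationConfig
from stasis_scan.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Compact, fully assembled dataset: clean clusters, no degradation."""
    return SimulationConfig(
        seed=11,
        n_species=2,
        members_per_species=4,
        n_genes=30,
        mean_gene_len=80,
        mu_cp=0.008,
        recomb_events_per_genome=1,
        import_length_mean=300,
        completeness_range=(100, 100),
        contamination_range=(0, 0),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def degraded_dataset():
    """MAG-style degradation: partial completeness plus planted contamination."""
    cfg = SimulationConfig(
        seed=23,
        n_species=2,
        members_per_species=4,
        n_genes=30,
        mean_gene_len=80,
        mu_cp=0.005,
        completeness_range=(60, 90),
        contamination_range=(5, 5),
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
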