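import numpy as np
import pytest

from orthozip import SimulationConfig, simulate_proteomes


@pytest.fixture(scope="session")
def two_species_cohort():
    """Small two-species cohort with duplications and mild divergence."""
    cfg = SimulationConfig(
        species_labels=("aspec", "bspec"),
        n_ancestral_genes=8,
        duplication_rate=0.3,
        substitution_rate=0.02,
        bzip_fraction=0.5,
        mean_protein_length=110,
        seed=42,
    )
    return simulate_proteomes(cfg)


@pytest.fixture(scope="session")
def frozen_cohort():
    """Zero-evolution cohort: identical proteomes, one-to-one truth."""
    cfg = SimulationConfig(
        species_labels=("aspec", "bspec"),
        n_ancestral_genes=5,
        duplication_rate=0.0,
        substitution_rate=0.0,
        bzip_fraction=0.4,
        mean_protein_length=100,
        seed=1,
    )
    return simulate_proteomes(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
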