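import numpy as np
import pytest

from mtartifact import (
    CircularGenome,
    ExperimentConfig,
    generate_genome,
    make_mtdna_like_genome,
)


@pytest.fixture(scope="session")
def small_genome() -> CircularGenome:
    """A 4 kb circular genome with a unique GGATCC planted at 3500."""
    return make_mtdna_like_genome(4000, 0.44, seed=11, site_position=3500)


@pytest.fixture(scope="session")
def mt_like_genome() -> CircularGenome:
    """Full-length synthetic mtDNA stand-in: 16,569 bp, one GGATCC at 14258."""
    return make_mtdna_like_genome(seed=42)


@pytest.fixture(scope="session")
def linear_genome() -> CircularGenome:
    return CircularGenome("lin", "ACGT" * 500, is_circular=False)


@pytest.fixture
def desk_config() -> ExperimentConfig:
    """Down-scaled experiment config used by pipeline-level tests: half-length
    genome at the default per-strand coverage (~600x)."""
    return ExperimentConfig(
        genome_length=8285,
        site_position=7129,
        target_fragment_count=35500,
        n_copies=1000,
        seed=1,
    )


@pytest.fixture
def tiny_config() -> ExperimentConfig:
    """Very small config for fast wiring tests (coverage still ~100x)."""
    return ExperimentConfig(
        genome_length=3000,
        site_position=2500,
        target_fragment_count=1100,
        n_copies=200,
        reads_per_region=60,
        regions=[
            (6, 298, "+", "D-Loop"),
            (577, 765, "+", "tRNA-F+12S"),
            (1500, 1650, "-", "16S-like"),
        ],
        seed=7,
    )
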