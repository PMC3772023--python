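import numpy as np
import pytest

from tumoronly import (
    CohortConfig,
    PopulationModel,
    build_germline_pool,
    simulate_cohort,
    simulate_panel,
    synthetic_annotations,
)
from tumoronly.variants import VariantKey


def vk(pos, chrom="1", ref="A", alt="C"):
    """Shorthand variant key for constructed examples."""
    return VariantKey(chrom, pos, ref, alt)


@pytest.fixture(scope="session")
def small_genome():
    return synthetic_annotations(n_genes=300, n_drivers=5, seed=11)


@pytest.fixture(scope="session")
def small_pool(small_genome):
    pop = PopulationModel(n_germline_sites=25_000)
    return build_germline_pool(pop, small_genome, seed=12)


@pytest.fixture(scope="session")
def small_panel(small_pool):
    return simulate_panel(small_pool, 30, "JPT", seed=13)


@pytest.fixture(scope="session")
def small_cohort(small_genome, small_pool):
    cfg = CohortConfig(n_patients=24, somatic_per_patient=60.0)
    return simulate_cohort(cfg, small_pool, small_genome, seed=14)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
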