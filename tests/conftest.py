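import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import driptools as dt


@pytest.fixture(scope="session")
def small_cfg() -> dt.SynthConfig:
    """A desk-scale study: 300 genes, all four sorted cell populations."""
    return dt.SynthConfig(n_genes=300, chrom_length=16_000_000, seed=42)


@pytest.fixture(scope="session")
def genome(small_cfg):
    genes, sites, chrom_sizes, _ = dt.make_genome(small_cfg)
    return genes, sites, chrom_sizes


@pytest.fixture(scope="session")
def regions(genome, small_cfg):
    genes, _, chrom_sizes = genome
    return dt.build_regions(genes, chrom_sizes)


@pytest.fixture(scope="session")
def study(genome, regions, small_cfg):
    """Simulated counts + ground truth for the session-wide study."""
    genes, sites, chrom_sizes = genome
    counts, truth = dt.simulate_drip_counts(genes, small_cfg, regions)
    return counts, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
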