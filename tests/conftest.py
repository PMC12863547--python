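import numpy as np
import pytest

from ddcfdna import (
    SimulationConfig,
    alt_ratio_profile,
    build_allele_kmers,
    random_panel,
    simulate_spikein,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_panel():
    """A 20-SNP synthetic panel with 61-bp variant-centered contexts."""
    return random_panel(n_snps=20, k=31, seed=5)


@pytest.fixture(scope="session")
def small_kmers(small_panel):
    result = build_allele_kmers(small_panel)
    assert not result.excluded
    return result


@pytest.fixture(scope="session")
def spikein():
    """One simulated mixing experiment under the default study conditions."""
    config = SimulationConfig(mixture_fractions=(0.0, 0.01, 0.05, 0.10), seed=11)
    return simulate_spikein(config)


@pytest.fixture(scope="session")
def spikein_profiles(spikein):
    return {f: alt_ratio_profile(t) for f, t in spikein.counts.items()}
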