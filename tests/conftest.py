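import numpy as np
import pytest

from finishkit import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    """600 kb genome with a tandem array and planted gap-prone motifs."""
    cfg = sim.GenomeConfig(length=600_000, n_gc_tracts=6, n_homopolymers=6,
                           tandem_arrays=[sim.TandemArraySpec(unit_length=5000,
                                                              copies=4)])
    genome, truth = sim.simulate_genome(cfg, seed=100)
    return genome, truth


@pytest.fixture(scope="session")
def small_library(small_genome):
    genome, _ = small_genome
    clones = sim.simulate_bac_library(
        genome, sim.BacConfig(n_clones=40, mean_length=120_000,
                              sd_length=10_000), seed=101)
    fps = sim.simulate_fingerprints(clones, sim.FingerprintConfig(), seed=102)
    return genome, clones, fps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
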