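import numpy as np
import pytest

from andromix.genotypes_io import HaplotypeMatrix
from andromix.synthetic_data import SimulationConfig, simulate_divergent_lineages


@pytest.fixture(scope="session")
def small_panel():
    """Two well-diverged lineages, 8 strains each, on two small windows."""
    cfg = SimulationConfig(
        n_individuals=60, n_generations=500, n_sampled_strains=8,
        seq_length=150_000, n_contigs=2, selfing_rate=0.9, seed=11,
    )
    return simulate_divergent_lineages(cfg, n_lineages=2,
                                       split_generations=900)


@pytest.fixture
def tiny_matrix():
    """Hand-built 3 strains x 4 sites on two contigs."""
    return HaplotypeMatrix(
        strains=["s1", "s2", "s3"],
        lineages=["A", "A", "B"],
        contigs=np.array(["c1", "c1", "c2", "c2"], dtype=object),
        positions=np.array([10, 250, 40, 90]),
        alleles=np.array([[0, 1, 0, 1],
                          [1, 0, 0, 1],
                          [0, 1, 1, 0]], dtype=np.int8),
    )
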