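import numpy as np
import pytest

from longkmt.pathway import AnnotationMap
from longkmt.simulate import (
    SimulationConfig,
    make_simulation_network,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_genotypes():
    """150 subjects, 5 pseudo-genes x 6 SNPs."""
    return simulate_genotypes(150, n_genes=5, snps_per_gene=6, seed=9)


@pytest.fixture(scope="session")
def small_network():
    return make_simulation_network(5, density=0.6, causal_genes=(0, 1, 2), seed=5)


@pytest.fixture(scope="session")
def small_annotation(small_genotypes, small_network):
    s = small_genotypes.n_snps
    inc = np.zeros((s, 5))
    inc[np.arange(s), small_genotypes.gene_index] = 1.0
    return AnnotationMap(
        list(small_genotypes.snp_ids), list(small_network.gene_ids), inc
    )


@pytest.fixture(scope="session")
def small_dataset(small_genotypes):
    cfg = SimulationConfig(n_subjects=150, m=3)
    return simulate_phenotypes(small_genotypes, cfg, seed=21)


@pytest.fixture(scope="session")
def small_dataset_m2(small_genotypes):
    cfg = SimulationConfig(n_subjects=150, m=2)
    return simulate_phenotypes(small_genotypes, cfg, seed=22)
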