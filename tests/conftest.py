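import numpy as np
import pytest

from qstfst import (ExperimentSimSpec, GenotypeSimSpec, GenotypeTable,
                    simulate_experiment, simulate_genotypes)


@pytest.fixture(scope="session")
def default_experiment():
    """One draw of the default half-sib common-garden design (128 families)."""
    return simulate_experiment(ExperimentSimSpec(seed=42))


@pytest.fixture(scope="session")
def diverged_genotypes():
    """Two clearly diverged populations at 7 multiallelic loci."""
    return simulate_genotypes(GenotypeSimSpec(
        n_populations=2, n_per_pop=60, n_loci=7, alleles_per_locus=10,
        divergence_f=0.25, missing_rate=0.0, seed=7,
    ))


@pytest.fixture
def tiny_table():
    """Hand-checkable 2-population, 1-locus table: {AA, AB} vs {AB, BB}."""
    return GenotypeTable(
        ids=["a", "b", "c", "d"],
        populations=["P1", "P1", "P2", "P2"],
        loci=["L1"],
        calls=np.array([[[1, 1]], [[1, 2]], [[1, 2]], [[2, 2]]]),
    )
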