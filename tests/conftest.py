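import numpy as np
import pytest

from ssrel.genomic import GenotypeSet
from ssrel.mme import VarianceComponents
from ssrel.pedigree import pedigree_from_records
from ssrel.synthetic import SimulationScenario, simulate_population


@pytest.fixture(scope="session")
def vc():
    """Variance components of the default synthetic trait (h2=0.4, omega=0.3)."""
    return VarianceComponents(sigma2_u=0.4, sigma2_e=0.6, omega=0.3)


@pytest.fixture
def trio():
    """Two unrelated founders and their offspring."""
    return pedigree_from_records([("1", "0", "0"), ("2", "0", "0"), ("3", "1", "2")])


@pytest.fixture(scope="session")
def small_pop():
    """A 300-animal population with 200 markers, shared across tests."""
    sc = SimulationScenario(
        n_founders=30,
        n_generations=3,
        offspring_per_mating=6,
        m_markers=200,
        seed=7,
    )
    return simulate_population(sc)


@pytest.fixture(scope="session")
def small_pop_external_freq(small_pop):
    """Genotyped subset with founder (external) allele frequencies.

    With external frequencies the centered columns of Z do not sum to zero,
    so ZZ' is nonsingular whenever n < m -- needed by the GBLUP(ZZ')
    equivalence checks.
    """
    return GenotypeSet(
        animal_ids=list(small_pop.geno.animal_ids),
        dosages=small_pop.geno.dosages,
        allele_freq=small_pop.founder_freqs,
    )
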