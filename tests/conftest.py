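import numpy as np
import pandas as pd
import pytest

from kinscan.datatypes import GenotypeMatrix, MarkerMap, PhenotypeTable
from kinscan import simpop


@pytest.fixture
def toy_genotypes():
    """Deterministic 6×8 dosage matrix with a 3-chromosome map."""
    rng = np.random.default_rng(7)
    values = rng.choice([0.0, 0.5, 1.0], size=(6, 8))
    gm = GenotypeMatrix(
        values, [f"i{k}" for k in range(6)], [f"m{k}" for k in range(8)]
    )
    mm = MarkerMap(
        pd.DataFrame(
            {
                "marker": [f"m{k}" for k in range(8)],
                "chromosome": ["1", "1", "1", "2", "2", "3", "3", "3"],
                "position_cM": [0, 10, 20, 0, 15, 0, 5, 30],
            }
        )
    )
    return gm, mm


@pytest.fixture(scope="session")
def small_f2():
    """F2 population (n=200, 2 chromosomes) reused across tests."""
    spec = simpop.GeneticMapSpec([("1", 100.0, 20), ("2", 100.0, 20)])
    design = simpop.BreedingDesign(scheme="F2", n_individuals=200)
    return simpop.simulate_population(design, spec, seed=11)


@pytest.fixture(scope="session")
def small_ril():
    """RIL with genomic replicates (20 lines × 4) on a 3-chromosome map."""
    spec = simpop.GeneticMapSpec([(str(c + 1), 80.0, 15) for c in range(3)])
    design = simpop.BreedingDesign(
        scheme="RIL", n_lines=20, replicates_per_line=4
    )
    return simpop.simulate_population(design, spec, seed=5)


@pytest.fixture
def noise_phenotypes():
    def make(pop, n_traits=2, seed=0):
        rng = np.random.default_rng(seed)
        n = pop.genotypes.n_individuals
        return PhenotypeTable(
            rng.standard_normal((n, n_traits)),
            list(pop.genotypes.individual_ids),
            [f"trait{t}" for t in range(n_traits)],
        )

    return make
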