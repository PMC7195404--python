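import numpy as np
import pandas as pd
import pytest

from hybridzone import (
    GenotypeLikelihoodMatrix,
    LocusMap,
    PopulationMap,
    SimulationConfig,
)


@pytest.fixture
def small_locus_map() -> LocusMap:
    return LocusMap(
        pd.DataFrame(
            {
                "locus_id": ["L1", "L2", "L3", "Z1", "Z2"],
                "chromosome": ["chr1", "chr1", "chr1", "Z", "Z"],
                "position": [100, 200, 300, 50, 150],
                "is_Z": [False, False, False, True, True],
            }
        )
    )


@pytest.fixture
def trio_pop_map() -> PopulationMap:
    return PopulationMap(
        pd.DataFrame(
            {
                "individual_id": ["a", "b", "c"],
                "population_id": ["pop1", "pop1", "pop1"],
                "role": ["hybrid", "hybrid", "hybrid"],
            }
        )
    )


def certain_gl(genotypes: np.ndarray) -> np.ndarray:
    """GL array with all likelihood on the true genotype (-1 = missing)."""
    g = np.asarray(genotypes)
    gl = np.full((*g.shape, 3), 1e-12)
    for val in range(3):
        gl[..., val][g == val] = 1.0
    gl[g == -1] = 1.0 / 3.0
    return gl


def gl_matrix_from_genotypes(
    genotypes: np.ndarray, loci: LocusMap | None = None
) -> GenotypeLikelihoodMatrix:
    g = np.asarray(genotypes)
    if loci is None:
        loci = LocusMap(
            pd.DataFrame(
                {
                    "locus_id": [f"L{k}" for k in range(g.shape[0])],
                    "chromosome": "chr1",
                    "position": np.arange(1, g.shape[0] + 1) * 100,
                    "is_Z": False,
                }
            )
        )
    individuals = [f"ind{j}" for j in range(g.shape[1])]
    return GenotypeLikelihoodMatrix(loci, individuals, certain_gl(g))


def one_pop_map(individuals, population="pop1", role="hybrid") -> PopulationMap:
    return PopulationMap(
        pd.DataFrame(
            {
                "individual_id": list(individuals),
                "population_id": population,
                "role": role,
            }
        )
    )


@pytest.fixture
def tiny_sim_config() -> SimulationConfig:
    return SimulationConfig(
        n_loci_per_chromosome=30,
        n_chromosomes=4,
        n_individuals=20,
        seed=11,
        window_snps=60,
        n_windows_per_chromosome=4,
    )
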