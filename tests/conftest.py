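import numpy as np
import pytest

from epiqtl import (
    Architecture,
    BackcrossData,
    GeneticMap,
    architecture_1,
    simulate_backcross,
)


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    """Two chromosomes, markers every 10 cM over 40 cM."""
    return GeneticMap.uniform(n_chrom=2, length_cm=40.0, spacing_cm=10.0)


@pytest.fixture(scope="session")
def arch1() -> Architecture:
    return architecture_1()


@pytest.fixture(scope="session")
def null_arch(arch1) -> Architecture:
    """Same 9 x 110 cM map as the reference architecture, but no QTL."""
    return Architecture(
        map=arch1.map,
        qtl=(),
        main_effects=np.zeros(0),
        interactions=(),
        interaction_effects=np.zeros(0),
        sigma=1.0,
    )


@pytest.fixture(scope="session")
def arch1_cross(arch1):
    return simulate_backcross(arch1, 300, seed=42)


@pytest.fixture(scope="session")
def null_data(null_arch) -> BackcrossData:
    return simulate_backcross(null_arch, 300, seed=7).data


def two_qtl_architecture(gamma: float = 2.0, a1: float = 1.0, a2: float = 1.0,
                         sigma: float = 1.0) -> Architecture:
    """Small two-chromosome architecture used across search tests."""
    from epiqtl import Locus

    gmap = GeneticMap.uniform(n_chrom=2, length_cm=60.0, spacing_cm=10.0)
    return Architecture(
        map=gmap,
        qtl=(Locus("1", 25.0), Locus("2", 35.0)),
        main_effects=np.array([a1, a2]),
        interactions=((0, 1),),
        interaction_effects=np.array([gamma]),
        sigma=sigma,
    )
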