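import numpy as np
import pytest

from hemidyad import (
    DigestionParams,
    LibraryParams,
    MethylomeDesign,
    make_genome,
    make_methylome,
    plant_construct,
    simulate_library,
)
from hemidyad.synthetic import make_construct_methylome

#: Idealized digestion: every methylated CNNR site is cut.
UNIT_DIGESTION = DigestionParams(efficiency_by_r={"G": 1.0, "A": 1.0})


@pytest.fixture(scope="session")
def construct():
    """The 146 bp worked-example duplex and its single resolvable dyad."""
    return plant_construct(seed=0)


@pytest.fixture(scope="session")
def construct_methylomes(construct):
    """Methylomes of the construct in each of the four dyad states."""
    genome, dyad = construct
    return {
        "me": make_construct_methylome(genome, dyad, True, True),
        "hemiW": make_construct_methylome(genome, dyad, True, False),
        "hemiC": make_construct_methylome(genome, dyad, False, True),
        "unme": make_construct_methylome(genome, dyad, False, False),
    }


@pytest.fixture(scope="session")
def small_genome():
    return make_genome(20_000, gc=0.5, seed=101)


@pytest.fixture(scope="session")
def designed_run(small_genome):
    """Designed methylome, truth table and an idealized 30-molecule library."""
    methylome, truth = make_methylome(small_genome, MethylomeDesign(), seed=102)
    fragments = simulate_library(
        small_genome,
        methylome,
        UNIT_DIGESTION,
        LibraryParams(n_molecules=30, seed=103),
    )
    return methylome, truth, fragments
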