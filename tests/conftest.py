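import numpy as np
import pytest

import rfmap as rf


@pytest.fixture
def small_genome() -> rf.GenomeMap:
    """Three-chromosome toy genome (fast meiosis, same code paths)."""
    return rf.GenomeMap(((1, 30_000_000), (2, 20_000_000), (3, 10_000_000)))


@pytest.fixture
def recmap() -> rf.RecombinationMap:
    return rf.RecombinationMap()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240817)


@pytest.fixture
def rf_locus() -> rf.RfLocus:
    return rf.RfLocus(1, 5_000_000, "Rf6")


@pytest.fixture
def two_loci() -> tuple[rf.RfLocus, rf.RfLocus]:
    """Two restorer loci on different (hence unlinked) chromosomes."""
    return (rf.RfLocus(1, 5_000_000, "Rf6"), rf.RfLocus(2, 8_000_000, "Rf5"))


def het_plant(genome, loci, cytoplasm="S"):
    """F1-like plant: one donor, one recipient haplotype genome-wide."""
    return rf.Plant(
        hap1=rf.uniform_haplotype(genome, 1),
        hap2=rf.uniform_haplotype(genome, 0),
        cytoplasm=cytoplasm,
        rf_loci=tuple(loci) if isinstance(loci, (tuple, list)) else (loci,),
        generation="F1",
    )
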