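"""Plants, gametophytic pollen selection, and crosses.

BT-type cytoplasmic male sterility (CMS) is gametophytic: the genotype of
the haploid pollen grain itself decides its fate.  On sterile (S)
cytoplasm, a pollen grain aborts unless it carries a functional restorer
(Rf) allele at one or more restorer loci; ovules are never selected.  A
plant heterozygous at one restorer locus therefore sheds 50% functional
pollen, and rf/rf offspring can never arise through the pollen side.

Restorer alleles ride on the donor genome: a haplotype carries Rf at a
restorer locus exactly when its origin at that position is donor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap
from .mosaic import DONOR, Haplotype, RecombinationMap, meiosis, uniform_haplotype

__all__ = [
    "RfLocus",
    "Plant",
    "GameteSample",
    "gametes",
    "cross",
    "expected_functional_pollen_fraction",
    "make_parent",
]


@dataclass(frozen=True)
class RfLocus:
    """A donor-restorer locus: donor origin here means an Rf allele."""

    chrom: int
    pos: int  # 1-based bp
    name: str = "Rf"


@dataclass
class Plant:
    """A diploid individual: two mosaic haplotypes plus cytoplasm type."""

    hap1: Haplotype
    hap2: Haplotype
    cytoplasm: str  # 'S' (BT-sterile) or 'N' (normal)
    rf_loci: tuple[RfLocus, ...] = ()
    generation: str = ""

    def __post_init__(self) -> None:
        if self.cytoplasm not in ("S", "N"):
            raise ValueError("cytoplasm must be 'S' or 'N'")

    def genotype_at(self, chrom: int, pos: int) -> int:
        """Donor-allele dosage at a position: 0, 1 or 2."""
        return int(self.hap1.origin_at(chrom, pos)) + int(self.hap2.origin_at(chrom, pos))

    def rf_genotype(self) -> dict[str, int]:
        """Rf-allele dosage per restorer locus, keyed by locus name."""
        return {loc.name: self.genotype_at(loc.chrom, loc.pos) for loc in self.rf_loci}

    def carries_rf(self) -> bool:
        return any(d > 0 for d in self.rf_genotype().values())


@dataclass
class GameteSample:
    """Gametes drawn from one parent; pollen may have been selected."""

    haplotypes: list[Haplotype]
    n_aborted: int = 0

    @property
    def functional_fraction(self) -> float:
        n = len(self.haplotypes) + self.n_aborted
        return len(self.haplotypes) / n if n else 0.0


def _carries_rf(hap: Haplotype, rf_loci: tuple[RfLocus, ...]) -> bool:
    return any(hap.origin_at(loc.chrom, loc.pos) == DONOR for loc in rf_loci)


def gametes(
    plant: Plant,
    role: str,
    n: int,
    genome: GenomeMap,
    recmap: RecombinationMap,
    rng: np.random.Generator,
) -> GameteSample:
    """Draw ``n`` meiotic products; apply pollen selection if applicable.

    For ``role='pollen'`` on S cytoplasm, haplotypes carrying no Rf allele
    at any restorer locus abort and are reported in ``n_aborted``.  Ovules
    (and pollen of N-cytoplasm plants) are never filtered.  A plant with S
    cytoplasm and no Rf allele returns an empty functional set, not an
    error.
    """
    if role not in ("pollen", "ovule"):
        raise ValueError("role must be 'pollen' or 'ovule'")
    if n <= 0:
        raise ValueError("n must be positive")
    select = role == "pollen" and plant.cytoplasm == "S"
    kept: list[Haplotype] = []
    aborted = 0
    for _ in range(n):
        g = meiosis(plant.hap1, plant.hap2, genome, recmap, rng)
        if select and not _carries_rf(g, plant.rf_loci):
            aborted += 1
        else:
            kept.append(g)
    return GameteSample(kept, aborted)


def expected_functional_pollen_fraction(plant: Plant) -> float:
    """Analytic expected fraction of functional pollen.

    Under gametophytic selection on S cytoplasm a pollen grain survives iff
    it carries Rf at >= 1 restorer locus.  Treating restorer loci as
    unlinked (they sit on different chromosomes in all configurations used
    here), the abort probability factorises over loci: rf/rf contributes 1,
    Rf/rf contributes 1/2, Rf/Rf contributes 0.  N-cytoplasm plants shed
    fully functional pollen.
    """
    if plant.cytoplasm == "N":
        return 1.0
    chroms = [loc.chrom for loc in plant.rf_loci]
    if len(set(chroms)) != len(chroms):
        raise ValueError("analytic fraction assumes restorer loci on distinct chromosomes")
    p_abort = 1.0
    for name, dosage in plant.rf_genotype().items():
        p_abort *= {0: 1.0, 1: 0.5, 2: 0.0}[dosage]
    return 1.0 - p_abort


def cross(
    mother: Plant,
    father: Plant,
    n_offspring: int,
    genome: GenomeMap,
    recmap: RecombinationMap,
    rng: np.random.Generator,
    generation: str = "",
) -> list[Plant]:
    """Cross two plants; offspring cytoplasm is always the mother's.

    Pollen is drawn from the father's functional pool (rejection sampling
    under gametophytic selection).  A father that can make no functional
    pollen at all (S cytoplasm, no Rf allele anywhere) raises.
    """
    if n_offspring <= 0:
        raise ValueError("n_offspring must be positive")
    father_selected = father.cytoplasm == "S"
    if father_selected and not father.carries_rf():
        raise ValueError("no functional pollen: father is fully male-sterile")
    rf_loci = tuple(dict.fromkeys(mother.rf_loci + father.rf_loci))
    offspring = []
    for _ in range(n_offspring):
        ovule = meiosis(mother.hap1, mother.hap2, genome, recmap, rng)
        while True:
            pollen = meiosis(father.hap1, father.hap2, genome, recmap, rng)
            if not father_selected or _carries_rf(pollen, father.rf_loci):
                break
        offspring.append(
            Plant(hap1=ovule, hap2=pollen, cytoplasm=mother.cytoplasm,
                  rf_loci=rf_loci, generation=generation)
        )
    return offspring


def make_parent(
    genome: GenomeMap,
    origin: int,
    cytoplasm: str,
    rf_loci: tuple[RfLocus, ...] = (),
    generation: str = "P",
) -> Plant:
    """Homozygous single-origin founder (donor or recipient parent)."""
    return Plant(
        hap1=uniform_haplotype(genome, origin),
        hap2=uniform_haplotype(genome, origin),
        cytoplasm=cytoplasm,
        rf_loci=rf_loci,
        generation=generation,
    )
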