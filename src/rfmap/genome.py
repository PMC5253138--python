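"""Genome coordinate system and biallelic SNP panels.

The simulated genome is rice-like: 12 chromosomes with Nipponbare-scale
physical lengths (~373 Mb total).  All positions are 1-based base pairs;
interval sizes throughout the package are reported as ``end - start``,
matching the convention used for substituted-segment and QTL intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeMap", "SnpPanel", "rice_genome", "simulate_parents"]

# Nipponbare-like chromosome lengths (bp), chromosomes 1..12, total ~373 Mb.
_RICE_CHROM_MB = (43.3, 35.9, 36.4, 35.5, 29.9, 31.2, 29.7, 28.4, 23.0, 23.2, 29.0, 27.5)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeMap:
    """Ordered chromosome ids and physical lengths."""

    chromosomes: tuple[tuple[int, int], ...]  # (id, length_bp)

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.chromosomes]
        if len(ids) != len(set(ids)):
            raise ValueError("chromosome ids must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")

    @property
    def ids(self) -> list[int]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[int, int]:
        return dict(self.chromosomes)

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, chrom: int) -> int:
        return self.lengths[chrom]


def rice_genome(scale: float = 1.0) -> GenomeMap:
    """Default 12-chromosome rice-like genome (~373 Mb at scale 1)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    chroms = tuple(
        (i + 1, int(round(mb * 1e6 * scale))) for i, mb in enumerate(_RICE_CHROM_MB)
    )
    return GenomeMap(chroms)


@dataclass
class SnpPanel:
    """Biallelic SNPs distinguishing donor from recipient parent.

    ``chrom``/``pos`` are parallel arrays sorted by (chromosome, position);
    positions are 1-based and strictly increasing within a chromosome.
    """

    chrom: np.ndarray  # int32
    pos: np.ndarray  # int64, 1-based
    donor_allele: np.ndarray  # '<U1'
    recipient_allele: np.ndarray  # '<U1'
    _index: dict[int, tuple[int, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.chrom) == len(self.pos) == len(self.donor_allele) == len(self.recipient_allele)):
            raise ValueError("panel arrays must have equal length")
        if np.any(self.donor_allele == self.recipient_allele):
            raise ValueError("donor and recipient alleles must differ at every SNP")
        self._index = {}
        for c in np.unique(self.chrom):
            mask = np.flatnonzero(self.chrom == c)
            lo, hi = mask[0], mask[-1] + 1
            if np.any(np.diff(self.pos[lo:hi]) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
            self._index[int(c)] = (int(lo), int(hi))

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self._index)

    def slice_chrom(self, chrom: int) -> slice:
        lo, hi = self._index[chrom]
        return slice(lo, hi)

    def positions(self, chrom: int) -> np.ndarray:
        return self.pos[self.slice_chrom(chrom)]


def simulate_parents(genome: GenomeMap, snp_density: float, seed) -> SnpPanel:
    """Place parental SNPs along the genome at ``snp_density`` SNPs/Mb.

    The per-chromosome SNP count is deterministic, ``round(density * L_Mb)``;
    positions are uniform draws made unique and sorted, so the marginal
    placement matches a homogeneous (binomial) point process.  Donor and
    recipient alleles are drawn to differ at every site.
    """
    if snp_density <= 0:
        raise ValueError("snp_density must be positive")
    if genome.genome_length <= 0:
        raise ValueError("zero-length genome")
    rng = np.random.default_rng(seed)
    chroms, poss = [], []
    for cid, length in genome.chromosomes:
        n = int(round(snp_density * length / 1e6))
        n = min(n, length)  # cannot exceed one SNP per bp
        p = rng.choice(length, size=n, replace=False) + 1 if n > length // 2 else None
        if p is None:
            # rejection-free: draw extra, unique, trim
            p = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 8))
            while len(p) < n:
                p = np.unique(np.concatenate([p, rng.integers(1, length + 1, size=n)]))
            p = np.sort(rng.choice(p, size=n, replace=False))
        else:
            p = np.sort(p)
        chroms.append(np.full(n, cid, dtype=np.int32))
        poss.append(p.astype(np.int64))
    n_total = sum(len(p) for p in poss)
    donor = rng.integers(0, 4, size=n_total)
    shift = rng.integers(1, 4, size=n_total)
    recip = (donor + shift) % 4
    return SnpPanel(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        donor_allele=_BASES[donor],
        recipient_allele=_BASES[recip],
    )
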