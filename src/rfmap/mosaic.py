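"""Mosaic haplotypes and meiosis.

A haplotype is, per chromosome, a run-length encoding of parental origin:
an array of half-open interval ends (0-based bp, last end = chromosome
length) and a parallel array of origins (0 = recipient, 1 = donor).
Recombination follows a Haldane model (no interference): crossover counts
are Poisson with mean equal to the chromosome's genetic length, positions
uniform.  The default map density is 1 cM per 400 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeMap

__all__ = ["RecombinationMap", "Haplotype", "meiosis", "uniform_haplotype"]

DONOR = 1
RECIPIENT = 0


@dataclass(frozen=True)
class RecombinationMap:
    """Uniform physical-to-genetic map; default 1 cM / 400 kb."""

    bp_per_cm: float = 400_000.0

    def morgans(self, length_bp: float) -> float:
        return length_bp / (self.bp_per_cm * 100.0)

    def rec_fraction(self, distance_bp: float) -> float:
        """Haldane recombination fraction between two points."""
        d = self.morgans(distance_bp)
        return 0.5 * (1.0 - np.exp(-2.0 * d))


@dataclass
class Haplotype:
    """Per-chromosome run-length encoded parental origin of one homolog."""

    ends: dict[int, np.ndarray] = field(default_factory=dict)  # int64, half-open ends
    origins: dict[int, np.ndarray] = field(default_factory=dict)  # int8

    def origin_at(self, chrom: int, pos) -> np.ndarray | int:
        """Origin at 1-based position(s)."""
        p = np.asarray(pos, dtype=np.int64) - 1
        idx = np.searchsorted(self.ends[chrom], p, side="right")
        out = self.origins[chrom][idx]
        return out if out.ndim else int(out)

    def donor_length(self) -> int:
        total = 0
        for c, ends in self.ends.items():
            starts = np.concatenate([[0], ends[:-1]])
            total += int(np.sum((ends - starts)[self.origins[c] == DONOR]))
        return total

    def donor_intervals(self, chrom: int) -> list[tuple[int, int]]:
        """Donor runs on ``chrom`` as 0-based half-open (start, end)."""
        ends = self.ends[chrom]
        starts = np.concatenate([[0], ends[:-1]])
        mask = self.origins[chrom] == DONOR
        return [(int(s), int(e)) for s, e, m in zip(starts, ends, mask) if m]

    def validate(self, genome: GenomeMap) -> None:
        for c, length in genome.chromosomes:
            ends = self.ends[c]
            if ends[-1] != length:
                raise ValueError(f"chromosome {c} not tiled to full length")
            if np.any(np.diff(ends) <= 0) or ends[0] <= 0:
                raise ValueError(f"chromosome {c} intervals empty or unsorted")
            if np.any(np.diff(self.origins[c]) == 0):
                raise ValueError(f"chromosome {c} has adjacent intervals of equal origin")


def uniform_haplotype(genome: GenomeMap, origin: int) -> Haplotype:
    """Single-origin haplotype covering the whole genome."""
    h = Haplotype()
    for c, length in genome.chromosomes:
        h.ends[c] = np.array([length], dtype=np.int64)
        h.origins[c] = np.array([origin], dtype=np.int8)
    return h


def _compress(ends: np.ndarray, origins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent intervals with equal origin."""
    if len(ends) <= 1:
        return ends, origins
    keep = np.concatenate([origins[:-1] != origins[1:], [True]])
    return ends[keep], origins[keep]


def meiosis(
    hap_a: Haplotype,
    hap_b: Haplotype,
    genome: GenomeMap,
    recmap: RecombinationMap,
    rng: np.random.Generator,
) -> Haplotype:
    """One recombinant gamete haplotype from a pair of homologs."""
    out = Haplotype()
    for c, length in genome.chromosomes:
        n_cx = rng.poisson(recmap.morgans(length))
        cx = np.sort(rng.integers(1, length, size=n_cx)) if n_cx else np.empty(0, dtype=np.int64)
        cx = np.unique(cx)
        start_on_a = bool(rng.integers(2))

        ea, oa = hap_a.ends[c], hap_a.origins[c]
        eb, ob = hap_b.ends[c], hap_b.origins[c]
        # elementary interval grid: union of both homolog breakpoints + crossovers
        pts = np.unique(np.concatenate([ea, eb, cx, [length]]))
        # source homolog per elementary interval (pts[i-1], pts[i]]:
        # parity of crossovers at or before the interval start
        starts = np.concatenate([[0], pts[:-1]])
        n_flips = np.searchsorted(cx, starts, side="right")
        on_a = (n_flips % 2 == 0) == start_on_a
        ia = np.searchsorted(ea, starts, side="right")
        ib = np.searchsorted(eb, starts, side="right")
        origins = np.where(on_a, oa[ia], ob[ib]).astype(np.int8)
        ends, origins = _compress(pts.astype(np.int64), origins)
        out.ends[c] = ends
        out.origins[c] = origins
    return out
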