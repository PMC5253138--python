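"""Breeding-design simulators: CSSL panels and F2/F3 marker populations.

Chromosome segment substitution lines (CSSLs) are built the way a breeder
builds them: an F1 between recipient and donor is backcrossed to the
recipient for several generations with marker-assisted selection (MAS)
that (a) retains donor material at the line's target position and (b)
minimises donor content elsewhere, then fixed to homozygosity.  Fixation
is modelled by drawing one gamete retaining the target and doubling it —
the endpoint of selfing-with-selection.

For the very large F2/F3 populations used in segregation testing and fine
mapping only marker-locus genotypes matter, so a vectorised Markov-chain
gamete sampler is provided: under Haldane's model (no interference) the
origin process along a chromosome is Markov, with switch probability
between adjacent sites equal to the recombination fraction.  It draws the
same distribution as interval-based meiosis, restricted to the queried
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap
from .mosaic import DONOR, RECIPIENT, Haplotype, RecombinationMap, meiosis
from .plants import Plant, RfLocus, cross, make_parent

__all__ = [
    "CsslLine",
    "simulate_cssl_panel",
    "backcross_generation",
    "f2_marker_population",
    "donor_union_coverage",
]


@dataclass
class CsslLine:
    """A finished (homozygous) CSSL with its true donor segments."""

    line_id: str
    plant: Plant
    target: tuple[int, int]  # (chrom, pos)
    # true donor intervals per chromosome, 0-based half-open
    true_segments: dict[int, list[tuple[int, int]]]

    @property
    def n_segments(self) -> int:
        return sum(len(v) for v in self.true_segments.values())


def _mas_score(plant: Plant, grid: dict[int, np.ndarray]) -> int:
    """Donor-allele dosage summed over the MAS marker grid (lower = better)."""
    total = 0
    for c, positions in grid.items():
        total += int(np.sum(plant.hap1.origin_at(c, positions)))
        total += int(np.sum(plant.hap2.origin_at(c, positions)))
    return total


def _marker_grid(genome: GenomeMap, spacing_bp: int) -> dict[int, np.ndarray]:
    return {
        c: np.arange(spacing_bp // 2, length, spacing_bp, dtype=np.int64) + 1
        for c, length in genome.chromosomes
    }


def backcross_generation(
    recipient: Plant,
    donor_carrier: Plant,
    genome: GenomeMap,
    recmap: RecombinationMap,
    rng: np.random.Generator,
    n_progeny: int = 1,
) -> list[Plant]:
    """One backcross to the recurrent (recipient) parent, no selection."""
    return cross(recipient, donor_carrier, n_progeny, genome, recmap, rng, generation="BC")


def simulate_cssl_panel(
    genome: GenomeMap,
    n_lines: int,
    n_backcrosses: int,
    rng: np.random.Generator,
    recmap: RecombinationMap | None = None,
    mas_marker_spacing: int = 1_000_000,
    mas_batch: int = 12,
    rf_loci: tuple[RfLocus, ...] = (),
    targets: list[tuple[int, int]] | None = None,
) -> list[CsslLine]:
    """Build a panel of homozygous CSSLs by backcrossing with MAS.

    Each line is assigned a target position: the first ``len(targets)``
    lines take the listed (chrom, pos) targets — the way a designed panel
    guarantees coverage of regions of interest — and the remainder draw
    uniform positions over the genome.  MAS keeps the target donor segment
    through every backcross while picking, from a batch of ``mas_batch``
    progeny, the candidate with the least donor content on a marker grid.
    Returns lines with their true donor segments as ground truth.
    """
    if n_backcrosses < 1:
        raise ValueError("n_backcrosses must be >= 1")
    if recmap is None:
        recmap = RecombinationMap()
    grid = _marker_grid(genome, mas_marker_spacing)
    recipient = make_parent(genome, RECIPIENT, "N", rf_loci, "recipient")
    donor = make_parent(genome, DONOR, "N", rf_loci, "donor")
    chrom_ids = genome.ids
    lengths = genome.lengths
    weights = np.array([lengths[c] for c in chrom_ids], dtype=float)
    weights /= weights.sum()

    lines: list[CsslLine] = []
    for i in range(n_lines):
        if targets is not None and i < len(targets):
            t_chrom, t_pos = targets[i]
        else:
            t_chrom = int(rng.choice(chrom_ids, p=weights))
            t_pos = int(rng.integers(1, lengths[t_chrom] + 1))
        f1 = cross(recipient, donor, 1, genome, recmap, rng, generation="F1")[0]
        current = f1
        for _ in range(n_backcrosses):
            batch = cross(recipient, current, mas_batch, genome, recmap, rng, generation="BC")
            keep = [p for p in batch if p.genotype_at(t_chrom, t_pos) >= 1]
            while not keep:  # target lost in the whole batch: redraw
                batch = cross(recipient, current, mas_batch, genome, recmap, rng, generation="BC")
                keep = [p for p in batch if p.genotype_at(t_chrom, t_pos) >= 1]
            current = min(keep, key=lambda p: _mas_score(p, grid))
        # fix to homozygosity: one target-retaining gamete, doubled
        while True:
            g = meiosis(current.hap1, current.hap2, genome, recmap, rng)
            if g.origin_at(t_chrom, t_pos) == DONOR:
                break
        plant = Plant(hap1=g, hap2=g, cytoplasm="N", rf_loci=rf_loci, generation="CSSL")
        segs = {c: g.donor_intervals(c) for c in chrom_ids}
        segs = {c: v for c, v in segs.items() if v}
        lines.append(CsslLine(f"L{i + 1}", plant, (t_chrom, t_pos), segs))
    return lines


def donor_union_coverage(lines: list[CsslLine], genome: GenomeMap) -> float:
    """Fraction of the genome covered by the union of donor segments."""
    covered = 0
    for c, length in genome.chromosomes:
        ivs = sorted(iv for ln in lines for iv in ln.true_segments.get(c, []))
        last_end = -1
        for s, e in ivs:
            s = max(s, last_end)
            if e > s:
                covered += e - s
                last_end = e
            last_end = max(last_end, e)
    return covered / genome.genome_length


# ---------------------------------------------------------------------------
# Vectorised marker-genotype population sampler


def _gamete_origins(
    rec_fracs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, m) origin matrix for gametes of a fully heterozygous parent.

    Column j is the parental origin (0/1) at ordered site j; switches
    between adjacent sites occur independently with the given
    recombination fractions (Haldane, no interference).
    """
    m = len(rec_fracs) + 1
    start = rng.integers(0, 2, size=(n, 1))
    if m == 1:
        return start.astype(np.int8)
    switches = rng.random((n, m - 1)) < rec_fracs
    cum = np.cumsum(switches, axis=1) % 2
    return ((start + np.concatenate([np.zeros((n, 1), dtype=int), cum], axis=1)) % 2).astype(np.int8)


def f2_marker_population(
    positions: np.ndarray,
    rf_index: int,
    n_plants: int,
    rng: np.random.Generator,
    recmap: RecombinationMap | None = None,
    cytoplasm: str = "S",
) -> np.ndarray:
    """Genotypes of a selfed-F1 population at ordered marker positions.

    The F1 is heterozygous donor/recipient at every queried site (one
    of which, ``rf_index``, is the restorer locus) on the stated
    cytoplasm.  Pollen selection removes rf gametes when cytoplasm is
    'S'; ovules are untouched.  Returns an (n_plants, m) donor-dosage
    matrix with values 0/1/2.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be ordered")
    if not 0 <= rf_index < len(positions):
        raise ValueError("rf_index out of range")
    if recmap is None:
        recmap = RecombinationMap()
    rec = recmap.rec_fraction(np.diff(positions).astype(float))
    ovules = _gamete_origins(rec, n_plants, rng)
    if cytoplasm == "S":
        pollen = np.empty((0, len(positions)), dtype=np.int8)
        while len(pollen) < n_plants:
            draw = _gamete_origins(rec, max(2 * n_plants, 64), rng)
            pollen = np.concatenate([pollen, draw[draw[:, rf_index] == DONOR]])
        pollen = pollen[:n_plants]
    else:
        pollen = _gamete_origins(rec, n_plants, rng)
    return (ovules + pollen).astype(np.int8)
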