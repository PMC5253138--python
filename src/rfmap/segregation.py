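"""Gametophytic segregation testing and recombinant-based fine mapping.

On sterile cytoplasm only Rf-bearing pollen functions, so a selfed F1
(Rf/rf) yields F2 plants that are homozygous-donor or heterozygous at a
completely linked marker in a 1:1 ratio — the homozygous-recipient class
is absent.  A plant that is nevertheless homozygous-recipient at a marker,
while its fertility proves it carries Rf, must be a recombinant between
that marker and the restorer locus; such plants localise the gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .snpcalls import MISSING

__all__ = [
    "Marker",
    "MarkerGenotypeCounts",
    "SegregationVerdict",
    "FineMapResult",
    "classify_population",
    "gametophytic_test",
    "screen_recombinants",
    "narrow_interval",
]

_VALID_CODES = (MISSING, 0, 1, 2)


@dataclass(frozen=True)
class Marker:
    name: str
    chrom: int
    pos: int  # 1-based bp


@dataclass(frozen=True)
class MarkerGenotypeCounts:
    marker: str
    n_hom_donor: int
    n_het: int
    n_hom_recipient: int
    n_missing: int

    @property
    def n(self) -> int:
        return self.n_hom_donor + self.n_het + self.n_hom_recipient + self.n_missing


@dataclass(frozen=True)
class SegregationVerdict:
    """Outcome of the single-restorer gametophytic segregation test."""

    counts: MarkerGenotypeCounts
    chi2: float  # GOF of hom-donor:het vs 1:1, df 1, no Yates correction
    p_value: float
    verdict: str  # 'consistent-single-Rf' | 'inconsistent'

    @property
    def n_hom_recipient(self) -> int:
        return self.counts.n_hom_recipient


def classify_population(genotypes: pd.DataFrame) -> list[MarkerGenotypeCounts]:
    """Exact genotype counts per marker.

    ``genotypes`` is plants x markers with codes 2 (hom donor), 1 (het),
    0 (hom recipient), -1 (missing).
    """
    arr = genotypes.to_numpy()
    if not np.isin(arr, _VALID_CODES).all():
        bad = sorted(set(np.unique(arr)) - set(_VALID_CODES))
        raise ValueError(f"unknown genotype code(s): {bad}")
    out = []
    for j, marker in enumerate(genotypes.columns):
        col = arr[:, j]
        out.append(MarkerGenotypeCounts(
            marker=str(marker),
            n_hom_donor=int(np.sum(col == 2)),
            n_het=int(np.sum(col == 1)),
            n_hom_recipient=int(np.sum(col == 0)),
            n_missing=int(np.sum(col == MISSING)),
        ))
    return out


def gametophytic_test(
    counts: MarkerGenotypeCounts, alpha: float = 0.05, tolerance: float = 0.01
) -> SegregationVerdict:
    """Test whether marker counts fit a single gametophytic restorer.

    Expectation under one Rf gene with complete linkage: hom-donor and het
    in 1:1, no hom-recipient plants.  The verdict is consistent-single-Rf
    iff the hom-recipient count is at most ``tolerance`` (a fraction of
    the non-missing population, covering rare marker-locus recombinants)
    and the 1:1 chi-square GOF is not rejected at ``alpha``.
    """
    a, b = counts.n_hom_donor, counts.n_het
    n_nonmissing = a + b + counts.n_hom_recipient
    if n_nonmissing == 0:
        raise ValueError("no non-missing genotypes")
    if a + b == 0:
        chi2, p = np.inf, 0.0
    else:
        exp = (a + b) / 2.0
        chi2 = (a - exp) ** 2 / exp + (b - exp) ** 2 / exp
        p = float(stats.chi2.sf(chi2, df=1))
    ok = counts.n_hom_recipient <= tolerance * n_nonmissing and p > alpha
    return SegregationVerdict(
        counts=counts, chi2=float(chi2), p_value=p,
        verdict="consistent-single-Rf" if ok else "inconsistent",
    )


def screen_recombinants(
    genotypes: pd.DataFrame, markers: list[Marker]
) -> dict[str, list]:
    """Plants homozygous-recipient at each screening marker.

    In a population whose fertility proves every plant carries Rf, a
    hom-recipient genotype at a marker can only arise by recombination
    between that marker and the restorer locus.
    """
    out: dict[str, list] = {}
    for m in markers:
        if m.name not in genotypes.columns:
            raise ValueError(f"marker {m.name} absent from genotype table")
        col = genotypes[m.name]
        out[m.name] = list(genotypes.index[col == 0])
    return out


@dataclass(frozen=True)
class FineMapResult:
    """Candidate interval from recombinant breakpoint analysis."""

    chrom: int
    left_marker: str | None
    right_marker: str | None
    left_pos: int
    right_pos: int
    recombinant_counts: dict[str, int]

    @property
    def size(self) -> int:
        return self.right_pos - self.left_pos


def narrow_interval(
    genotypes: pd.DataFrame,
    markers: list[Marker],
    fertile: pd.Series | None = None,
    chrom_bounds: tuple[int, int] | None = None,
) -> FineMapResult:
    """Narrow the restorer-locus interval using fertile recombinants.

    ``markers`` must be on one chromosome with strictly increasing
    positions and match columns of ``genotypes``.  A fertile plant that is
    homozygous-recipient in a run extending from the left end of the
    ladder places its breakpoint — and hence the locus — right of the
    run's last marker (symmetrically for right-anchored runs), assuming a
    single crossover.  The locus is placed by maximum parsimony over the
    inter-marker gaps: each anchoring recombinant votes for every gap
    consistent with its run, and the interval spans the best-supported
    gaps.  Rare double recombinants (inconsistent with the consensus gap)
    are thereby outvoted rather than allowed to contradict the placement.
    If no gap is consistent with any anchoring recombinant the data are
    contradictory and an error is raised.  A side with no informative
    recombinant stays at the chromosome bound, and adjacent markers never
    separated by a recombinant cannot shrink the interval.
    """
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    pos = np.array([m.pos for m in markers])
    if np.any(np.diff(pos) <= 0):
        raise ValueError("marker positions must be strictly increasing")
    chroms = {m.chrom for m in markers}
    if len(chroms) != 1:
        raise ValueError("markers must be on a single chromosome")
    chrom = chroms.pop()
    arr = genotypes[[m.name for m in markers]].to_numpy()
    if fertile is None:
        keep = np.ones(len(genotypes), dtype=bool)
    else:
        keep = pd.Series(fertile).loc[genotypes.index].to_numpy(dtype=bool)

    m = len(markers)
    rec_counts = {mk.name: 0 for mk in markers}
    # gap g = 0..m: locus between marker g-1 and marker g (g=0: left of
    # the ladder, g=m: right of it)
    gap_votes = np.zeros(m + 1)
    n_anchoring = 0
    for row, informative in zip(arr, keep):
        hom_rec = row == 0
        if not hom_rec.any():
            continue
        for j in np.flatnonzero(hom_rec):
            rec_counts[markers[j].name] += 1
        if not informative:
            continue
        idx = np.flatnonzero(hom_rec)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        allowed = np.ones(m + 1, dtype=bool)
        anchoring = False
        if idx[0] == 0:  # left-anchored run: locus right of its last marker
            run_end = int(idx[breaks[0]]) if len(breaks) else int(idx[-1])
            allowed[: run_end + 1] = False
            anchoring = True
        if idx[-1] == m - 1:  # right-anchored run: locus left of its first marker
            run_start = int(idx[breaks[-1] + 1]) if len(breaks) else int(idx[0])
            allowed[run_start + 1:] = False
            anchoring = True
        # interior-only blocks exclude no gap; they carry no boundary signal
        if anchoring:
            n_anchoring += 1
            gap_votes += allowed

    if n_anchoring == 0:
        left_idx, right_idx = -1, m
    else:
        best = gap_votes.max()
        if best == 0:
            raise ValueError("inconsistent recombinants: locus excluded everywhere")
        best_gaps = np.flatnonzero(gap_votes == best)
        left_idx = int(best_gaps.min()) - 1
        right_idx = int(best_gaps.max())
    if chrom_bounds is None:
        chrom_bounds = (1, int(pos[-1]))
    left_marker = markers[left_idx].name if left_idx >= 0 else None
    right_marker = markers[right_idx].name if right_idx < m else None
    left_pos = int(pos[left_idx]) if left_idx >= 0 else chrom_bounds[0]
    right_pos = int(pos[right_idx]) if right_idx < m else chrom_bounds[1]
    return FineMapResult(
        chrom=chrom, left_marker=left_marker, right_marker=right_marker,
        left_pos=left_pos, right_pos=right_pos, recombinant_counts=rec_counts,
    )
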