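"""Sliding-window genotype calling, donor segments, panel stats, bin map.

Per line and chromosome, consecutive SNP calls are evaluated in windows of
``window_size`` SNPs advancing by ``step``.  A window is called
donor-homozygous (recipient-homozygous) when at least 80% of its
non-missing calls are of that state; otherwise heterozygous when the
donor-allele dosage fraction (2*donor + het) / (2*non-missing) falls in
[0.3, 0.7]; otherwise ambiguous.  Maximal runs of identical non-recipient
window calls, bridged across at most ``max_gap`` ambiguous windows, become
donor segments whose coordinates are the first/last SNP positions of the
run (1-based; reported size is end - start).

Bins are the minimal intervals delimited by the union of all segment
breakpoints across the panel: the units of QTL testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .snpcalls import SnpCallMatrix

__all__ = [
    "WindowCall",
    "Segment",
    "PanelStats",
    "Bin",
    "BinMatrix",
    "WindowParams",
    "call_windows",
    "merge_windows",
    "panel_stats",
    "build_bins",
]

logger = logging.getLogger(__name__)

# window-call codes
W_RECIPIENT, W_HET, W_DONOR, W_AMBIGUOUS = 0, 1, 2, 3
_CALL_NAMES = {0: "recipient-hom", 1: "het", 2: "donor-hom", 3: "ambiguous"}


@dataclass(frozen=True)
class WindowParams:
    window_size: int = 15
    step: int = 5
    hom_threshold: float = 0.8
    het_band: tuple[float, float] = (0.3, 0.7)
    max_gap: int = 1  # ambiguous windows bridged inside a run

    def __post_init__(self) -> None:
        if self.window_size < 3:
            raise ValueError("window_size must be >= 3")
        if not 1 <= self.step <= self.window_size:
            raise ValueError("step must be in [1, window_size]")

    def scaled_to(self, expected_snps_per_window: float) -> "WindowParams":
        """Grow the window so it is expected to hold >= 10 SNPs."""
        if expected_snps_per_window >= 10:
            return self
        factor = int(np.ceil(10 / max(expected_snps_per_window, 1e-9)))
        return WindowParams(
            self.window_size * factor, self.step * factor,
            self.hom_threshold, self.het_band, self.max_gap,
        )


@dataclass(frozen=True)
class WindowCall:
    line_id: str
    chrom: int
    index: int
    start: int  # first SNP position in window (1-based)
    end: int  # last SNP position in window
    call: int  # W_* code

    @property
    def call_name(self) -> str:
        return _CALL_NAMES[self.call]


@dataclass(frozen=True)
class Segment:
    """Donor-derived (or heterozygous) substituted segment of one line."""

    line_id: str
    chrom: int
    start: int  # 1-based
    end: int
    state: int  # W_DONOR or W_HET

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def size(self) -> int:
        return self.end - self.start


def classify_window(counts_donor: int, counts_het: int, counts_recipient: int,
                    params: WindowParams) -> int:
    """Classify one window from its non-missing call counts."""
    nm = counts_donor + counts_het + counts_recipient
    if nm == 0:
        return W_AMBIGUOUS
    if counts_donor / nm >= params.hom_threshold:
        return W_DONOR
    if counts_recipient / nm >= params.hom_threshold:
        return W_RECIPIENT
    dosage = (2 * counts_donor + counts_het) / (2 * nm)
    lo, hi = params.het_band
    if lo <= dosage <= hi:
        return W_HET
    return W_AMBIGUOUS


def _window_counts(row: np.ndarray, w: int, s: int) -> tuple[np.ndarray, ...]:
    """Per-window counts of each call state via cumulative sums."""
    m = len(row)
    starts = np.arange(0, max(m - w, 0) + 1, s)
    if len(starts) == 0:
        starts = np.array([0])
        w = m
    out = []
    for state in (2, 1, 0):
        cs = np.concatenate([[0], np.cumsum(row == state)])
        out.append(cs[starts + w] - cs[starts])
    return starts, w, out[0], out[1], out[2]


def call_windows(
    matrix: SnpCallMatrix, params: WindowParams | None = None
) -> list[WindowCall]:
    """Sliding-window genotype calls for every line and chromosome."""
    if params is None:
        params = WindowParams()
    calls_out: list[WindowCall] = []
    for i, line_id in enumerate(matrix.line_ids):
        for c in matrix.panel.chromosomes:
            sl = matrix.panel.slice_chrom(c)
            row = matrix.calls[i, sl]
            pos = matrix.panel.pos[sl]
            if len(row) == 0:
                continue
            starts, w, nd, nh, nr = _window_counts(row, params.window_size, params.step)
            nm = nd + nh + nr
            dosage = np.where(nm > 0, (2 * nd + nh) / np.maximum(2 * nm, 1), np.nan)
            wcall = np.full(len(starts), W_AMBIGUOUS, dtype=np.int8)
            with np.errstate(invalid="ignore"):
                frac_d = np.where(nm > 0, nd / np.maximum(nm, 1), 0.0)
                frac_r = np.where(nm > 0, nr / np.maximum(nm, 1), 0.0)
            lo, hi = params.het_band
            het = (nm > 0) & (dosage >= lo) & (dosage <= hi)
            wcall[het] = W_HET
            wcall[(nm > 0) & (frac_r >= params.hom_threshold)] = W_RECIPIENT
            wcall[(nm > 0) & (frac_d >= params.hom_threshold)] = W_DONOR
            if np.any(nm == 0):
                logger.warning(
                    "line %s chr %d: %d all-missing window(s) set ambiguous",
                    line_id, c, int(np.sum(nm == 0)),
                )
            last = np.minimum(starts + w, len(row)) - 1
            for k in range(len(starts)):
                calls_out.append(WindowCall(
                    line_id, int(c), k, int(pos[starts[k]]), int(pos[last[k]]), int(wcall[k]),
                ))
    return calls_out


def merge_windows(calls: list[WindowCall], max_gap: int = 1) -> list[Segment]:
    """Merge window calls into donor/het segments.

    Maximal runs of identical non-recipient calls become one segment;
    runs interrupted by at most ``max_gap`` consecutive ambiguous windows
    are bridged.  Segment start/end are the first/last SNP positions of
    the run's windows.
    """
    segments: list[Segment] = []
    # group by (line, chrom) preserving order
    from itertools import groupby

    for (line_id, chrom), grp in groupby(calls, key=lambda wc: (wc.line_id, wc.chrom)):
        grp = list(grp)
        cur_state: int | None = None
        cur_start = cur_end = 0
        pending_gap = 0

        def flush() -> None:
            nonlocal cur_state
            if cur_state in (W_DONOR, W_HET):
                segments.append(Segment(line_id, chrom, cur_start, cur_end, cur_state))
            cur_state = None

        for wc in grp:
            if wc.call == cur_state and cur_state is not None:
                cur_end = max(cur_end, wc.end)
                pending_gap = 0
            elif wc.call == W_AMBIGUOUS and cur_state in (W_DONOR, W_HET):
                pending_gap += 1
                if pending_gap > max_gap:
                    flush()
                    pending_gap = 0
            else:
                flush()
                pending_gap = 0
                cur_state = wc.call
                cur_start, cur_end = wc.start, wc.end
        flush()
    n_het = sum(1 for s in segments if s.state == W_HET)
    if n_het:
        logger.warning(
            "%d heterozygous segment(s) called; in a finished (homozygous) "
            "CSSL panel these are boundary/resolution artifacts of segments "
            "shorter than the window span", n_het,
        )
    return segments


@dataclass
class PanelStats:
    """Per-chromosome substituted-segment summary with grand totals."""

    table: pd.DataFrame  # index chrom + 'Total'; columns n_segments, length_mb, density_pct

    @property
    def total_segments(self) -> int:
        return int(self.table.loc["Total", "n_segments"])

    @property
    def total_length_mb(self) -> float:
        return float(self.table.loc["Total", "length_mb"])

    @property
    def mean_segment_length_mb(self) -> float:
        return self.total_length_mb / self.total_segments


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, last_end = 0, -1
    for s, e in sorted(intervals):
        s = max(s, last_end)
        if e > s:
            total += e - s
            last_end = e
        last_end = max(last_end, e)
    return total


def panel_stats(segments: list[Segment], genome: GenomeMap, n_lines: int) -> PanelStats:
    """Segment counts, summed lengths and union densities per chromosome."""
    lengths = genome.lengths
    rows = {}
    union_total = 0
    for c in genome.ids:
        segs_c = [s for s in segments if s.chrom == c]
        for s in segs_c:
            if s.end > lengths[c] or s.start < 1:
                raise ValueError(f"segment outside chromosome {c}: {s.start}-{s.end}")
        union = _union_length([(s.start, s.end) for s in segs_c])
        union_total += union
        rows[c] = {
            "n_segments": len(segs_c),
            "length_mb": sum(s.size for s in segs_c) / 1e6,
            "density_pct": 100.0 * union / lengths[c],
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    total = pd.DataFrame(
        {
            "n_segments": [int(table["n_segments"].sum())],
            "length_mb": [float(table["length_mb"].sum())],
            "density_pct": [100.0 * union_total / genome.genome_length],
        },
        index=["Total"],
    )
    return PanelStats(pd.concat([table, total]))


@dataclass(frozen=True)
class Bin:
    """Minimal interval delimited by segment breakpoints across the panel."""

    id: int  # serial in genome order, 1-based
    chrom: int
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class BinMatrix:
    """Line x bin donor-dosage genotype matrix over a shared bin map."""

    line_ids: list[str]
    bins: list[Bin]
    genotypes: np.ndarray  # int8 (n_lines, n_bins); 0 recipient, 1 het, 2 donor

    def carriers(self, bin_index: int) -> list[str]:
        return [l for l, g in zip(self.line_ids, self.genotypes[:, bin_index]) if g > 0]


def build_bins(segments: list[Segment], line_ids: list[str] | None = None) -> BinMatrix:
    """Construct the bin map and line-by-bin genotype matrix.

    Breakpoints per chromosome are the sorted union of all segment starts
    and ends; bins are the consecutive breakpoint intervals intersected by
    at least one segment.  Every segment is then an exact union of bins,
    and the matrix entry is the state of the covering segment (recipient
    where none).
    """
    if not segments:
        raise ValueError("need at least one segment to build bins")
    if line_ids is None:
        line_ids = sorted({s.line_id for s in segments}, key=_natural_key)
    bins: list[Bin] = []
    per_chrom: dict[int, list[Segment]] = {}
    for s in segments:
        per_chrom.setdefault(s.chrom, []).append(s)
    next_id = 1
    for c in sorted(per_chrom):
        segs = per_chrom[c]
        pts = np.unique([p for s in segs for p in (s.start, s.end)])
        for lo, hi in zip(pts[:-1], pts[1:]):
            if any(s.start <= lo and s.end >= hi for s in segs):
                bins.append(Bin(next_id, c, int(lo), int(hi)))
                next_id += 1
    geno = np.zeros((len(line_ids), len(bins)), dtype=np.int8)
    idx = {l: i for i, l in enumerate(line_ids)}
    for s in segments:
        i = idx[s.line_id]
        for j, b in enumerate(bins):
            if b.chrom == s.chrom and s.start <= b.start and s.end >= b.end:
                geno[i, j] = 2 if s.state == W_DONOR else 1
    return BinMatrix(line_ids=list(line_ids), bins=bins, genotypes=geno)


def _natural_key(line_id: str):
    digits = "".join(ch for ch in line_id if ch.isdigit())
    return (int(digits) if digits else 0, line_id)
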