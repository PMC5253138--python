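"""End-to-end pipeline: simulate -> segments -> bins -> scan -> segtest -> finemap.

Every stage draws from an independent substream spawned from the single
run seed, so any stage is reproducible in isolation and identical
(config, seed) pairs give byte-identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import (BinMatrix, PanelStats, WindowParams, build_bins,
                      call_windows, merge_windows, panel_stats)
from .breeding import CsslLine, donor_union_coverage, f2_marker_population, simulate_cssl_panel
from .config import PipelineConfig
from .fertility import FertilityModelParams, seed_setting
from .genome import simulate_parents
from .io import write_json, write_phenotypes, write_segments_bed, write_snp_calls
from .mosaic import RecombinationMap
from .plants import RfLocus, cross, make_parent
from .qtl import BinScan, QtlHit
from .segregation import (FineMapResult, Marker, SegregationVerdict,
                          classify_population, gametophytic_test, narrow_interval)
from .snpcalls import emit_snp_calls

logger = logging.getLogger(__name__)

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    """Bundle of per-stage results from one pipeline run."""

    lines: list[CsslLine]
    stats: PanelStats
    bin_matrix: BinMatrix
    phenotypes: pd.DataFrame
    qtl_hits: list[QtlHit]
    qtl_threshold: float
    qtl_table: pd.DataFrame
    verdicts: dict[str, SegregationVerdict]
    finemap: dict[str, FineMapResult]
    finemap_contains_truth: dict[str, bool]
    coverage: float = 0.0
    summary: dict = field(default_factory=dict)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _testcross_phenotypes(
    lines: list[CsslLine], genome, recmap, rf_loci, params: FertilityModelParams,
    regime: str, n_reps: int, rng: np.random.Generator,
) -> pd.DataFrame:
    """NIPA x CSSL testcross F1 seed setting, averaged over replicates."""
    nipa = make_parent(genome, 0, "S", rf_loci, "NIPA")
    rows = {}
    for ln in lines:
        f1s = cross(nipa, ln.plant, n_reps, genome, recmap, rng, generation="F1")
        nat = [seed_setting(p, regime, "natural", params, rng) for p in f1s]
        bag = [seed_setting(p, regime, "bagged", params, rng) for p in f1s]
        rows[ln.line_id] = {
            "natural_pct": float(np.mean(nat)),
            "bagged_pct": float(np.mean(bag)),
            "regime": regime,
            "n_replicates": n_reps,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def _locus_on(chrom: int, rf_loci: tuple[RfLocus, ...]) -> RfLocus | None:
    for loc in rf_loci:
        if loc.chrom == chrom:
            return loc
    return None


def _segtest_for_hit(
    hit: QtlHit, rf_loci, marker_pos: int, n_f2: int, alpha: float,
    tolerance: float, recmap: RecombinationMap, rng: np.random.Generator,
) -> SegregationVerdict:
    """Selfed-F1 F2 genotyped at ``marker_pos``, then the 1:1 test."""
    locus = _locus_on(hit.chrom, rf_loci)
    if locus is not None:
        positions = sorted({marker_pos, locus.pos})
        rf_index = positions.index(locus.pos)
        geno = f2_marker_population(np.array(positions), rf_index, n_f2, rng, recmap)
        marker_col = geno[:, positions.index(marker_pos)]
    else:
        # marker unlinked to any restorer: plain Mendelian F2 at the marker
        marker_col = rng.integers(0, 2, size=n_f2) + rng.integers(0, 2, size=n_f2)
    df = pd.DataFrame({f"M{hit.chrom}": marker_col})
    counts = classify_population(df)[0]
    return gametophytic_test(counts, alpha=alpha, tolerance=tolerance)


def _finemap_for_hit(
    hit: QtlHit, rf_loci, genome, n_plants: int, n_markers: int, margin: int,
    recmap: RecombinationMap, rng: np.random.Generator,
) -> tuple[FineMapResult, bool]:
    """Recombinant screen across the hit's significant region.

    Markers span the whole supra-threshold bin run — the screen brackets
    the full QTL region with flanking markers before walking inward.
    """
    chrom_len = genome.lengths[hit.chrom]
    lo = max(1, hit.region_start - margin)
    hi = min(chrom_len, hit.region_end + margin)
    marker_pos = np.unique(np.linspace(lo, hi, n_markers).astype(np.int64))
    markers = [Marker(f"M{hit.chrom}_{i + 1}", hit.chrom, int(p))
               for i, p in enumerate(marker_pos)]
    locus = _locus_on(hit.chrom, rf_loci)
    if locus is None:
        raise ValueError(f"no restorer locus on chromosome {hit.chrom} to fine-map")
    positions = np.unique(np.concatenate([marker_pos, [locus.pos]]))
    rf_index = int(np.searchsorted(positions, locus.pos))
    geno = f2_marker_population(positions, rf_index, n_plants, rng, recmap)
    cols = {m.name: geno[:, int(np.searchsorted(positions, m.pos))] for m in markers}
    df = pd.DataFrame(cols, index=[f"P{i + 1}" for i in range(n_plants)])
    # every S-cytoplasm F2 plant carries Rf, hence is fertile/informative
    result = narrow_interval(df, markers, fertile=None, chrom_bounds=(1, chrom_len))
    contains = result.left_pos <= locus.pos <= result.right_pos
    return result, contains


def run_pipeline(
    config: PipelineConfig, seed: int, out_dir: str | Path | None = None
) -> PipelineReport:
    """Run the full inference chain on freshly simulated data."""
    genome = config.genome.build()
    recmap = RecombinationMap()
    rf_loci = tuple(l.build() for l in config.rf_loci)
    params = FertilityModelParams()
    (rng_panel, rng_cssl, rng_calls, rng_pheno, rng_scan,
     rng_seg, rng_fine) = _substreams(seed, 7)

    panel = simulate_parents(genome, config.snp_density, rng_panel)
    pinned = [(loc.chrom, loc.pos) for loc in rf_loci
              for _ in range(config.carrier_lines_per_locus)]
    lines = simulate_cssl_panel(
        genome, config.n_lines, config.n_backcrosses, rng_cssl,
        recmap=recmap, mas_batch=config.mas_batch, rf_loci=rf_loci,
        targets=pinned or None,
    )
    coverage = donor_union_coverage(lines, genome)
    matrix = emit_snp_calls(
        [(ln.plant.hap1, ln.plant.hap2) for ln in lines],
        [ln.line_id for ln in lines], panel,
        config.error_rate, config.missing_rate, rng_calls,
    )
    wp = WindowParams(config.window.window_size, config.window.step,
                      max_gap=config.window.max_gap)
    segments = merge_windows(call_windows(matrix, wp), max_gap=wp.max_gap)
    stats = panel_stats(segments, genome, len(lines))
    bin_matrix = build_bins(segments, [ln.line_id for ln in lines])

    pheno = _testcross_phenotypes(
        lines, genome, recmap, rf_loci, params, config.regime,
        config.f1_replicates, rng_pheno,
    )
    results = BinScan(bin_matrix, pheno["natural_pct"]).fit()
    hits, threshold = results.call_qtls(
        alpha=config.scan.alpha, n_permutations=config.scan.n_permutations,
        seed=rng_scan.integers(2**31),
    )
    qtl_table = results.to_table3(hits)

    verdicts: dict[str, SegregationVerdict] = {}
    finemap: dict[str, FineMapResult] = {}
    contains: dict[str, bool] = {}
    for hit in hits:
        if hit.flag.startswith("confounded"):
            continue
        # fine-map first; the segregation test then uses the most tightly
        # linked marker available — one inside the fine-mapped interval
        marker_pos = (hit.start + hit.end) // 2
        if _locus_on(hit.chrom, rf_loci) is not None:
            fm, ok = _finemap_for_hit(
                hit, rf_loci, genome, config.finemap.n_plants,
                config.finemap.n_markers, config.finemap.margin_bp, recmap, rng_fine,
            )
            finemap[hit.name] = fm
            contains[hit.name] = ok
            marker_pos = (fm.left_pos + fm.right_pos) // 2
        verdicts[hit.name] = _segtest_for_hit(
            hit, rf_loci, marker_pos, config.segtest.n_f2, config.segtest.alpha,
            config.segtest.tolerance, recmap, rng_seg,
        )

    summary = {
        "n_lines": len(lines),
        "n_snps": len(panel),
        "n_segments": stats.total_segments,
        "total_length_mb": round(stats.total_length_mb, 4),
        "coverage_pct": round(100.0 * coverage, 4),
        "n_bins": len(bin_matrix.bins),
        "qtl_threshold_F": round(threshold, 4),
        "qtls": [
            {"name": h.name, "chrom": h.chrom, "bin": h.bin_id,
             "interval": f"{h.start}-{h.end}", "size": h.size,
             "partial_r2": round(h.partial_r2, 4), "F": round(h.f_stat, 4),
             "flag": h.flag}
            for h in hits
        ],
        "segregation": {
            name: {"verdict": v.verdict, "chi2": round(v.chi2, 4),
                   "p": round(v.p_value, 6), "hom_recipient": v.n_hom_recipient}
            for name, v in verdicts.items()
        },
        "finemap": {
            name: {"interval": f"{fm.left_pos}-{fm.right_pos}", "size": fm.size,
                   "left_marker": fm.left_marker, "right_marker": fm.right_marker,
                   "contains_planted_locus": contains[name]}
            for name, fm in finemap.items()
        },
    }

    report = PipelineReport(
        lines=lines, stats=stats, bin_matrix=bin_matrix, phenotypes=pheno,
        qtl_hits=hits, qtl_threshold=threshold, qtl_table=qtl_table,
        verdicts=verdicts, finemap=finemap, finemap_contains_truth=contains,
        coverage=coverage, summary=summary,
    )
    if out_dir is not None:
        _write_artifacts(report, matrix, segments, Path(out_dir))
    return report


def _write_artifacts(report: PipelineReport, matrix, segments, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_snp_calls(matrix, out / "snp_calls.tsv")
    write_segments_bed(segments, out / "segments.bed")
    true_segs = []
    from .binning import Segment

    for ln in report.lines:
        for c, ivs in ln.true_segments.items():
            for s, e in ivs:
                true_segs.append(Segment(ln.line_id, c, s + 1, e + 1, 2))
    write_segments_bed(true_segs, out / "true_segments.bed")
    report.stats.table.to_csv(out / "panel_stats.tsv", sep="\t",
                              index_label="chrom", float_format="%.6g",
                              lineterminator="\n")
    bins_df = pd.DataFrame(
        [{"bin": b.id, "chrom": b.chrom, "start": b.start, "end": b.end}
         for b in report.bin_matrix.bins]
    )
    bins_df.to_csv(out / "bins.tsv", sep="\t", index=False, lineterminator="\n")
    write_phenotypes(report.phenotypes, out / "phenotypes.tsv")
    report.qtl_table.to_csv(out / "qtl_hits.tsv", sep="\t", index=False,
                            float_format="%.10g", lineterminator="\n")
    write_json(report.summary, out / "report.json")
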