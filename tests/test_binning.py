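import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rfmap as rf
from rfmap.binning import (W_AMBIGUOUS, W_DONOR, W_HET, W_RECIPIENT,
                           WindowParams, build_bins, call_windows,
                           classify_window, merge_windows, panel_stats)
from rfmap.mosaic import DONOR, RECIPIENT
from rfmap.snpcalls import SnpCallMatrix


def _panel(positions):
    n = len(positions)
    return rf.SnpPanel(
        chrom=np.ones(n, dtype=np.int32),
        pos=np.asarray(positions, dtype=np.int64),
        donor_allele=np.full(n, "A"),
        recipient_allele=np.full(n, "G"),
    )


def _matrix(calls, positions=None):
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[None, :]
    if positions is None:
        positions = 1000 * (np.arange(calls.shape[1]) + 1)
    return SnpCallMatrix(
        line_ids=[f"L{i + 1}" for i in range(calls.shape[0])],
        panel=_panel(positions),
        calls=calls,
    )


class TestClassifyWindow:
    def test_all_donor_is_donor_hom(self):
        assert classify_window(15, 0, 0, WindowParams()) == W_DONOR

    def test_seven_donor_eight_recipient_is_het_by_dosage(self):
        """Dosage (2*7 + 0) / 30 = 0.467 falls in the het band."""
        assert classify_window(7, 0, 8, WindowParams()) == W_HET

    def test_all_het_calls_is_het(self):
        assert classify_window(0, 15, 0, WindowParams()) == W_HET

    def test_all_missing_is_ambiguous(self):
        assert classify_window(0, 0, 0, WindowParams()) == W_AMBIGUOUS

    def test_dosage_outside_band_without_majority_is_ambiguous(self):
        # 11 donor + 4 recipient: donor frac 0.73 < 0.8, dosage 0.73 > 0.7
        assert classify_window(11, 0, 4, WindowParams()) == W_AMBIGUOUS


class TestCallWindows:
    def test_error_free_recipient_line_all_windows_recipient(self):
        m = _matrix(np.zeros(60, dtype=np.int8))
        calls = call_windows(m, WindowParams(15, 5))
        assert calls and all(wc.call == W_RECIPIENT for wc in calls)

    def test_window_spans_are_snp_positions(self):
        m = _matrix(np.full(30, 2, dtype=np.int8))
        calls = call_windows(m, WindowParams(15, 5))
        assert calls[0].start == 1000 and calls[0].end == 15_000
        assert all(wc.call == W_DONOR for wc in calls)

    def test_window_params_validated(self):
        with pytest.raises(ValueError):
            WindowParams(2, 1)
        with pytest.raises(ValueError):
            WindowParams(15, 16)


class TestMergeWindows:
    def test_single_donor_run_becomes_one_segment(self):
        row = np.full(45, 2, dtype=np.int8)
        m = _matrix(row)
        segs = merge_windows(call_windows(m, WindowParams(15, 5)))
        assert len(segs) == 1
        s = segs[0]
        assert s.state == W_DONOR and s.start == 1000 and s.end == 45_000

    def test_ambiguous_gap_is_bridged(self):
        # donor run, one ambiguous window (11d+4r: dosage 0.73), donor run
        ambig = [2] * 11 + [0] * 4
        row = np.concatenate([np.full(15, 2), ambig, np.full(15, 2)]).astype(np.int8)
        m = _matrix(row)
        segs = merge_windows(call_windows(m, WindowParams(15, 15)), max_gap=1)
        assert len(segs) == 1
        assert segs[0].start == 1000 and segs[0].end == 45_000

    def test_gap_beyond_limit_splits_segments(self):
        ambig = [2] * 11 + [0] * 4
        row = np.concatenate([
            np.full(15, 2), ambig, ambig, np.full(15, 2)
        ]).astype(np.int8)
        m = _matrix(row)
        segs = merge_windows(call_windows(m, WindowParams(15, 15)), max_gap=1)
        assert len(segs) == 2

    def test_recovered_segments_match_simulated_truth(self, small_genome, recmap, rng):
        """Round trip: error-free dense SNPs recover true donor segments to
        within one window span."""
        panel = rf.simulate_parents(small_genome, 400, seed=21)
        lines = rf.simulate_cssl_panel(small_genome, 8, 3, rng, mas_batch=6)
        m = rf.emit_snp_calls(
            [(l.plant.hap1, l.plant.hap2) for l in lines],
            [l.line_id for l in lines], panel, 0.0, 0.0, rng)
        wp = WindowParams(15, 5)
        segs = merge_windows(call_windows(m, wp), max_gap=1)
        window_span_bp = wp.window_size * 1e6 / 400 * 3  # generous slack
        for ln in lines:
            true = {(c, s, e) for c, ivs in ln.true_segments.items() for s, e in ivs
                    if e - s > window_span_bp}
            called = [(s.chrom, s.start, s.end) for s in segs if s.line_id == ln.line_id]
            for c, s0, e0 in true:
                match = [x for x in called if x[0] == c and x[1] < e0 and x[2] > s0]
                assert match, f"true segment {c}:{s0}-{e0} of {ln.line_id} missed"
                c_, s_, e_ = max(match, key=lambda x: x[2] - x[1])
                assert abs(s_ - s0) < window_span_bp and abs(e_ - e0) < window_span_bp


class TestPanelStats:
    def test_totals_equal_column_sums(self, small_genome):
        segs = [
            rf.Segment("L1", 1, 1_000, 5_000_000, W_DONOR),
            rf.Segment("L2", 1, 2_000_000, 9_000_000, W_DONOR),
            rf.Segment("L2", 2, 1_000, 20_000_000, W_DONOR),
        ]
        st_ = panel_stats(segs, small_genome, 2)
        per_chrom = st_.table.drop(index="Total")
        assert st_.total_segments == per_chrom["n_segments"].sum()
        assert st_.total_length_mb == pytest.approx(per_chrom["length_mb"].sum())

    def test_full_chromosome_density_100(self, small_genome):
        segs = [rf.Segment("L1", 3, 1, 10_000_000, W_DONOR)]
        st_ = panel_stats(segs, small_genome, 1)
        assert st_.table.loc[3, "density_pct"] == pytest.approx(100.0, abs=0.01)

    def test_identical_segments_in_two_lines_count_twice_union_once(self, small_genome):
        seg = (1, 1_000_000, 2_000_000)
        segs = [rf.Segment("L1", *seg, W_DONOR), rf.Segment("L2", *seg, W_DONOR)]
        st_ = panel_stats(segs, small_genome, 2)
        assert st_.table.loc[1, "n_segments"] == 2
        one = panel_stats(segs[:1], small_genome, 1)
        assert st_.table.loc[1, "density_pct"] == one.table.loc[1, "density_pct"]

    def test_segment_outside_chromosome_rejected(self, small_genome):
        with pytest.raises(ValueError):
            panel_stats([rf.Segment("L1", 3, 1, 99_000_000, W_DONOR)], small_genome, 1)


class TestBuildBins:
    def test_identical_segments_give_single_bin(self):
        segs = [rf.Segment("L1", 1, 100, 500, W_DONOR),
                rf.Segment("L2", 1, 100, 500, W_DONOR)]
        bm = build_bins(segs)
        assert len(bm.bins) == 1
        assert np.all(bm.genotypes == 2)

    def test_overlapping_segments_split_into_three_bins(self):
        segs = [rf.Segment("L1", 1, 0 + 1, 10, W_DONOR),
                rf.Segment("L2", 1, 5, 15, W_DONOR)]
        bm = build_bins(segs)
        coords = [(b.start, b.end) for b in bm.bins]
        assert coords == [(1, 5), (5, 10), (10, 15)]
        assert bm.genotypes.tolist() == [[2, 2, 0], [0, 2, 2]]

    def test_bin_ids_serial_in_genome_order(self):
        segs = [rf.Segment("L1", 2, 10, 20, W_DONOR),
                rf.Segment("L1", 1, 5, 9, W_DONOR)]
        bm = build_bins(segs)
        assert [b.id for b in bm.bins] == [1, 2]
        assert [b.chrom for b in bm.bins] == [1, 2]

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_every_segment_is_exact_union_of_bins(self, seed):
        rng = np.random.default_rng(seed)
        segs = []
        for i in range(rng.integers(1, 30)):
            chrom = int(rng.integers(1, 4))
            s = int(rng.integers(1, 900))
            e = s + int(rng.integers(1, 100))
            segs.append(rf.Segment(f"L{rng.integers(1, 10)}", chrom, s, e,
                                   W_DONOR if rng.random() < 0.8 else W_HET))
        # segments of one line on one chromosome may overlap in this draw;
        # deduplicate line/chrom overlaps by keeping the first
        seen = []
        clean = []
        for s in segs:
            if not any(s.line_id == t.line_id and s.chrom == t.chrom
                       and s.start < t.end and s.end > t.start for t in clean):
                clean.append(s)
        bm = build_bins(clean)
        for s in clean:
            covering = sorted(
                [(b.start, b.end) for b in bm.bins
                 if b.chrom == s.chrom and b.start >= s.start and b.end <= s.end])
            assert covering[0][0] == s.start
            assert covering[-1][1] == s.end
            for (a1, e1), (s2, e2) in zip(covering, covering[1:]):
                assert e1 == s2  # contiguous tiling of the segment

    def test_bin_genotype_constant_within_bin(self, small_genome, rng):
        """Re-reading genotype at any interior point of a bin from the
        source segments gives the matrix entry."""
        lines = rf.simulate_cssl_panel(small_genome, 6, 3, rng, mas_batch=6)
        segs = []
        for ln in lines:
            for c, ivs in ln.true_segments.items():
                for s, e in ivs:
                    segs.append(rf.Segment(ln.line_id, c, s + 1, e + 1, W_DONOR))
        bm = build_bins(segs, [ln.line_id for ln in lines])
        for j, b in enumerate(bm.bins):
            mid = (b.start + b.end) // 2
            for i, ln in enumerate(lines):
                covered = any(
                    s.start <= mid < s.end for s in segs
                    if s.line_id == ln.line_id and s.chrom == b.chrom)
                assert (bm.genotypes[i, j] > 0) == covered
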