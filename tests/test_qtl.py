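import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway

import rfmap as rf
from rfmap.binning import Bin, BinMatrix
from rfmap.qtl import BinScan, scan_bins


def _bin_matrix(geno, n_per_chrom=None):
    geno = np.asarray(geno, dtype=np.int8)
    n_lines, n_bins = geno.shape
    bins = [Bin(j + 1, 1, 1000 * j + 1, 1000 * (j + 1)) for j in range(n_bins)]
    return BinMatrix(
        line_ids=[f"L{i + 1}" for i in range(n_lines)],
        bins=bins, genotypes=geno,
    )


def _pheno(values, ids=None):
    ids = ids or [f"L{i + 1}" for i in range(len(values))]
    return pd.Series(values, index=ids, dtype=float)


class TestScanBins:
    def test_constant_phenotype_gives_zero_f_and_r2(self):
        bm = _bin_matrix([[2, 0], [0, 2], [2, 0], [0, 0]])
        res = scan_bins(bm, _pheno([50, 50, 50, 50]))
        assert np.all(res.f_stats[~np.isnan(res.f_stats)] == 0)
        assert np.all(res.partial_r2[~np.isnan(res.partial_r2)] == 0)

    def test_two_group_toy_matches_anova_oracle(self):
        """Donor lines {90, 92} vs recipient {10, 12}: exact agreement with
        scipy's one-way ANOVA to 1e-10."""
        bm = _bin_matrix([[2], [2], [0], [0]])
        y = [90.0, 92.0, 10.0, 12.0]
        res = scan_bins(bm, _pheno(y))
        f_ref, p_ref = f_oneway([90, 92], [10, 12])
        assert res.f_stats[0] == pytest.approx(f_ref, abs=1e-10)
        assert res.p_values[0] == pytest.approx(p_ref, abs=1e-10)
        # partial R^2 from sums of squares directly
        ym = np.mean(y)
        ssb = 2 * (91 - ym) ** 2 + 2 * (11 - ym) ** 2
        sst = sum((v - ym) ** 2 for v in y)
        assert res.partial_r2[0] == pytest.approx(ssb / sst, abs=1e-12)

    def test_exhaustive_oracle_agreement_on_random_panels(self):
        """Every bin of random panels up to 20 lines agrees with the
        brute-force ANOVA oracle to 1e-10."""
        rng = np.random.default_rng(99)
        for trial in range(20):
            n = int(rng.integers(4, 21))
            m = int(rng.integers(1, 15))
            geno = rng.integers(0, 3, size=(n, m)).astype(np.int8)
            y = rng.normal(50, 20, size=n)
            res = scan_bins(_bin_matrix(geno), _pheno(y))
            for j in range(m):
                carrier = geno[:, j] > 0
                if carrier.all() or not carrier.any():
                    assert np.isnan(res.f_stats[j])
                    continue
                f_ref, p_ref = f_oneway(y[carrier], y[~carrier])
                assert res.f_stats[j] == pytest.approx(f_ref, abs=1e-10, rel=1e-10)
                assert res.p_values[j] == pytest.approx(p_ref, abs=1e-10)

    def test_monomorphic_bin_flagged(self):
        bm = _bin_matrix([[2, 2], [0, 2], [2, 2], [0, 2]])
        res = scan_bins(bm, _pheno([90, 10, 92, 12]))
        assert np.isnan(res.f_stats[1])
        assert res.table["flag"].tolist() == ["", "monomorphic"]

    def test_no_segregation_anywhere_rejected(self):
        with pytest.raises(ValueError, match="no segregation"):
            BinScan(_bin_matrix([[2, 2], [2, 2]]), _pheno([1, 2]))

    def test_phenotype_must_cover_all_lines(self):
        with pytest.raises(ValueError, match="missing"):
            BinScan(_bin_matrix([[2], [0]]), pd.Series({"L1": 5.0}))


class TestCallQtls:
    def test_planted_restorer_gives_peak_at_its_bin(self, rng):
        """50 lines, one planted effect bin: strongest F lands there and the
        Table-2-scale effect (fertile ~85-93 vs sterile <5) is always found."""
        n, m = 50, 30
        hits_found = 0
        for rep in range(30):
            geno = np.zeros((n, m), dtype=np.int8)
            for i in range(n):  # each line carries 1-3 random bins
                geno[i, rng.choice(m, size=rng.integers(1, 4), replace=False)] = 2
            causal = 12
            geno[:3, causal] = 2  # designed panel: >= 3 carrier lines
            carrier = geno[:, causal] > 0
            if carrier.all():
                continue
            y = np.where(carrier, rng.normal(89, 3, n), rng.uniform(0, 5, n))
            res = scan_bins(_bin_matrix(geno), _pheno(y))
            hits, thr = res.call_qtls(alpha=0.05, n_permutations=200,
                                      seed=int(rng.integers(2**31)))
            top = max(hits, key=lambda h: h.f_stat, default=None)
            if top is not None and top.bin_id == causal + 1:
                hits_found += 1
        assert hits_found >= 29

    def test_null_false_positive_rate_matches_alpha(self):
        """With no effect anywhere, genome-wide hits at alpha=0.05 appear in
        5% of runs (3-sigma band over 200 replicates)."""
        rng = np.random.default_rng(7)
        n, m, reps = 30, 25, 200
        fp = 0
        for _ in range(reps):
            geno = (rng.random((n, m)) < 0.3).astype(np.int8) * 2
            poly = (geno > 0).any(0) & ~(geno > 0).all(0)
            if not poly.any():
                continue
            y = rng.normal(50, 10, size=n)
            res = scan_bins(_bin_matrix(geno), _pheno(y))
            hits, _ = res.call_qtls(alpha=0.05, n_permutations=199,
                                    seed=int(rng.integers(2**31)))
            fp += bool(hits)
        rate = fp / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_threshold_invariant_to_line_relabeling(self):
        rng = np.random.default_rng(13)
        geno = (rng.random((20, 10)) < 0.4).astype(np.int8) * 2
        y = rng.normal(60, 8, size=20)
        bm1 = _bin_matrix(geno)
        res1 = scan_bins(bm1, _pheno(y))
        # rename every line id consistently in matrix and phenotype
        new_ids = [f"X{i}" for i in range(20)]
        bm2 = BinMatrix(line_ids=new_ids, bins=bm1.bins, genotypes=geno)
        res2 = scan_bins(bm2, _pheno(y, ids=new_ids))
        t1 = res1.permutation_threshold(0.05, 300, np.random.default_rng(5))
        t2 = res2.permutation_threshold(0.05, 300, np.random.default_rng(5))
        assert t1 == t2

    def test_interval_size_is_end_minus_start(self):
        hit = rf.QtlHit("qSF8-1", 222, 8, 1, 688_039, 0.5, 100.0, 1e-9, ("L1",))
        assert hit.size == 688_038

    def test_confounded_hit_flagged(self):
        """A hit whose carriers are a strict subset of another hit's
        carriers cannot be separated and is flagged (the qSF12-1 case)."""
        rng = np.random.default_rng(3)
        n = 40
        geno = np.zeros((n, 3), dtype=np.int8)
        carriers_a = [0, 1, 2, 3]       # bin 1: real restorer
        carriers_b = [3]                # bin 3: only line 3 (subset)
        geno[carriers_a, 0] = 2
        geno[10:14, 1] = 2              # neutral polymorphic bin
        geno[carriers_b, 2] = 2
        y = rng.uniform(0, 5, n)
        y[carriers_a] = rng.normal(89, 3, len(carriers_a))
        bins = [Bin(1, 8, 1, 688_039), Bin(2, 9, 1, 1000), Bin(349, 12, 4_816_707, 6_620_947)]
        bm = BinMatrix([f"L{i}" for i in range(n)], bins, geno)
        res = scan_bins(bm, _pheno(y, ids=bm.line_ids))
        hits, _ = res.call_qtls(alpha=0.05, n_permutations=300, seed=42)
        by_chrom = {h.chrom: h for h in hits}
        assert 8 in by_chrom and by_chrom[8].flag == ""
        if 12 in by_chrom:
            assert by_chrom[12].flag.startswith("confounded")

    def test_summary_mentions_dimensions(self):
        bm = _bin_matrix([[2], [0], [2], [0]])
        res = scan_bins(bm, _pheno([90, 10, 92, 12]))
        s = res.summary()
        assert "lines: 4" in s and "bins: 1" in s
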