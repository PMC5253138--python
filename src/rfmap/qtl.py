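"""Bin-level QTL scan of seed-setting phenotypes.

``BinScan`` is a model object in the statsmodels mould: it holds a line-by-
bin genotype matrix and a per-line phenotype, ``fit()`` performs a one-way
fixed-effect ANOVA at every bin (donor-carrying vs recipient lines) and
returns a ``BinScanResults`` carrying per-bin F statistics, partial R-
squared, p-values and a ``summary()`` table.  Genome-wide significance is
assessed by permutation: the (1 - alpha) quantile of the max-F statistic
over phenotype permutations.  Contiguous supra-threshold bins merge into
one hit reported at its peak bin, named ``qSF{chrom}-{serial}``.

A hit whose carrier lines all also carry another hit's peak bin cannot be
distinguished from that hit with this panel; the conditional rescan flags
it "confounded".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .binning import Bin, BinMatrix

__all__ = ["BinScan", "BinScanResults", "QtlHit", "scan_bins"]


@dataclass(frozen=True)
class QtlHit:
    """A significant fertility-restoration QTL (Table-3 shape)."""

    name: str  # qSF{chrom}-{serial}
    bin_id: int
    chrom: int
    start: int
    end: int
    partial_r2: float
    f_stat: float
    p_value: float
    carriers: tuple[str, ...]
    flag: str = ""  # '' or 'confounded:<other hit>'
    region_start: int = 0  # extent of the whole supra-threshold bin run
    region_end: int = 0

    @property
    def size(self) -> int:
        return self.end - self.start


def _anova_all_bins(geno: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-group one-way ANOVA per bin.

    Groups are carrier (dosage > 0) vs non-carrier lines.  Returns (F,
    partial R^2) arrays; monomorphic bins get NaN.  When the between-group
    sum of squares is zero (e.g. constant phenotype) F and R^2 are 0.
    """
    n = len(y)
    carrier = geno > 0
    n1 = carrier.sum(axis=0).astype(float)
    n0 = n - n1
    ybar = y.mean()
    sst = float(np.sum((y - ybar) ** 2))
    s1 = carrier.T.astype(float) @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = s1 / n1
        m0 = (y.sum() - s1) / n0
        ssb = n1 * (m1 - ybar) ** 2 + n0 * (m0 - ybar) ** 2
        ssw = sst - ssb
        f = (ssb / 1.0) / (ssw / (n - 2))
        r2 = ssb / sst if sst > 0 else np.zeros_like(ssb)
    zero_effect = np.isclose(ssb, 0.0, atol=1e-12 * max(sst, 1.0))
    f = np.where(zero_effect, 0.0, f)
    r2 = np.where(zero_effect, 0.0, r2)
    mono = (n1 == 0) | (n0 == 0)
    f[mono] = np.nan
    r2[mono] = np.nan
    return f, r2


class BinScan:
    """One-way ANOVA QTL scan over a bin map.

    Parameters
    ----------
    bin_matrix : BinMatrix
        Line-by-bin donor-dosage genotypes.
    phenotypes : pandas.Series or mapping
        Per-line phenotype (natural seed-setting %), indexed by line id.
    """

    def __init__(self, bin_matrix: BinMatrix, phenotypes) -> None:
        self.bin_matrix = bin_matrix
        pheno = pd.Series(phenotypes)
        missing = [l for l in bin_matrix.line_ids if l not in pheno.index]
        if missing:
            raise ValueError(f"phenotype missing for lines: {missing[:5]}")
        self.y = pheno.loc[bin_matrix.line_ids].to_numpy(dtype=float)
        carrier = bin_matrix.genotypes > 0
        poly = (carrier.any(axis=0)) & (~carrier.all(axis=0))
        if not poly.any():
            raise ValueError("no segregation: all lines monomorphic at every bin")

    @classmethod
    def from_dataframe(cls, genotypes: pd.DataFrame, phenotypes) -> "BinScan":
        """Build from a line x bin DataFrame whose columns are Bin objects
        or (chrom, start, end) tuples."""
        bins = []
        for k, col in enumerate(genotypes.columns):
            if isinstance(col, Bin):
                bins.append(col)
            else:
                c, s, e = col
                bins.append(Bin(k + 1, int(c), int(s), int(e)))
        bm = BinMatrix(
            line_ids=list(genotypes.index),
            bins=bins,
            genotypes=genotypes.to_numpy(dtype=np.int8),
        )
        return cls(bm, phenotypes)

    def fit(self) -> "BinScanResults":
        f, r2 = _anova_all_bins(self.bin_matrix.genotypes, self.y)
        n = len(self.y)
        with np.errstate(invalid="ignore"):
            p = stats.f.sf(f, 1, n - 2)
        return BinScanResults(self, f, r2, p)


class BinScanResults:
    """Per-bin scan statistics plus permutation-based QTL calling."""

    def __init__(self, model: BinScan, f: np.ndarray, r2: np.ndarray, p: np.ndarray) -> None:
        self.model = model
        self.f_stats = f
        self.partial_r2 = r2
        self.p_values = p

    @property
    def table(self) -> pd.DataFrame:
        bins = self.model.bin_matrix.bins
        return pd.DataFrame(
            {
                "bin": [b.id for b in bins],
                "chrom": [b.chrom for b in bins],
                "start": [b.start for b in bins],
                "end": [b.end for b in bins],
                "size": [b.size for b in bins],
                "partial_r2": self.partial_r2,
                "F": self.f_stats,
                "p": self.p_values,
                "flag": ["monomorphic" if np.isnan(f) else "" for f in self.f_stats],
            }
        )

    def summary(self, top: int = 10) -> str:
        tab = self.table.dropna(subset=["F"]).sort_values("F", ascending=False).head(top)
        lines = [
            "Bin-level QTL scan (one-way ANOVA, donor carriers vs recipient lines)",
            f"lines: {len(self.model.y)}   bins: {len(self.model.bin_matrix.bins)}",
            "",
            tab.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def permutation_threshold(
        self, alpha: float, n_permutations: int, rng: np.random.Generator
    ) -> float:
        """Genome-wide (1 - alpha) quantile of max-F over phenotype permutations."""
        if n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        geno = self.model.bin_matrix.genotypes
        y = self.model.y
        max_f = np.empty(n_permutations)
        for b in range(n_permutations):
            f, _ = _anova_all_bins(geno, rng.permutation(y))
            max_f[b] = np.nanmax(f)
        return float(np.quantile(max_f, 1.0 - alpha))

    def call_qtls(
        self,
        alpha: float = 0.05,
        n_permutations: int = 1000,
        seed=None,
        trait: str = "SF",
    ) -> tuple[list[QtlHit], float]:
        """Call QTLs at a permutation-derived genome-wide threshold.

        Returns (hits, threshold).  Hits are peak bins of contiguous
        supra-threshold runs, named q{trait}{chrom}-{serial}; hits whose
        carriers are indistinguishable from another hit's carriers are
        flagged 'confounded' by the conditional rescan.
        """
        rng = np.random.default_rng(seed)
        threshold = self.permutation_threshold(alpha, n_permutations, rng)
        bins = self.model.bin_matrix.bins
        above = np.where(np.nan_to_num(self.f_stats, nan=-np.inf) > threshold)[0]
        hits: list[QtlHit] = []
        if len(above):
            runs: list[list[int]] = [[int(above[0])]]
            for j in above[1:]:
                prev = runs[-1][-1]
                if j == prev + 1 and bins[j].chrom == bins[prev].chrom:
                    runs[-1].append(int(j))
                else:
                    runs.append([int(j)])
            runs = self._merge_nested_runs(runs)
            serial_per_chrom: dict[int, int] = {}
            for run in runs:
                peak = max(run, key=lambda j: self.f_stats[j])
                b = bins[peak]
                serial_per_chrom[b.chrom] = serial_per_chrom.get(b.chrom, 0) + 1
                hits.append(QtlHit(
                    name=f"q{trait}{b.chrom}-{serial_per_chrom[b.chrom]}",
                    bin_id=b.id, chrom=b.chrom, start=b.start, end=b.end,
                    partial_r2=float(self.partial_r2[peak]),
                    f_stat=float(self.f_stats[peak]),
                    p_value=float(self.p_values[peak]),
                    carriers=tuple(self.model.bin_matrix.carriers(peak)),
                    region_start=min(bins[j].start for j in run),
                    region_end=max(bins[j].end for j in run),
                ))
        hits = self._flag_confounded(hits)
        return hits, threshold

    def _merge_nested_runs(self, runs: list[list[int]]) -> list[list[int]]:
        """Merge same-chromosome supra-threshold runs with nested carrier
        sets.

        A single introgression can split into two significant runs when
        intermediate bins (carried by extra, non-restoring lines) dip
        below threshold; runs whose peak carrier sets are nested carry the
        same fertile-line signal and are reported as one region.  Distinct
        linked QTLs with non-nested carriers stay separate."""
        bins = self.model.bin_matrix.bins
        merged = True
        while merged and len(runs) > 1:
            merged = False
            for k in range(len(runs) - 1):
                a, b = runs[k], runs[k + 1]
                if bins[a[-1]].chrom != bins[b[0]].chrom:
                    continue
                pa = max(a, key=lambda j: self.f_stats[j])
                pb = max(b, key=lambda j: self.f_stats[j])
                ca = set(self.model.bin_matrix.carriers(pa))
                cb = set(self.model.bin_matrix.carriers(pb))
                if ca <= cb or cb <= ca:
                    runs[k:k + 2] = [a + b]
                    merged = True
                    break
        return runs

    def _flag_confounded(self, hits: list[QtlHit]) -> list[QtlHit]:
        """Conditional rescan: a hit with no carrier private to it,
        relative to some other hit with a strictly larger carrier set, is
        flagged confounded."""
        out = []
        for a in hits:
            flag = ""
            ca = set(a.carriers)
            for b in hits:
                if b is a:
                    continue
                cb = set(b.carriers)
                if ca <= cb and ca != cb:
                    flag = f"confounded:{b.name}"
                    break
            out.append(QtlHit(**{**a.__dict__, "flag": flag}))
        return out

    def to_table3(self, hits: list[QtlHit]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "QTL": [h.name for h in hits],
                "Bin": [h.bin_id for h in hits],
                "Chr": [h.chrom for h in hits],
                "Interval": [f"{h.start}-{h.end}" for h in hits],
                "Size": [h.size for h in hits],
                "PartialR2": [h.partial_r2 for h in hits],
                "F": [h.f_stat for h in hits],
                "p": [h.p_value for h in hits],
                "flag": [h.flag for h in hits],
            }
        )


def scan_bins(bin_matrix: BinMatrix, phenotypes) -> BinScanResults:
    """Functional wrapper: fit a BinScan and return its results."""
    return BinScan(bin_matrix, phenotypes).fit()
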