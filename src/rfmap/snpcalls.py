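"""SNP-call matrices: the pipeline's observational input.

Calls are donor-allele dosages per line per SNP with codes
2 = donor-homozygous, 1 = heterozygous, 0 = recipient-homozygous,
-1 = missing.  ``emit_snp_calls`` reads truth from simulated mosaic
diplotypes and corrupts it with genotyping error (a call flipped to one
of the other two states) and missingness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import SnpPanel
from .mosaic import Haplotype

__all__ = ["MISSING", "SnpCallMatrix", "emit_snp_calls", "true_snp_calls"]

MISSING = -1


@dataclass
class SnpCallMatrix:
    """Lines x SNPs donor-dosage calls over a shared panel."""

    line_ids: list[str]
    panel: SnpPanel
    calls: np.ndarray  # int8 (n_lines, n_snps)

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.line_ids), len(self.panel)):
            raise ValueError("calls shape does not match line_ids x panel")
        valid = np.isin(self.calls, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("calls must be in {-1, 0, 1, 2}")

    def row(self, line_id: str) -> np.ndarray:
        return self.calls[self.line_ids.index(line_id)]


def true_snp_calls(
    diplotypes: list[tuple[Haplotype, Haplotype]], panel: SnpPanel
) -> np.ndarray:
    """Noise-free dosage matrix from mosaic diplotypes."""
    n, m = len(diplotypes), len(panel)
    out = np.empty((n, m), dtype=np.int8)
    for i, (h1, h2) in enumerate(diplotypes):
        for c in panel.chromosomes:
            sl = panel.slice_chrom(c)
            pos = panel.pos[sl]
            out[i, sl] = h1.origin_at(c, pos) + h2.origin_at(c, pos)
    return out


def emit_snp_calls(
    diplotypes: list[tuple[Haplotype, Haplotype]],
    line_ids: list[str],
    panel: SnpPanel,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> SnpCallMatrix:
    """Emit noisy SNP calls from true diplotypes.

    Each call is flipped to one of the two other genotype states with
    probability ``error_rate``, then dropped to missing with probability
    ``missing_rate`` (rates in [0, 1)).
    """
    for name, r in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= r < 1.0:
            raise ValueError(f"{name} must be in [0, 1)")
    calls = true_snp_calls(diplotypes, panel)
    if error_rate > 0:
        flip = rng.random(calls.shape) < error_rate
        # move to one of the other two states uniformly
        offset = rng.integers(1, 3, size=calls.shape)
        calls = np.where(flip, (calls + offset) % 3, calls).astype(np.int8)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate, MISSING, calls).astype(np.int8)
    return SnpCallMatrix(line_ids=list(line_ids), panel=panel, calls=calls)
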