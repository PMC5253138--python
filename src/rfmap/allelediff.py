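"""Pairwise allele comparison: substitutions and indels between two
candidate-gene sequences.

Sequences are globally aligned under unit mismatch and unit gap costs
(Needleman-Wunsch edit distance); substitutions and insertions/deletions
are read off the alignment path.  Positions are 1-based on the first
sequence (the reference allele), so an insertion reported at position p
sits immediately before reference base p — the "+p" convention used when
describing variants relative to a gene start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

__all__ = ["AlleleDiff", "Substitution", "Indel", "diff_alleles"]

_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class Substitution:
    pos: int  # 1-based on seq_a
    ref: str
    alt: str


@dataclass(frozen=True)
class Indel:
    pos: int  # 1-based on seq_a; insertions sit before this base
    kind: str  # 'ins' | 'del'
    seq: str  # inserted (from seq_b) or deleted (from seq_a) bases

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AlleleDiff:
    substitutions: list[Substitution] = field(default_factory=list)
    indels: list[Indel] = field(default_factory=list)

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    @property
    def n_indels(self) -> int:
        return len(self.indels)


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def diff_alleles(seq_a: str, seq_b: str) -> AlleleDiff:
    """Catalogue differences of ``seq_b`` relative to ``seq_a``.

    Both sequences must be non-empty and over {A, C, G, T}.  Runs of
    consecutive mismatches are reported base-by-base as substitutions;
    each maximal gap becomes one indel record.
    """
    for name, s in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not s:
            raise ValueError(f"{name} is empty")
        if not set(s) <= _ALPHABET:
            raise ValueError(f"{name} contains characters outside ACGT")
    res = edlib.align(seq_b, seq_a, mode="NW", task="path")
    diff = AlleleDiff()
    pa = pb = 0  # 0-based cursors on seq_a (target) and seq_b (query)
    for length, op in _parse_cigar(res["cigar"]):
        if op == "=":
            pa += length
            pb += length
        elif op == "X":
            for k in range(length):
                diff.substitutions.append(
                    Substitution(pa + k + 1, seq_a[pa + k], seq_b[pb + k])
                )
            pa += length
            pb += length
        elif op == "D":
            # consumes target (seq_a) only: bases of seq_a absent in seq_b
            diff.indels.append(Indel(pa + 1, "del", seq_a[pa:pa + length]))
            pa += length
        elif op == "I":
            # consumes query (seq_b) only: bases inserted relative to seq_a
            diff.indels.append(Indel(pa + 1, "ins", seq_b[pb:pb + length]))
            pb += length
        else:  # pragma: no cover
            raise ValueError(f"unexpected CIGAR op {op!r}")
    return diff
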