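"""Text interchange: TSV, BED, FASTA and JSON readers/writers.

Internal coordinates are 1-based with interval size = end - start.  BED
exports are 0-based half-open; for SNP-delimited segments (whose start and
end are the first/last SNP positions of a window run) the shift is
bed_start = start - 1, bed_end = end - 1, which preserves the reported
size.  Machine-readable files keep full float precision; report tables
round to 4 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import Segment
from .genome import SnpPanel
from .snpcalls import SnpCallMatrix

__all__ = [
    "write_snp_calls",
    "read_snp_calls",
    "write_segments_bed",
    "read_segments_bed",
    "write_phenotypes",
    "read_phenotypes",
    "write_json",
    "read_fasta",
    "write_fasta",
]

_CALL_TO_STR = {2: "donor-hom", 1: "het", 0: "recipient-hom", -1: "missing"}
_STR_TO_CALL = {v: k for k, v in _CALL_TO_STR.items()}


def write_snp_calls(matrix: SnpCallMatrix, path: str | Path) -> None:
    """Long-format TSV: line_id, chrom, pos, call."""
    n_lines, n_snps = matrix.calls.shape
    df = pd.DataFrame(
        {
            "line_id": np.repeat(matrix.line_ids, n_snps),
            "chrom": np.tile(matrix.panel.chrom, n_lines),
            "pos": np.tile(matrix.panel.pos, n_lines),
            "call": [_CALL_TO_STR[int(c)] for c in matrix.calls.ravel()],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_snp_calls(path: str | Path, panel: SnpPanel) -> SnpCallMatrix:
    df = pd.read_csv(path, sep="\t")
    line_ids = list(dict.fromkeys(df["line_id"]))
    calls = (
        df["call"].map(_STR_TO_CALL).to_numpy(dtype=np.int8).reshape(len(line_ids), len(panel))
    )
    return SnpCallMatrix(line_ids=line_ids, panel=panel, calls=calls)


def write_segments_bed(segments: list[Segment], path: str | Path, shift: int = 1) -> None:
    """Segments as BED; ``shift`` converts 1-based starts/ends to 0-based."""
    with open(path, "w", newline="\n") as fh:
        for s in segments:
            state = "donor" if s.state == 2 else "het"
            fh.write(f"{s.chrom}\t{s.start - shift}\t{s.end - shift}\t{s.line_id}:{state}\n")


def read_segments_bed(path: str | Path, shift: int = 1) -> list[Segment]:
    out = []
    for line in Path(path).read_text().splitlines():
        chrom, start, end, name = line.split("\t")
        line_id, state = name.rsplit(":", 1)
        out.append(Segment(
            line_id=line_id, chrom=int(chrom),
            start=int(start) + shift, end=int(end) + shift,
            state=2 if state == "donor" else 1,
        ))
    return out


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=True, index_label="line_id",
                 lineterminator="\n", float_format="%.10g")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="line_id").rename_axis(index=None)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = []
        elif name is not None:
            seqs[name].append(line.strip())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
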