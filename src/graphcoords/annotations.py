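"""Readers/writers for gene annotation tables (BED12 and genePred).

All coordinates are 0-based half-open.  Records are kept deliberately
minimal: a transcript id, the source sequence it is annotated on (a
chromosome or an alt-locus name), its span and its exon blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

from .errors import ParseError


@dataclass(frozen=True)
class AnnotationRecord:
    """One transcript row: id, source sequence, span, absolute exon coords."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    exon_starts: tuple
    exon_ends: tuple
    strand: str = "+"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ParseError(f"{self.transcript_id}: bad span [{self.start}, {self.end})")
        if len(self.exon_starts) != len(self.exon_ends) or not self.exon_starts:
            raise ParseError(f"{self.transcript_id}: malformed exon lists")
        prev_end = None
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not self.start <= s < e <= self.end:
                raise ParseError(f"{self.transcript_id}: exon [{s}, {e}) outside span")
            if prev_end is not None and s < prev_end:
                raise ParseError(f"{self.transcript_id}: exons overlap or are unsorted")
            prev_end = e


def _iter_lines(source) -> Iterable[str]:
    if isinstance(source, str):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def read_bed12(source) -> List[AnnotationRecord]:
    """Read BED12 (or BED6+) rows; blockStarts are relative to chromStart."""
    out = []
    for ln, line in enumerate(_iter_lines(source), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 4:
            raise ParseError(f"BED line {ln}: expected >= 4 columns")
        chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
        strand = f[5] if len(f) > 5 else "+"
        if len(f) >= 12:
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            rel = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(rel) != int(f[9]):
                raise ParseError(f"BED line {ln}: blockCount disagrees with block lists")
            exon_starts = tuple(start + r for r in rel)
            exon_ends = tuple(start + r + s for r, s in zip(rel, sizes))
        else:
            exon_starts, exon_ends = (start,), (end,)
        out.append(AnnotationRecord(name, chrom, start, end, exon_starts, exon_ends, strand))
    return out


def write_bed12(records: Iterable[AnnotationRecord]) -> str:
    lines = []
    for r in records:
        sizes = ",".join(str(e - s) for s, e in zip(r.exon_starts, r.exon_ends))
        rel = ",".join(str(s - r.start) for s in r.exon_starts)
        lines.append(
            "\t".join(
                [
                    r.chrom,
                    str(r.start),
                    str(r.end),
                    r.transcript_id,
                    "0",
                    r.strand,
                    str(r.start),
                    str(r.end),
                    "0",
                    str(len(r.exon_starts)),
                    sizes + ",",
                    rel + ",",
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def read_genepred(source) -> List[AnnotationRecord]:
    """Read genePred-style TSV: name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds (absolute coords)."""
    out = []
    for ln, line in enumerate(_iter_lines(source), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 10:
            raise ParseError(f"genePred line {ln}: expected >= 10 columns")
        name, chrom, strand = f[0], f[1], f[2]
        tx_start, tx_end = int(f[3]), int(f[4])
        n = int(f[7])
        exon_starts = tuple(int(x) for x in f[8].rstrip(",").split(","))
        exon_ends = tuple(int(x) for x in f[9].rstrip(",").split(","))
        if len(exon_starts) != n or len(exon_ends) != n:
            raise ParseError(f"genePred line {ln}: exonCount disagrees with exon lists")
        out.append(AnnotationRecord(name, chrom, tx_start, tx_end, exon_starts, exon_ends, strand))
    return out
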