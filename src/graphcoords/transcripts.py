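"""Projecting transcript annotations onto graph coordinate systems,
categorizing alt-locus transcripts, and comparing transcripts as
multipath intervals.

Annotation rows are given in the linear coordinates of their source
sequence (a chromosome or an alt locus); projection maps them through the
graph's source maps into single-path intervals (one per exon).  On the
trimmed graph, an alt-locus transcript with a same-id main-path
counterpart is assigned one of five categories:

A. wholly on flank-derived shared blocks, with a counterpart whose
   projected span is identical;
B. wholly on the varying-region block(s), with a counterpart inside the
   parallel main segment;
C. partly on flanks and partly on the varying region, with a counterpart
   inside the parallel main segment;
D. wholly on shared blocks, with a counterpart elsewhere on the main
   path (disjoint from the placement);
E. wholly on shared blocks, with a counterpart extending outside the
   placement.

Rules are evaluated in order A..E; 'none' is the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .annotations import AnnotationRecord
from .assembly import AltLocusPlacement
from .coordinates import Position, RegionPathPartition
from .errors import CoordinateError, GraphCoordsError, ValidationError
from .intervals import SinglePathInterval, from_block_path
from .multipath import (
    CriticalSubpathsInterval,
    FuzzyPathInterval,
    MultipathInterval,
    multipath_equal,
)

CATEGORY_LABELS = ("A", "B", "C", "D", "E", "none")


@dataclass(frozen=True)
class Transcript:
    """A transcript projected onto a graph coordinate system."""

    transcript_id: str
    source_name: str
    source_start: int
    source_end: int
    exons: tuple  # of SinglePathInterval
    span: SinglePathInterval = field(compare=False)

    def exon_blocks(self) -> frozenset:
        out = set()
        for e in self.exons:
            out.update(e.block_path)
        return frozenset(out)


def project_linear(
    p: RegionPathPartition,
    source_name: str,
    start: int,
    end: int,
) -> SinglePathInterval:
    """Project a half-open linear range on a source sequence into a
    single-path interval, via the graph's source map."""
    segs = p.graph.source_maps.get(source_name)
    if segs is None:
        raise CoordinateError(f"no source map for {source_name!r}")
    total = segs[-1].end
    if not 0 <= start < end <= total:
        raise CoordinateError(
            f"range [{start}, {end}) outside {source_name!r} (length {total})"
        )
    block_path: List[str] = []
    start_pos = end_pos = None
    for seg in segs:
        if seg.end <= start or seg.start >= end:
            continue
        if not block_path or block_path[-1] != seg.block_id:
            block_path.append(seg.block_id)
        if seg.start <= start < seg.end:
            intra = seg.block_offset + (start - seg.start)
            start_pos = Position(
                p.rp_of_block(seg.block_id),
                p.block_start_in_rp(seg.block_id) + intra,
            )
        if seg.start < end <= seg.end:
            intra = seg.block_offset + (end - seg.start)
            end_pos = Position(
                p.rp_of_block(seg.block_id),
                p.block_start_in_rp(seg.block_id) + intra,
            )
    assert start_pos is not None and end_pos is not None
    return from_block_path(p, block_path, start_pos, end_pos)


def project_annotation(
    records: Sequence[AnnotationRecord],
    p: RegionPathPartition,
) -> Tuple[List[Transcript], List[Tuple[AnnotationRecord, str]]]:
    """Project annotation rows into transcripts.

    Returns ``(transcripts, errors)``: rows whose coordinates fall outside
    their source sequence (or that cannot be placed on a single path) are
    collected as ``(record, reason)`` pairs while the remaining records
    proceed.
    """
    transcripts: List[Transcript] = []
    errors: List[Tuple[AnnotationRecord, str]] = []
    for rec in records:
        try:
            exons = tuple(
                project_linear(p, rec.chrom, s, e)
                for s, e in zip(rec.exon_starts, rec.exon_ends)
            )
            span = project_linear(p, rec.chrom, rec.start, rec.end)
        except GraphCoordsError as exc:
            errors.append((rec, str(exc)))
            continue
        transcripts.append(
            Transcript(rec.transcript_id, rec.chrom, rec.start, rec.end, exons, span)
        )
    return transcripts, errors


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------


def _counterparts(alt_t: Transcript, main_ts: Sequence[Transcript]):
    return [t for t in main_ts if t.transcript_id == alt_t.transcript_id]


def _span_within(t: Transcript, placement: AltLocusPlacement) -> bool:
    return (
        t.source_name == placement.chrom
        and placement.chrom_start <= t.source_start
        and t.source_end <= placement.chrom_stop
    )


def _span_disjoint(t: Transcript, placement: AltLocusPlacement) -> bool:
    if t.source_name != placement.chrom:
        return True
    return t.source_end <= placement.chrom_start or t.source_start >= placement.chrom_stop


def _span_extends_outside(t: Transcript, placement: AltLocusPlacement) -> bool:
    if t.source_name != placement.chrom:
        return False
    overlaps = not _span_disjoint(t, placement)
    outside = t.source_start < placement.chrom_start or t.source_end > placement.chrom_stop
    return overlaps and outside


def categorize(
    alt_t: Transcript,
    main_ts: Sequence[Transcript],
    p: RegionPathPartition,
    placements: Mapping[str, AltLocusPlacement],
) -> str:
    """Category label (A..E or 'none') for one alt-locus transcript.

    ``placements`` maps alt-locus names to their placement records.
    Evaluated on a trimmed-mode graph, in rule order A, B, C, D, E.
    """
    placement = placements.get(alt_t.source_name)
    if placement is None:
        raise ValidationError(f"{alt_t.transcript_id}: source {alt_t.source_name!r} is not an alt locus")
    counterparts = _counterparts(alt_t, main_ts)
    if not counterparts:
        return "none"
    main_blocks = p.graph.main_path_blocks()
    blocks = alt_t.exon_blocks()
    on_shared = blocks <= main_blocks
    on_varying = not (blocks & main_blocks)

    if on_shared and any(c.span == alt_t.span for c in counterparts):
        return "A"
    if on_varying and any(_span_within(c, placement) for c in counterparts):
        return "B"
    if not on_shared and not on_varying and any(_span_within(c, placement) for c in counterparts):
        return "C"
    if on_shared and any(_span_disjoint(c, placement) for c in counterparts):
        return "D"
    if on_shared and any(_span_extends_outside(c, placement) for c in counterparts):
        return "E"
    return "none"


def categorize_all(
    alt_ts: Sequence[Transcript],
    main_ts: Sequence[Transcript],
    p: RegionPathPartition,
    placements: Mapping[str, AltLocusPlacement],
) -> Dict[str, int]:
    """Category count table over all alt-locus transcripts; counts always
    sum to ``len(alt_ts)`` and are invariant to input order."""
    counts = {label: 0 for label in CATEGORY_LABELS}
    for t in sorted(alt_ts, key=lambda t: (t.transcript_id, t.source_name, t.source_start)):
        counts[categorize(t, main_ts, p, placements)] += 1
    return counts


def split_by_source(
    transcripts: Sequence[Transcript],
    placements: Mapping[str, AltLocusPlacement],
) -> Tuple[List[Transcript], List[Transcript]]:
    """(alt-locus transcripts, main-path transcripts)."""
    alt = [t for t in transcripts if t.source_name in placements]
    main = [t for t in transcripts if t.source_name not in placements]
    return alt, main


def placements_by_alt(placements: Sequence[AltLocusPlacement]) -> Dict[str, AltLocusPlacement]:
    return {p.alt_name: p for p in placements}


# ---------------------------------------------------------------------------
# multipath representations
# ---------------------------------------------------------------------------


def to_multipath(
    t: Transcript,
    mode: str = "critical",
    fuzzy_threshold: Optional[int] = None,
    distance_mode: str = "global",
) -> MultipathInterval:
    """Represent a projected transcript as a multipath interval.

    ``critical`` mode uses the transcript's span endpoints with one
    critical subpath per exon (the exon's region-path list); ``fuzzy``
    mode uses the transcript's full single path as the central path.
    """
    if mode == "critical":
        subs = frozenset(e.region_path_ids for e in t.exons)
        return CriticalSubpathsInterval(t.span.start, t.span.end, subs, t.span.partition)
    if mode == "fuzzy":
        if fuzzy_threshold is None:
            raise ValidationError("fuzzy mode requires a threshold")
        return FuzzyPathInterval(t.span, fuzzy_threshold, distance_mode)
    raise ValidationError(f"unknown multipath mode {mode!r}")


def count_multipath_matches(
    alt_ts: Sequence[Transcript],
    main_ts: Sequence[Transcript],
    mode: str,
    p: RegionPathPartition,
    fuzzy_threshold: Optional[int] = None,
    distance_mode: str = "global",
    max_paths: int = 10000,
) -> int:
    """Number of alt-locus transcripts whose multipath representation
    equals that of some same-id main-path transcript (on a merged-mode
    graph)."""
    by_id: Dict[str, list] = {}
    for t in main_ts:
        by_id.setdefault(t.transcript_id, []).append(t)
    n = 0
    for alt_t in sorted(alt_ts, key=lambda t: (t.transcript_id, t.source_name, t.source_start)):
        ma = to_multipath(alt_t, mode, fuzzy_threshold, distance_mode)
        for cand in by_id.get(alt_t.transcript_id, []):
            mb = to_multipath(cand, mode, fuzzy_threshold, distance_mode)
            if multipath_equal(ma, mb, p, max_paths=max_paths):
                n += 1
                break
    return n
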