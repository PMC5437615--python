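"""Graph construction from assembly-style inputs, plus the synthetic
fixture generator.

Three builders are provided, in increasing level of detail:

* :func:`build_simple_graph` — each alt locus is a single block connected
  in parallel to the chromosome segment it is placed on.
* :func:`build_trimmed_graph` — the flanking regions of each alt locus
  (leading/trailing sequence identical to the main path) are removed, and
  only the varying region is connected to the main path.
* :func:`build_merged_graph` — alt-to-main alignment records are used to
  merge regions of common sequence onto shared blocks, interspersed with
  bubbles for SNPs, insertions and deletions.

:func:`generate_fixture` stands in for assembly downloads: it produces a
deterministic synthetic chromosome, alt loci with exact-match flanks and
planted variants, transcripts with known categories, and a ground-truth
record of everything planted.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .annotations import AnnotationRecord, write_bed12
from .errors import (
    AlignmentError,
    FixtureParamError,
    ParseError,
    PlacementError,
)
from .graph import Block, SequenceGraph, SourceSegment, build_graph

logger = logging.getLogger(__name__)

PLACEMENTS_HEADER = "#region_name\tchrom\tchrom_start\tchrom_stop\talt_name\talt_length"
ALIGNMENTS_HEADER = "#alt_name\talt_start\talt_stop\tchrom\tchrom_start\tchrom_stop\tidentity"


@dataclass(frozen=True)
class AltLocusPlacement:
    """Placement of one alt locus on a main chromosome path.

    ``chrom_start``/``chrom_stop`` are 0-based half-open coordinates of
    the parallel main-path segment; ``alt_length`` is the total length of
    the alt-locus sequence (flanks included).
    """

    region_name: str
    chrom: str
    chrom_start: int
    chrom_stop: int
    alt_name: str
    alt_length: int

    def __post_init__(self):
        if not 0 <= self.chrom_start < self.chrom_stop:
            raise PlacementError(
                f"{self.alt_name}: bad placement range [{self.chrom_start}, {self.chrom_stop})"
            )
        if self.alt_length < 1:
            raise PlacementError(f"{self.alt_name}: alt_length must be positive")


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned segment pairing alt-locus and main-path coordinates.

    ``identity`` is True for exact-match segments and False for variant
    segments (which may be empty on one side: insertions have zero main
    extent, deletions zero alt extent).
    """

    alt_name: str
    alt_start: int
    alt_stop: int
    chrom: str
    chrom_start: int
    chrom_stop: int
    identity: bool

    def __post_init__(self):
        if self.alt_start > self.alt_stop or self.chrom_start > self.chrom_stop:
            raise AlignmentError(f"{self.alt_name}: reversed segment coordinates")
        if self.identity and (self.alt_stop - self.alt_start) != (self.chrom_stop - self.chrom_start):
            raise AlignmentError(
                f"{self.alt_name}: identity segment has unequal alt/main lengths"
            )


# ---------------------------------------------------------------------------
# table IO
# ---------------------------------------------------------------------------


def _iter_lines(source):
    if isinstance(source, str):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def read_placements(source) -> List[AltLocusPlacement]:
    """Read an alt-locus placement table.

    Accepts the package's 6-column TSV (region_name, chrom, chrom_start,
    chrom_stop, alt_name, alt_length; '#' comments skipped) and, leniently,
    the NCBI ``alt_scaffold_placement.txt`` dialect (1-based inclusive
    parent coordinates, converted on input).
    """
    out = []
    for ln, line in enumerate(_iter_lines(source), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) == 6:
            out.append(
                AltLocusPlacement(f[0], f[1], int(f[2]), int(f[3]), f[4], int(f[5]))
            )
        elif len(f) >= 13:
            # NCBI alt_scaffold_placement.txt: alt_asm_name prim_asm_name
            # alt_scaf_name alt_scaf_acc parent_type parent_name parent_acc
            # region_name ori alt_scaf_start alt_scaf_stop parent_start
            # parent_stop [alt_start_tail alt_stop_tail]
            region, chrom = f[7], f[5]
            parent_start, parent_stop = int(f[11]) - 1, int(f[12])
            alt_stop = int(f[10])
            tail = int(f[14]) if len(f) > 14 and f[14].strip().isdigit() else 0
            out.append(
                AltLocusPlacement(region, chrom, parent_start, parent_stop, f[2], alt_stop + tail)
            )
        else:
            raise ParseError(f"placements line {ln}: expected 6 or >= 13 columns, got {len(f)}")
    return out


def write_placements(placements: Iterable[AltLocusPlacement]) -> str:
    lines = [PLACEMENTS_HEADER]
    for p in placements:
        lines.append(
            f"{p.region_name}\t{p.chrom}\t{p.chrom_start}\t{p.chrom_stop}\t{p.alt_name}\t{p.alt_length}"
        )
    return "\n".join(lines) + "\n"


def read_alignments(source) -> List[AlignmentRecord]:
    """Read the 7-column alignments TSV (identity flag as 0/1)."""
    out = []
    for ln, line in enumerate(_iter_lines(source), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 7:
            raise ParseError(f"alignments line {ln}: expected 7 columns, got {len(f)}")
        out.append(
            AlignmentRecord(
                f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5]), bool(int(f[6]))
            )
        )
    return out


def write_alignments(records: Iterable[AlignmentRecord]) -> str:
    lines = [ALIGNMENTS_HEADER]
    for r in records:
        lines.append(
            f"{r.alt_name}\t{r.alt_start}\t{r.alt_stop}\t{r.chrom}\t{r.chrom_start}"
            f"\t{r.chrom_stop}\t{int(r.identity)}"
        )
    return "\n".join(lines) + "\n"


def count_alt_scaffolds(source) -> int:
    """Count alt-scaffold records in an NCBI assembly report."""
    n = 0
    for line in _iter_lines(source):
        if line.startswith("#") or not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) > 1 and f[1].strip() == "alt-scaffold":
            n += 1
    return n


def read_fasta(source) -> Dict[str, str]:
    """Read sequences from FASTA into ``{name: sequence}``."""
    from Bio import SeqIO

    if isinstance(source, str):
        with open(source) as fh:
            return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 70):
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# flank detection
# ---------------------------------------------------------------------------


def detect_flanks(main_segment_seq: str, alt_seq: str) -> Tuple[int, int]:
    """Flank lengths of an alt locus against its parallel main segment.

    Left flank: longest common prefix.  Right flank: longest common suffix
    of the remainders after the prefix is removed (so ties are resolved
    prefix-first; for identical sequences of length L the result is
    ``(L, 0)``).  Always ``left + right <= min(len(main), len(alt))``.
    """
    if not main_segment_seq or not alt_seq:
        raise PlacementError("flank detection requires non-empty sequences")
    limit = min(len(main_segment_seq), len(alt_seq))
    left = 0
    while left < limit and main_segment_seq[left] == alt_seq[left]:
        left += 1
    rm, ra = main_segment_seq[left:], alt_seq[left:]
    right = 0
    limit2 = min(len(rm), len(ra))
    while right < limit2 and rm[-1 - right] == ra[-1 - right]:
        right += 1
    return left, right


# ---------------------------------------------------------------------------
# shared builder machinery
# ---------------------------------------------------------------------------


def _group_placements(placements: Sequence[AltLocusPlacement], chrom_lengths: Mapping[str, int]):
    """Group by chromosome, sort, and reject partial overlaps.

    Placements sharing the exact same region on one chromosome are allowed
    (several alt loci for the same region); partially overlapping ranges
    are unsupported and raise :class:`PlacementError`.
    """
    seen = set()
    by_chrom: Dict[str, list] = {}
    for p in placements:
        if p.chrom not in chrom_lengths:
            raise PlacementError(f"{p.alt_name}: unknown chromosome {p.chrom!r}")
        if p.chrom_stop > chrom_lengths[p.chrom]:
            raise PlacementError(
                f"{p.alt_name}: placement end {p.chrom_stop} beyond chromosome "
                f"length {chrom_lengths[p.chrom]}"
            )
        if p.alt_name in seen:
            raise PlacementError(f"duplicate alt name {p.alt_name!r}")
        seen.add(p.alt_name)
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: (p.chrom_start, p.chrom_stop, p.alt_name))
        for a, b in zip(plist, plist[1:]):
            same_region = (a.chrom_start, a.chrom_stop) == (b.chrom_start, b.chrom_stop)
            if not same_region and b.chrom_start < a.chrom_stop:
                raise PlacementError(
                    f"overlapping placements {a.alt_name!r} and {b.alt_name!r} on {chrom!r}"
                )
    return by_chrom


class _ChromSplitter:
    """Splits one chromosome at a set of cut points into main blocks."""

    def __init__(self, chrom: str, length: int, cuts: Iterable[int], seq: Optional[str]):
        points = sorted({0, length} | {c for c in cuts if 0 < c < length})
        self.chrom = chrom
        self.bounds = list(zip(points, points[1:]))
        single = len(self.bounds) == 1
        self.block_ids = []
        self.blocks = []
        self.starts = [lo for lo, _ in self.bounds]
        for i, (lo, hi) in enumerate(self.bounds):
            bid = chrom if single else f"{chrom}-{i}"
            self.block_ids.append(bid)
            self.blocks.append(
                Block(bid, hi - lo, seq[lo:hi] if seq is not None else None)
            )

    def block_ending_at(self, pos: int) -> Optional[str]:
        if pos == 0:
            return None
        for (lo, hi), bid in zip(self.bounds, self.block_ids):
            if hi == pos:
                return bid
        raise PlacementError(f"{self.chrom}: no block boundary at {pos}")

    def block_starting_at(self, pos: int) -> Optional[str]:
        if pos == self.bounds[-1][1]:
            return None
        for (lo, hi), bid in zip(self.bounds, self.block_ids):
            if lo == pos:
                return bid
        raise PlacementError(f"{self.chrom}: no block boundary at {pos}")

    def blocks_covering(self, lo: int, hi: int) -> List[Tuple[str, int, int]]:
        """(block id, range lo, range hi) triples covering [lo, hi)."""
        out = []
        for (a, b), bid in zip(self.bounds, self.block_ids):
            s, e = max(a, lo), min(b, hi)
            if s < e:
                out.append((bid, s, e))
        return out

    def source_map(self) -> List[SourceSegment]:
        return [
            SourceSegment(lo, hi, bid, 0)
            for (lo, hi), bid in zip(self.bounds, self.block_ids)
        ]

    def segments_for(self, lo: int, hi: int, src_offset: int) -> List[SourceSegment]:
        """Source segments mapping source coords starting at ``src_offset``
        onto the main blocks covering chromosome range [lo, hi)."""
        out = []
        pos = src_offset
        for bid, s, e in self.blocks_covering(lo, hi):
            block_lo = s - [a for (a, b), i in zip(self.bounds, self.block_ids) if i == bid][0]
            out.append(SourceSegment(pos, pos + (e - s), bid, block_lo))
            pos += e - s
        return out


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_simple_graph(
    placements: Sequence[AltLocusPlacement],
    chrom_lengths: Mapping[str, int],
    sequences: Optional[Mapping[str, str]] = None,
) -> SequenceGraph:
    """Connect each alt locus, as a single block, in parallel to the main
    chromosome segment it is placed on.

    Chromosomes are split at placement boundaries; an alt placed at the
    chromosome start (or end) simply becomes a source (or sink) block.
    """
    by_chrom = _group_placements(placements, chrom_lengths)
    blocks, edges, main_paths, source_maps = [], [], {}, {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        plist = by_chrom.get(chrom, [])
        seq = sequences.get(chrom) if sequences else None
        cuts = {c for p in plist for c in (p.chrom_start, p.chrom_stop)}
        splitter = _ChromSplitter(chrom, length, cuts, seq)
        blocks.extend(splitter.blocks)
        main_paths[chrom] = list(splitter.block_ids)
        edges.extend(zip(splitter.block_ids, splitter.block_ids[1:]))
        source_maps[chrom] = splitter.source_map()
        for p in plist:
            alt_seq = sequences.get(p.alt_name) if sequences else None
            if alt_seq is not None and len(alt_seq) != p.alt_length:
                raise PlacementError(
                    f"{p.alt_name}: sequence length {len(alt_seq)} != declared {p.alt_length}"
                )
            blocks.append(Block(p.alt_name, p.alt_length, alt_seq))
            pre = splitter.block_ending_at(p.chrom_start)
            post = splitter.block_starting_at(p.chrom_stop)
            if pre is not None:
                edges.append((pre, p.alt_name))
            if post is not None:
                edges.append((p.alt_name, post))
            source_maps[p.alt_name] = [SourceSegment(0, p.alt_length, p.alt_name, 0)]
    g = build_graph(blocks, dict.fromkeys(edges), main_paths, source_maps=source_maps)
    logger.info("simple graph: %d blocks, %d edges", len(g.blocks), len(g.edges))
    return g


@dataclass
class AltBuildInfo:
    """Per-alt bookkeeping recorded by the trimmed/merged builders."""

    placement: AltLocusPlacement
    left_flank: int = 0
    right_flank: int = 0
    alt_blocks: tuple = ()  # blocks private to the alt path

    def to_dict(self):
        return {
            "placement": asdict(self.placement),
            "left_flank": self.left_flank,
            "right_flank": self.right_flank,
            "alt_blocks": list(self.alt_blocks),
        }

    @classmethod
    def from_dict(cls, doc):
        return cls(
            AltLocusPlacement(**doc["placement"]),
            doc["left_flank"],
            doc["right_flank"],
            tuple(doc["alt_blocks"]),
        )


@dataclass
class GraphBuild:
    """A built graph plus per-alt metadata (mode: simple/trimmed/merged)."""

    graph: SequenceGraph
    mode: str
    alt_info: Dict[str, AltBuildInfo] = field(default_factory=dict)

    def meta_dict(self):
        return {
            "mode": self.mode,
            "alt_info": {k: v.to_dict() for k, v in sorted(self.alt_info.items())},
        }


def build_trimmed_graph(
    placements: Sequence[AltLocusPlacement],
    sequences: Mapping[str, str],
) -> GraphBuild:
    """Remove flanking regions from the alt loci and connect only their
    varying regions to the main path.

    Flank-equivalent bases live on shared main blocks; each alt
    contributes a single varying-region block (or none at all when the
    alt is identical to its main segment, which is logged).
    """
    chrom_lengths = {
        name: len(seq) for name, seq in sequences.items()
        if not any(p.alt_name == name for p in placements)
    }
    by_chrom = _group_placements(placements, chrom_lengths)
    flanks = {}
    for p in placements:
        if p.alt_name not in sequences:
            raise PlacementError(f"{p.alt_name}: no sequence provided")
        alt_seq = sequences[p.alt_name]
        if len(alt_seq) != p.alt_length:
            raise PlacementError(
                f"{p.alt_name}: sequence length {len(alt_seq)} != declared {p.alt_length}"
            )
        main_seg = sequences[p.chrom][p.chrom_start:p.chrom_stop]
        fl, fr = detect_flanks(main_seg, alt_seq)
        if fl + fr > p.alt_length:
            raise PlacementError(f"{p.alt_name}: flanks exceed alt sequence length")
        flanks[p.alt_name] = (fl, fr)

    blocks, edges, main_paths, source_maps = [], [], {}, {}
    alt_info = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        plist = by_chrom.get(chrom, [])
        seq = sequences[chrom]
        cuts = set()
        for p in plist:
            fl, fr = flanks[p.alt_name]
            cuts |= {p.chrom_start, p.chrom_start + fl, p.chrom_stop - fr, p.chrom_stop}
        splitter = _ChromSplitter(chrom, length, cuts, seq)
        blocks.extend(splitter.blocks)
        main_paths[chrom] = list(splitter.block_ids)
        edges.extend(zip(splitter.block_ids, splitter.block_ids[1:]))
        source_maps[chrom] = splitter.source_map()
        for p in plist:
            fl, fr = flanks[p.alt_name]
            alt_seq = sequences[p.alt_name]
            varying = alt_seq[fl:p.alt_length - fr]
            segs: List[SourceSegment] = []
            if fl:
                segs.extend(splitter.segments_for(p.chrom_start, p.chrom_start + fl, 0))
            info = AltBuildInfo(p, fl, fr)
            if varying:
                blocks.append(Block(p.alt_name, len(varying), varying))
                info.alt_blocks = (p.alt_name,)
                pre = splitter.block_ending_at(p.chrom_start + fl)
                post = splitter.block_starting_at(p.chrom_stop - fr)
                if pre is not None:
                    edges.append((pre, p.alt_name))
                if post is not None:
                    edges.append((p.alt_name, post))
                segs.append(SourceSegment(fl, fl + len(varying), p.alt_name, 0))
            else:
                logger.warning(
                    "%s: alt locus identical to its main segment; no varying block", p.alt_name
                )
            if fr:
                segs.extend(
                    splitter.segments_for(p.chrom_stop - fr, p.chrom_stop, p.alt_length - fr)
                )
            source_maps[p.alt_name] = segs
            alt_info[p.alt_name] = info
    g = build_graph(blocks, dict.fromkeys(edges), main_paths, source_maps=source_maps)
    logger.info("trimmed graph: %d blocks, %d edges", len(g.blocks), len(g.edges))
    return GraphBuild(g, "trimmed", alt_info)


def _check_alignment_tiling(p: AltLocusPlacement, records: List[AlignmentRecord]):
    records = sorted(records, key=lambda r: (r.alt_start, r.chrom_start))
    alt_pos, chrom_pos = 0, p.chrom_start
    for r in records:
        if r.alt_start != alt_pos or r.chrom_start != chrom_pos:
            raise AlignmentError(
                f"{p.alt_name}: alignment records do not tile the locus "
                f"(expected alt {alt_pos}/main {chrom_pos}, got {r.alt_start}/{r.chrom_start})"
            )
        alt_pos, chrom_pos = r.alt_stop, r.chrom_stop
    if alt_pos != p.alt_length or chrom_pos != p.chrom_stop:
        raise AlignmentError(
            f"{p.alt_name}: alignment records stop at alt {alt_pos}/main {chrom_pos}, "
            f"expected {p.alt_length}/{p.chrom_stop}"
        )
    return records


def build_merged_graph(
    placements: Sequence[AltLocusPlacement],
    sequences: Mapping[str, str],
    alignments: Sequence[AlignmentRecord],
) -> GraphBuild:
    """Merge alt loci onto the main path using alignment records.

    Identity segments become blocks shared by the main and alt paths;
    variant segments become parallel blocks (SNP: equal lengths; insertion:
    alt-only block; deletion: an edge skipping main blocks), producing a
    DAG of bubbles.
    """
    chrom_lengths = {
        name: len(seq) for name, seq in sequences.items()
        if not any(p.alt_name == name for p in placements)
    }
    by_chrom = _group_placements(placements, chrom_lengths)
    recs_by_alt: Dict[str, list] = {}
    for r in alignments:
        recs_by_alt.setdefault(r.alt_name, []).append(r)

    tiled = {}
    for p in placements:
        if p.alt_name not in sequences:
            raise PlacementError(f"{p.alt_name}: no sequence provided")
        if p.alt_name not in recs_by_alt:
            raise AlignmentError(f"{p.alt_name}: no alignment records")
        tiled[p.alt_name] = _check_alignment_tiling(p, recs_by_alt[p.alt_name])

    blocks, edges, main_paths, source_maps = [], [], {}, {}
    alt_info = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        plist = by_chrom.get(chrom, [])
        seq = sequences[chrom]
        cuts = set()
        for p in plist:
            for r in tiled[p.alt_name]:
                cuts |= {r.chrom_start, r.chrom_stop}
        splitter = _ChromSplitter(chrom, length, cuts, seq)
        blocks.extend(splitter.blocks)
        main_paths[chrom] = list(splitter.block_ids)
        edges.extend(zip(splitter.block_ids, splitter.block_ids[1:]))
        source_maps[chrom] = splitter.source_map()
        for p in plist:
            alt_seq = sequences[p.alt_name]
            if len(alt_seq) != p.alt_length:
                raise PlacementError(
                    f"{p.alt_name}: sequence length {len(alt_seq)} != declared {p.alt_length}"
                )
            alt_path: List[str] = []
            segs: List[SourceSegment] = []
            variant_blocks = []
            vidx = 0
            for r in tiled[p.alt_name]:
                if r.identity:
                    covered = splitter.blocks_covering(r.chrom_start, r.chrom_stop)
                    if seq[r.chrom_start:r.chrom_stop] != alt_seq[r.alt_start:r.alt_stop]:
                        raise AlignmentError(
                            f"{p.alt_name}: identity segment alt[{r.alt_start}:{r.alt_stop}] "
                            f"does not match the main sequence"
                        )
                    alt_path.extend(bid for bid, _, _ in covered)
                    segs.extend(splitter.segments_for(r.chrom_start, r.chrom_stop, r.alt_start))
                elif r.alt_stop > r.alt_start:
                    bid = f"{p.alt_name}-v{vidx}"
                    vidx += 1
                    blocks.append(
                        Block(bid, r.alt_stop - r.alt_start, alt_seq[r.alt_start:r.alt_stop])
                    )
                    variant_blocks.append(bid)
                    alt_path.append(bid)
                    segs.append(SourceSegment(r.alt_start, r.alt_stop, bid, 0))
                # deletion: no alt-side block, no segment; the skip edge
                # falls out of consecutive alt_path entries below
            pre = splitter.block_ending_at(p.chrom_start)
            post = splitter.block_starting_at(p.chrom_stop)
            full = ([pre] if pre else []) + alt_path + ([post] if post else [])
            edges.extend(zip(full, full[1:]))
            source_maps[p.alt_name] = segs
            alt_info[p.alt_name] = AltBuildInfo(p, 0, 0, tuple(variant_blocks))
    g = build_graph(blocks, dict.fromkeys(edges), main_paths, source_maps=source_maps)
    logger.info("merged graph: %d blocks, %d edges", len(g.blocks), len(g.edges))
    return GraphBuild(g, "merged", alt_info)


def alt_region_paths(build: GraphBuild) -> Dict[str, list]:
    """Explicit alt-path designation for the partition constructors."""
    out = {}
    for alt, info in sorted(build.alt_info.items()):
        for j, bid in enumerate(info.alt_blocks):
            name = alt if len(info.alt_blocks) == 1 else f"{alt}-v{j}"
            out[name] = [bid]
    return out


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

CATEGORY_LABELS = ("A", "B", "C", "D", "E", "none")


@dataclass
class FixtureParams:
    """Knobs for :func:`generate_fixture`.  All sizes in base pairs."""

    n_chroms: int = 1
    chrom_len: int = 900
    n_alts: int = 1
    flank_range: tuple = (14, 24)
    n_variants: int = 3
    variant_types: tuple = ("snp", "ins", "del")
    category_counts: dict = field(
        default_factory=lambda: {"A": 1, "B": 1, "C": 1, "D": 1, "E": 1, "none": 1}
    )
    n_mp_equal_pairs: int = 1
    n_mp_snp_pairs: int = 1
    n_extra_main: int = 1


@dataclass
class Fixture:
    """A complete synthetic dataset plus the ground truth planted in it."""

    params: FixtureParams
    seed: int
    sequences: Dict[str, str]
    chrom_lengths: Dict[str, int]
    placements: List[AltLocusPlacement]
    alignments: List[AlignmentRecord]
    transcripts: List[AnnotationRecord]
    ground_truth: dict

    def write(self, outdir: str):
        import os

        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.sequences, os.path.join(outdir, "sequences.fa"))
        with open(os.path.join(outdir, "placements.tsv"), "w") as fh:
            fh.write(write_placements(self.placements))
        with open(os.path.join(outdir, "alignments.tsv"), "w") as fh:
            fh.write(write_alignments(self.alignments))
        with open(os.path.join(outdir, "transcripts.bed"), "w") as fh:
            fh.write(write_bed12(self.transcripts))
        with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def build_simple(self) -> SequenceGraph:
        return build_simple_graph(self.placements, self.chrom_lengths, self.sequences)

    def build_trimmed(self) -> GraphBuild:
        return build_trimmed_graph(self.placements, self.sequences)

    def build_merged(self) -> GraphBuild:
        return build_merged_graph(self.placements, self.sequences, self.alignments)


_VAR_SLOT = 30  # spacing between planted variants inside the varying region


def _rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _other_base(rng, base):
    return rng.choice([b for b in "ACGT" if b != base])


def generate_fixture(params: Optional[FixtureParams] = None, seed: int = 0, **overrides) -> Fixture:
    """Generate a deterministic synthetic assembly with planted ground truth.

    The output records every planted flank length, variant, transcript
    category and multipath-pair expectation, so tests can compare recovered
    values against known truth.  Infeasible parameters raise
    :class:`FixtureParamError` before any output is produced.
    """
    if params is None:
        params = FixtureParams(**overrides)
    elif overrides:
        raise TypeError("pass either params or keyword overrides, not both")
    p = params
    if p.n_chroms < 1 or p.n_alts < 1:
        raise FixtureParamError("need at least one chromosome and one alt locus")
    if p.flank_range[0] < 12 or p.flank_range[0] > p.flank_range[1]:
        raise FixtureParamError("flank_range must satisfy 12 <= lo <= hi")
    for label in p.category_counts:
        if label not in CATEGORY_LABELS:
            raise FixtureParamError(f"unknown category label {label!r}")
    bad = set(p.variant_types) - {"snp", "ins", "del"}
    if bad:
        raise FixtureParamError(f"unknown variant types {sorted(bad)}")

    rng = random.Random(seed)
    chroms = [f"chr{i + 1}" for i in range(p.n_chroms)]
    alt_specs = []  # (alt_name, chrom, f_l, f_r, n_slots, forced snp plan)

    # distribute multipath pairs over alts; each pair needs its own
    # wide-gapped SNP slot
    mp_plan: Dict[int, list] = {i: [] for i in range(p.n_alts)}
    pair_idx = 0
    for kind, count in (("equal", p.n_mp_equal_pairs), ("snp", p.n_mp_snp_pairs)):
        for _ in range(count):
            mp_plan[pair_idx % p.n_alts].append(kind)
            pair_idx += 1

    n_d = p.category_counts.get("D", 0)
    margin = 40 + 16 * max(1, n_d)
    cursor = {c: 30 for c in chroms}
    for j in range(p.n_alts):
        chrom = chroms[j % p.n_chroms]
        f_l = rng.randint(*p.flank_range)
        f_r = rng.randint(*p.flank_range)
        n_slots = max(p.n_variants, len(mp_plan[j]))
        varying_main_len = 2 + 14 + n_slots * _VAR_SLOT + 20
        region_len = f_l + varying_main_len + f_r
        start = cursor[chrom]
        stop = start + region_len
        cursor[chrom] = stop + margin
        if cursor[chrom] + 30 > p.chrom_len:
            raise FixtureParamError(
                f"chrom_len={p.chrom_len} too small for {p.n_alts} alt loci "
                f"(need >= {cursor[chrom] + 30}); increase chrom_len"
            )
        alt_specs.append((f"alt{j + 1}", chrom, start, stop, f_l, f_r, n_slots, varying_main_len))

    sequences = {c: _rand_seq(rng, p.chrom_len) for c in chroms}
    chrom_lengths = {c: p.chrom_len for c in chroms}

    placements, alignments = [], []
    gt_flanks, gt_variants = {}, {}
    alt_layout = {}  # alt -> dict used for transcript planting
    for j, (alt, chrom, start, stop, f_l, f_r, n_slots, vlen) in enumerate(alt_specs):
        main_var = sequences[chrom][start + f_l:stop - f_r]
        # variant events: (rel main pos, type, main_len)
        events = [(0, "snp", 1)]
        n_forced = len(mp_plan[j])
        slot_pos = []
        for k in range(n_slots):
            pos = 14 + k * _VAR_SLOT + rng.randint(0, 4)
            slot_pos.append(pos)
            if k < n_forced:
                vtype = "snp"
            else:
                vtype = p.variant_types[k % len(p.variant_types)] if p.variant_types else "snp"
            main_len = 1 if vtype == "snp" else (rng.randint(2, 5) if vtype == "del" else 0)
            events.append((pos, vtype, main_len))
        events.append((vlen - 1, "snp", 1))

        alt_var_parts = []
        var_records = []  # relative (alt-rel, main-rel) variant coords
        gt_list = []
        cur = 0
        alt_cur = 0
        for pos, vtype, main_len in events:
            ident = main_var[cur:pos]
            if ident:
                var_records.append(("identity", cur, pos, alt_cur, alt_cur + len(ident)))
                alt_var_parts.append(ident)
                alt_cur += len(ident)
            if vtype == "snp":
                alt_base = _other_base(rng, main_var[pos])
                alt_var_parts.append(alt_base)
                var_records.append(("snp", pos, pos + 1, alt_cur, alt_cur + 1))
                gt_list.append({"type": "snp", "main_rel": pos, "alt_rel": alt_cur,
                                "main_len": 1, "alt_len": 1})
                alt_cur += 1
                cur = pos + 1
            elif vtype == "ins":
                ins_len = rng.randint(2, 5)
                ins = _rand_seq(rng, ins_len)
                alt_var_parts.append(ins)
                var_records.append(("ins", pos, pos, alt_cur, alt_cur + ins_len))
                gt_list.append({"type": "ins", "main_rel": pos, "alt_rel": alt_cur,
                                "main_len": 0, "alt_len": ins_len})
                alt_cur += ins_len
                cur = pos
            else:  # del
                var_records.append(("del", pos, pos + main_len, alt_cur, alt_cur))
                gt_list.append({"type": "del", "main_rel": pos, "alt_rel": alt_cur,
                                "main_len": main_len, "alt_len": 0})
                cur = pos + main_len
        tail = main_var[cur:]
        if tail:
            var_records.append(("identity", cur, vlen, alt_cur, alt_cur + len(tail)))
            alt_var_parts.append(tail)
            alt_cur += len(tail)
        alt_varying = "".join(alt_var_parts)

        alt_seq = (
            sequences[chrom][start:start + f_l]
            + alt_varying
            + sequences[chrom][stop - f_r:stop]
        )
        alt_len = len(alt_seq)
        sequences[alt] = alt_seq
        placements.append(
            AltLocusPlacement(f"REGION{j + 1}", chrom, start, stop, alt, alt_len)
        )
        v0 = start + f_l  # main coordinate of the varying-region start
        if f_l:
            alignments.append(AlignmentRecord(alt, 0, f_l, chrom, start, v0, True))
        for kind, m_lo, m_hi, a_lo, a_hi in var_records:
            alignments.append(
                AlignmentRecord(
                    alt, f_l + a_lo, f_l + a_hi, chrom, v0 + m_lo, v0 + m_hi,
                    kind == "identity",
                )
            )
        if f_r:
            alignments.append(
                AlignmentRecord(alt, alt_len - f_r, alt_len, chrom, stop - f_r, stop, True)
            )
        gt_flanks[alt] = [f_l, f_r]
        gt_variants[alt] = gt_list
        alt_layout[alt] = {
            "chrom": chrom, "start": start, "stop": stop, "f_l": f_l, "f_r": f_r,
            "alt_len": alt_len, "alt_varying_len": len(alt_varying),
            "snp_slots": slot_pos[:n_forced], "mp_kinds": mp_plan[j],
        }

    # ---- transcripts -------------------------------------------------
    transcripts: List[AnnotationRecord] = []
    gt_categories: Dict[str, str] = {}
    tx_counter = [0]

    def next_id():
        tx_counter[0] += 1
        return f"TX{tx_counter[0]:03d}"

    def add(label, tid, alt, alt_span, alt_exons, main_span=None, main_exons=None, chrom=None):
        transcripts.append(
            AnnotationRecord(tid, alt, alt_span[0], alt_span[1],
                             tuple(s for s, _ in alt_exons), tuple(e for _, e in alt_exons))
        )
        if main_span is not None:
            transcripts.append(
                AnnotationRecord(tid, chrom, main_span[0], main_span[1],
                                 tuple(s for s, _ in main_exons), tuple(e for _, e in main_exons))
            )
        gt_categories[tid] = label

    alt_names = [spec[0] for spec in alt_specs]
    d_slot = {a: 0 for a in alt_names}
    item = 0
    for label in CATEGORY_LABELS:
        for _ in range(p.category_counts.get(label, 0)):
            alt = alt_names[item % len(alt_names)]
            item += 1
            lay = alt_layout[alt]
            chrom, start, stop = lay["chrom"], lay["start"], lay["stop"]
            f_l, f_r, alt_len = lay["f_l"], lay["f_r"], lay["alt_len"]
            valen = lay["alt_varying_len"]
            tid = next_id()
            if label == "A":
                lo, hi = 3, f_l - 3
                exons = [(lo, lo + 4), (hi - 4, hi)]
                add("A", tid, alt, (lo, hi), exons,
                    (start + lo, start + hi),
                    [(start + s, start + e) for s, e in exons], chrom)
            elif label == "B":
                lo, hi = f_l + 3, f_l + valen - 3
                add("B", tid, alt, (lo, hi), [(lo, hi)],
                    (start + f_l + 3, stop - f_r - 3),
                    [(start + f_l + 3, stop - f_r - 3)], chrom)
            elif label == "C":
                lo, hi = f_l - 6, f_l + 7
                add("C", tid, alt, (lo, hi), [(lo, hi)],
                    (start + lo, start + hi),
                    [(start + lo, start + hi)], chrom)
            elif label == "D":
                lo, hi = alt_len - f_r + 2, alt_len - 2
                w = min(hi - lo, 12)
                m_lo = stop + 5 + 16 * d_slot[alt]
                d_slot[alt] += 1
                add("D", tid, alt, (lo, hi), [(lo, hi)],
                    (m_lo, m_lo + w), [(m_lo, m_lo + w)], chrom)
            elif label == "E":
                lo, hi = 1, f_l - 1
                add("E", tid, alt, (lo, hi), [(lo, hi)],
                    (start - 8, start + hi),
                    [(start - 8, start + hi)], chrom)
            else:  # none: no main counterpart
                add("none", tid, alt, (2, 6), [(2, 6)])

    # multipath pairs (exons land in identity segments around forced SNPs)
    mp_pairs = {"critical_equal": [], "fuzzy_equal_t2": []}
    for alt in alt_names:
        lay = alt_layout[alt]
        f_l, start = lay["f_l"], lay["start"]
        v0 = start + f_l
        for kind, q in zip(lay["mp_kinds"], lay["snp_slots"]):
            tid = next_id()
            a = f_l + q  # alt coordinate of the SNP (no indels precede it)
            m = v0 + q
            if kind == "equal":
                exons = [(a - 10, a - 2), (a + 2, a + 10)]
                m_exons = [(m - 10, m - 2), (m + 2, m + 10)]
                span, m_span = (a - 10, a + 10), (m - 10, m + 10)
                mp_pairs["critical_equal"].append(tid)
                mp_pairs["fuzzy_equal_t2"].append(tid)
            else:  # snp inside the single exon
                exons = [(a - 8, a + 8)]
                m_exons = [(m - 8, m + 8)]
                span, m_span = (a - 8, a + 8), (m - 8, m + 8)
                mp_pairs["fuzzy_equal_t2"].append(tid)
            add("B", tid, alt, span, exons, m_span, m_exons, lay["chrom"])

    for _ in range(p.n_extra_main):
        tid = f"MAIN{tx_counter[0]:03d}"
        tx_counter[0] += 1
        chrom = chroms[tx_counter[0] % len(chroms)]
        transcripts.append(AnnotationRecord(tid, chrom, 2, 12, (2,), (12,)))

    gt_counts = {label: 0 for label in CATEGORY_LABELS}
    for label in gt_categories.values():
        gt_counts[label] += 1
    # On the merged graph, planted A pairs project identically (so they
    # match under both multipath modes), and planted C pairs span exactly
    # one SNP bubble (so they match fuzzily at threshold 2 but not
    # critically, the bubble being exonic).
    ground_truth = {
        "flanks": gt_flanks,
        "variants": gt_variants,
        "categories": gt_categories,
        "category_counts": gt_counts,
        "multipath": {
            "critical_matches": gt_counts["A"] + len(mp_pairs["critical_equal"]),
            "fuzzy_matches_t2": (
                gt_counts["A"] + gt_counts["C"] + len(mp_pairs["fuzzy_equal_t2"])
            ),
            "pairs": mp_pairs,
        },
        "layout": alt_layout,
    }
    return Fixture(
        p, seed, sequences, chrom_lengths, placements, alignments, transcripts, ground_truth
    )
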