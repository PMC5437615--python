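"""Single-path intervals on offset-based graph coordinate systems.

An interval is a single directed path between two coordinates.  Start and
end coordinates alone are ambiguous on a graph, so the representation also
stores the ordered list of region paths the interval traverses — the
*full* form lists the region-path identifier every time it changes, while
the *minimal* text form only lists it where the traversal is ambiguous.

End offsets are exclusive.  An end position ``F:0`` is legal: block ``F``
terminates the region-path list while contributing zero bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .coordinates import Position, RegionPathPartition, parse_offset
from .errors import (
    AmbiguousPathError,
    CoordinateError,
    NoPathError,
    ParseError,
    ValidationError,
)
from .graph import path_sequence

MINIMAL = "minimal"
FULL = "full"


def _collapse(seq):
    """Collapse consecutive duplicates: [a,a,b,a] -> [a,b,a]."""
    out = []
    for x in seq:
        if not out or out[-1] != x:
            out.append(x)
    return out


@dataclass(frozen=True)
class SinglePathInterval:
    """An unambiguous interval: endpoints plus the region paths traversed.

    ``region_path_ids`` is always stored in full form (one entry per
    identifier change, so re-entered region paths appear repeatedly).
    ``block_path`` is the induced block-level path, including the end
    block even when it contributes zero bases.
    """

    start: Position
    end: Position
    region_path_ids: tuple
    block_path: tuple
    partition: RegionPathPartition = field(compare=False, repr=False)

    def __post_init__(self):
        if self.region_path_ids[0] != self.start.region_path_id:
            raise ValidationError("region_path_ids must begin with the start region path")
        if self.region_path_ids[-1] != self.end.region_path_id:
            raise ValidationError("region_path_ids must end with the end region path")

    # -- derived quantities -------------------------------------------

    @property
    def graph(self):
        return self.partition.graph

    def start_intra(self) -> int:
        """Offset of the start within the first block."""
        return self.partition.locate(self.start)[1] if self._nonempty_start() else 0

    def _nonempty_start(self):
        return self.start.offset < self.partition.rp_length(self.start.region_path_id)

    def endpoint_offsets(self) -> tuple:
        """(intra offset of start in first block, boundary offset of end in
        last block)."""
        sb, so = self.partition.locate_boundary(self.start)
        eb, eo = self.partition.locate_boundary(self.end)
        if sb != self.block_path[0]:
            # start at a block seam resolves left; the path's first block is
            # the right-hand one, so the intra offset is 0
            so = 0
        if eb != self.block_path[-1]:
            eo = 0
        return so, eo

    def length(self) -> int:
        """Number of bases covered (half-open)."""
        so, eo = self.endpoint_offsets()
        total = sum(self.graph.block_length(b) for b in self.block_path)
        last_len = self.graph.block_length(self.block_path[-1])
        if len(self.block_path) == 1:
            return eo - so
        return total - so - (last_len - eo)

    def sequence(self) -> str:
        """Spell the interval's DNA (requires sequences on every block)."""
        so, eo = self.endpoint_offsets()
        return path_sequence(self.graph, list(self.block_path), so, eo)

    def bases(self) -> frozenset:
        """The set of (block, intra-offset) bases covered."""
        so, eo = self.endpoint_offsets()
        out = []
        for i, b in enumerate(self.block_path):
            lo = so if i == 0 else 0
            hi = eo if i == len(self.block_path) - 1 else self.graph.block_length(b)
            out.extend((b, off) for off in range(lo, hi))
        return frozenset(out)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def _start_blocks(p: RegionPathPartition, start: Position):
    """Candidate start blocks.  A start on a mid-path block seam may mean
    'first base of the right block' or 'zero bases of the left block, then
    an immediate transition' (as in an interval that leaves the main path
    exactly at its start coordinate)."""
    if start.offset >= p.rp_length(start.region_path_id):
        return [p.locate_boundary(start)[0]]
    b, o = p.locate(start)
    out = {b}
    if o == 0 and start.offset > 0:
        out.add(p.locate_boundary(start)[0])
    return sorted(out)


def _end_blocks(p: RegionPathPartition, end: Position):
    """Candidate end blocks.  An end falling on a mid-path block seam is
    ambiguous between 'end of the left block' and 'zero bases of the right
    block'; both readings denote the same bases and print identically, so
    both are tried and the results canonicalized."""
    eb, _ = p.locate_boundary(end)
    out = {eb}
    if end.offset < p.rp_length(end.region_path_id):
        b2, o2 = p.locate(end)
        if o2 == 0:
            out.add(b2)
    return sorted(out)


def from_block_path(
    p: RegionPathPartition,
    block_path: Sequence[str],
    start: Position,
    end: Position,
) -> SinglePathInterval:
    """Assemble an interval directly from a known block path.

    A trailing block to which the end contributes zero bases is dropped
    when it lies in the same region path as its predecessor: its presence
    is invisible in both the covered bases and the printed notation (an
    end like ``F:0`` in a *different* region path is kept, as F still
    terminates the region-path list).
    """
    block_path = list(block_path)
    for a, b in zip(block_path, block_path[1:]):
        if not p.graph.has_edge(a, b):
            raise NoPathError(f"{a!r} -> {b!r} is not an edge")
    while (
        len(block_path) > 1
        and end.region_path_id == p.rp_of_block(block_path[-1])
        and end.offset == p.block_start_in_rp(block_path[-1])
        and p.rp_of_block(block_path[-2]) == p.rp_of_block(block_path[-1])
    ):
        block_path.pop()
    while (
        len(block_path) > 1
        and start.region_path_id == p.rp_of_block(block_path[0])
        and start.offset
        == p.block_start_in_rp(block_path[0]) + p.graph.block_length(block_path[0])
        and p.rp_of_block(block_path[1]) == p.rp_of_block(block_path[0])
    ):
        block_path.pop(0)
    rps = tuple(_collapse(p.rp_of_block(b) for b in block_path))
    return SinglePathInterval(start, end, rps, tuple(block_path), p)


def make_interval(
    start: Position,
    end: Position,
    via: Sequence[str],
    p: RegionPathPartition,
    max_paths: int = 10000,
) -> SinglePathInterval:
    """Build an interval from endpoints and a (possibly minimal) region-path
    hint list.

    ``via`` holds the inner region-path identifiers, either the complete
    full-form list or any subsequence of it (minimal form).  A unique block
    path must be consistent with ``(start, via, end)``; otherwise a
    :class:`NoPathError` or an :class:`AmbiguousPathError` listing the
    candidates is raised.  Input given in full form wins over minimal
    readings of the same text.
    """
    from .graph import enumerate_paths

    via = list(via)
    if start == end and not via:
        # zero-length interval: canonically anchored to the block holding
        # the base at this offset (or the path's last block at the very end)
        if start.offset < p.rp_length(start.region_path_id):
            block = p.locate(start)[0]
        else:
            block = p.locate_boundary(start)[0]
        return from_block_path(p, [block], start, end)
    seen = set()
    candidates = []
    for sb in _start_blocks(p, start):
      for eb in _end_blocks(p, end):
        for path in enumerate_paths(p.graph, sb, eb, max_paths=max_paths):
            try:
                ival = from_block_path(p, path, start, end)
            except ValidationError:
                continue  # collapsed path inconsistent with the endpoints
            if ival.block_path in seen:
                continue
            seen.add(ival.block_path)
            inner = list(ival.region_path_ids[1:-1])
            candidates.append((list(ival.block_path), inner))

    def is_subsequence(small, big):
        it = iter(big)
        return all(x in it for x in small)

    # a candidate is consistent with `via` iff its ambiguous branch choices
    # (its own minimal form) are all spelled out in `via`, and `via` only
    # names region paths the candidate actually visits:
    # minimal(candidate) <= via <= full(candidate), as subsequences
    exact = [(path, inner) for path, inner in candidates if list(inner) == via]
    loose = [(path, inner) for path, inner in candidates if is_subsequence(via, inner)]
    matching = exact or [
        (path, inner)
        for path, inner in loose
        if is_subsequence(_minimal_inner(from_block_path(p, path, start, end)), via)
    ]
    if not matching and not loose:
        raise NoPathError(f"no path from {start} to {end} via {via!r}")
    if len(matching) != 1:
        # either several candidates survive, or several loose candidates
        # exist but none has all its branch choices spelled out in `via`
        reprs = sorted(
            "(" + " ".join([str(start)] + list(inner) + [str(end)]) + ")"
            for _, inner in (matching or loose)
        )
        raise AmbiguousPathError(
            f"via list {via!r} underdetermines the path from {start} to {end}; "
            f"candidates: {', '.join(reprs)}",
            candidates=reprs,
        )
    path, _ = matching[0]
    return from_block_path(p, path, start, end)


# ---------------------------------------------------------------------------
# formatting / parsing
# ---------------------------------------------------------------------------


def _runs(interval: SinglePathInterval):
    """Split the block path into (region path, [blocks]) runs."""
    p = interval.partition
    runs = []
    for b in interval.block_path:
        rp = p.rp_of_block(b)
        if runs and runs[-1][0] == rp:
            runs[-1][1].append(b)
        else:
            runs.append((rp, [b]))
    return runs


def _minimal_inner(interval: SinglePathInterval):
    """Inner identifiers kept by the minimal style: a region path is listed
    iff, at the junction where the interval leaves the previous region
    path, more than one successor region path can reach the rest of the
    interval."""
    g = interval.graph
    p = interval.partition
    runs = _runs(interval)
    end_block = interval.block_path[-1]
    kept = []
    for i in range(1, len(runs) - 1):
        exit_block = runs[i - 1][1][-1]
        choices = set()
        for nb in g.successors(exit_block):
            if g.is_reachable(nb, end_block):
                choices.add(p.rp_of_block(nb))
        if len(choices) > 1:
            kept.append(runs[i][0])
    return kept


def format_interval(interval: SinglePathInterval, style: str = FULL) -> str:
    """Render an interval as text: ``(start:off inner... end:off)``.

    ``full`` lists every identifier change; ``minimal`` omits inner region
    paths whose traversal is unambiguous given the graph.
    """
    if style == FULL:
        inner = list(interval.region_path_ids[1:-1])
    elif style == MINIMAL:
        inner = _minimal_inner(interval)
    else:
        raise ValueError(f"unknown style {style!r}")
    toks = [str(interval.start)] + inner + [str(interval.end)]
    return "(" + " ".join(toks) + ")"


_TOKEN_SPLIT = re.compile(r"[\s,]+")


def parse_interval(text: str, p: RegionPathPartition, max_paths: int = 10000) -> SinglePathInterval:
    """Parse interval text in either style.

    Accepts both the space and the comma dialect; offsets may carry SI
    suffixes (``chr14:150m``).  Minimal-form input is expanded to full form
    during construction; genuinely ambiguous input raises
    :class:`AmbiguousPathError`.
    """
    s = text.strip()
    if s.startswith("(") and s.endswith(")"):
        s = s[1:-1]
    toks = [t for t in _TOKEN_SPLIT.split(s.strip()) if t]
    if len(toks) < 2:
        raise ParseError(f"interval text needs start and end coordinates: {text!r}")
    for t in (toks[0], toks[-1]):
        if ":" not in t:
            raise ParseError(f"endpoint token {t!r} lacks an offset (expected name:offset)")

    def parse_pos(tok):
        name, _, off = tok.rpartition(":")
        if not name:
            raise ParseError(f"cannot parse coordinate {tok!r}")
        return Position(name, parse_offset(off))

    start = parse_pos(toks[0])
    end = parse_pos(toks[-1])
    via = toks[1:-1]
    for name in [start.region_path_id, end.region_path_id] + via:
        if name not in p.region_paths:
            raise ParseError(f"unknown region path {name!r} in {text!r}")
    return make_interval(start, end, via, p, max_paths=max_paths)


def interval_length(interval: SinglePathInterval) -> int:
    return interval.length()


def translate_interval(
    interval: SinglePathInterval,
    from_partition: RegionPathPartition,
    to_partition: RegionPathPartition,
) -> SinglePathInterval:
    """Re-express an interval in another partition over the same graph:
    same block path and base span, endpoints translated."""
    if from_partition is not interval.partition:
        raise CoordinateError("interval does not belong to the given source partition")
    if from_partition.graph is not to_partition.graph and not from_partition.graph.same_blocks(
        to_partition.graph
    ):
        raise CoordinateError("partitions are not over the same underlying graph")
    # endpoints stay anchored to the same first/last block of the block path,
    # so that an end like F:0 keeps terminating the region-path list
    so, eo = interval.endpoint_offsets()
    sb, eb = interval.block_path[0], interval.block_path[-1]
    start = Position(
        to_partition.rp_of_block(sb), to_partition.block_start_in_rp(sb) + so
    )
    end = Position(
        to_partition.rp_of_block(eb), to_partition.block_start_in_rp(eb) + eo
    )
    return from_block_path(to_partition, interval.block_path, start, end)


def to_bed(interval: SinglePathInterval) -> str:
    """BED line for an interval lying within one region path.

    Multi-region-path intervals cannot be expressed in linear BED and
    raise :class:`ValidationError`.
    """
    if len(set(interval.region_path_ids)) != 1:
        raise ValidationError(
            "interval spans multiple region paths and cannot be expressed in linear BED"
        )
    return f"{interval.start.region_path_id}\t{interval.start.offset}\t{interval.end.offset}"
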