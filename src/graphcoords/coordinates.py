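"""Offset-based coordinate systems on sequence graphs.

A coordinate system is obtained by partitioning the graph into
non-overlapping *region paths*; a coordinate is then a
``(region path id, offset)`` pair with the offset counted from the start
of the region path.

Two partitionings are provided:

* *hierarchical* — one region path per chromosome main path, one per
  alternative locus (recursively for alternatives of alternatives).
  Stable under updates: adding a new alternative path never changes
  existing coordinates.
* *sequential* — main paths are additionally divided wherever an
  alternative path starts or stops, so that parallel sequence gets
  similar coordinates.  Updates break old coordinates, so each update
  returns an :class:`UpdateMapping` that rebases them.

Offsets are 0-based and intervals are half-open throughout.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

from .errors import (
    CoordinateError,
    NameCollisionError,
    ParseError,
    PartitionError,
    ValidationError,
)
from .graph import Block, SequenceGraph, SourceSegment, build_graph

HIERARCHICAL = "hierarchical"
SEQUENTIAL = "sequential"

_SI = {"": 1, "k": 10**3, "m": 10**6, "g": 10**9}
_POS_RE = re.compile(r"^(?P<name>.+):(?P<num>\d+)(?P<si>[kmgKMG]?)$")


@dataclass(frozen=True)
class Position:
    """An offset-based coordinate: region path id + 0-based offset."""

    region_path_id: str
    offset: int

    def __post_init__(self):
        if self.offset < 0:
            raise CoordinateError(f"negative offset in {self.region_path_id}:{self.offset}")

    def __str__(self):
        return f"{self.region_path_id}:{self.offset}"


def parse_offset(text: str) -> int:
    """Parse an offset with an optional SI-style suffix (``150m``, ``2k``)."""
    m = re.match(r"^(\d+)([kmgKMG]?)$", text)
    if not m:
        raise ParseError(f"cannot parse offset {text!r}")
    return int(m.group(1)) * _SI[m.group(2).lower()]


def parse_position(text: str) -> Position:
    """Parse ``name:offset`` text (offset may carry an SI suffix)."""
    m = _POS_RE.match(text.strip())
    if not m:
        raise ParseError(f"cannot parse position {text!r}")
    return Position(m.group("name"), parse_offset(m.group("num") + m.group("si")))


class RegionPathPartition:
    """A partition of a graph's blocks into named linear region paths.

    Every block belongs to exactly one region path, and each region
    path's block list is a directed path in the graph.
    """

    def __init__(self, kind: str, region_paths: Mapping[str, Sequence[str]], graph: SequenceGraph):
        if kind not in (HIERARCHICAL, SEQUENTIAL):
            raise PartitionError(f"unknown partition kind {kind!r}")
        self.kind = kind
        self.graph = graph
        self.region_paths: dict = {name: list(path) for name, path in region_paths.items()}
        self._validate()
        self._index()

    @classmethod
    def from_region_paths(cls, graph, region_paths, kind=HIERARCHICAL):
        """Build a partition from an explicit ``{name: [block ids]}`` map."""
        return cls(kind, region_paths, graph)

    def _validate(self):
        seen: dict = {}
        for name, path in self.region_paths.items():
            if not path:
                raise PartitionError(f"region path {name!r} is empty")
            for b in path:
                if b not in self.graph.blocks:
                    raise PartitionError(f"region path {name!r} references unknown block {b!r}")
                if b in seen:
                    raise PartitionError(
                        f"block {b!r} appears in region paths {seen[b]!r} and {name!r}"
                    )
                seen[b] = name
            for a, b in zip(path, path[1:]):
                if not self.graph.has_edge(a, b):
                    raise PartitionError(f"region path {name!r}: {a!r} -> {b!r} is not an edge")
        missing = set(self.graph.blocks) - set(seen)
        if missing:
            raise PartitionError(f"blocks not covered by any region path: {sorted(missing)}")

    def _index(self):
        self._block_rp: dict = {}
        self._block_start: dict = {}
        self._rp_len: dict = {}
        self._rp_starts: dict = {}
        for name, path in self.region_paths.items():
            pos = 0
            starts = []
            for b in path:
                self._block_rp[b] = name
                self._block_start[b] = pos
                starts.append(pos)
                pos += self.graph.block_length(b)
            self._rp_len[name] = pos
            self._rp_starts[name] = starts

    # -- lookups -------------------------------------------------------

    def rp_length(self, rp_id: str) -> int:
        try:
            return self._rp_len[rp_id]
        except KeyError:
            raise CoordinateError(f"unknown region path {rp_id!r}") from None

    def rp_of_block(self, block_id: str) -> str:
        return self._block_rp[block_id]

    def block_start_in_rp(self, block_id: str) -> int:
        return self._block_start[block_id]

    def locate(self, pos: Position) -> tuple:
        """Resolve a base position to ``(block id, intra-block offset)``."""
        total = self.rp_length(pos.region_path_id)
        if not 0 <= pos.offset < total:
            raise CoordinateError(
                f"offset {pos.offset} out of range for region path "
                f"{pos.region_path_id!r} (length {total})"
            )
        path = self.region_paths[pos.region_path_id]
        starts = self._rp_starts[pos.region_path_id]
        i = bisect.bisect_right(starts, pos.offset) - 1
        return path[i], pos.offset - starts[i]

    def locate_boundary(self, pos: Position) -> tuple:
        """Resolve a boundary (interval endpoint) to ``(block id, offset)``.

        ``offset`` may equal the region-path length; a boundary falling on a
        block seam resolves to the *end* of the left block, except offset 0
        which resolves to the start of the first block.
        """
        total = self.rp_length(pos.region_path_id)
        if not 0 <= pos.offset <= total:
            raise CoordinateError(
                f"offset {pos.offset} out of range for region path "
                f"{pos.region_path_id!r} (length {total})"
            )
        path = self.region_paths[pos.region_path_id]
        starts = self._rp_starts[pos.region_path_id]
        if pos.offset == 0:
            return path[0], 0
        i = bisect.bisect_left(starts, pos.offset) - 1
        if i < 0:
            i = 0
        return path[i], pos.offset - starts[i]

    def position_of(self, block_id: str, intra_offset: int = 0) -> Position:
        """The Position addressing base ``intra_offset`` of ``block_id``."""
        rp = self._block_rp[block_id]
        return Position(rp, self._block_start[block_id] + intra_offset)

    def base_key(self, pos: Position) -> tuple:
        """Update-stable identity of the base addressed by ``pos``."""
        block, off = self.locate(pos)
        return self.graph.blocks[block].base_key(off)

    def all_base_positions(self) -> Iterable[Position]:
        """Every valid base position, in deterministic order."""
        for name in sorted(self.region_paths):
            for off in range(self._rp_len[name]):
                yield Position(name, off)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "region_paths": {k: list(v) for k, v in sorted(self.region_paths.items())},
        }

    @classmethod
    def from_dict(cls, doc, graph):
        return cls(doc["kind"], doc["region_paths"], graph)


# ---------------------------------------------------------------------------
# partition construction
# ---------------------------------------------------------------------------


def _chain_decomposition(g: SequenceGraph, free: set):
    """Decompose ``free`` blocks into maximal unbranched directed chains.

    Only edges with both endpoints in ``free`` are considered.  Returned
    in deterministic order (sorted by head block id).
    """
    def free_succ(b):
        return [s for s in g.successors(b) if s in free]

    def free_pred(b):
        return [p for p in g.predecessors(b) if p in free]

    heads = []
    for b in sorted(free):
        preds = free_pred(b)
        if len(preds) != 1 or len(free_succ(preds[0])) != 1:
            heads.append(b)
    chains = []
    used = set()
    for head in heads:
        chain = [head]
        used.add(head)
        cur = head
        while True:
            succs = free_succ(cur)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if len(free_pred(nxt)) != 1 or nxt in used:
                break
            chain.append(nxt)
            used.add(nxt)
            cur = nxt
        chains.append(chain)
    leftover = free - used
    if leftover:  # pragma: no cover - defensive; heads cover all cases
        for b in sorted(leftover):
            chains.append([b])
    return chains


def _anchor_of_chain(g, chain, block_rp):
    """Pick the region path a chain attaches to, plus its attachment order key.

    Prefers an upstream (predecessor) anchor; falls back to a downstream
    one for chains that are sources.  Returns ``(rp_id, order_key)`` or
    ``(None, ...)`` for fully isolated chains.
    """
    preds = sorted(p for p in g.predecessors(chain[0]) if p in block_rp)
    if preds:
        p = preds[0]
        return block_rp[p], (0, p)
    succs = sorted(s for s in g.successors(chain[-1]) if s in block_rp)
    if succs:
        s = succs[0]
        return block_rp[s], (1, s)
    return None, (2, chain[0])


def hierarchical_partition(
    g: SequenceGraph,
    alt_paths: Optional[Mapping[str, Sequence[str]]] = None,
) -> RegionPathPartition:
    """One region path per chromosome main path; each alternative locus is
    its own region path, recursively for deeper layers.

    Parameters
    ----------
    alt_paths:
        Optional explicit designation ``{name: [block ids]}`` of alternative
        region paths, processed in order.  This is how the main region path
        of a deeper layer (an alternative with its own alternatives) is
        designated.  Any blocks still uncovered afterwards are decomposed
        into maximal unbranched chains and named ``<anchor>-alt<j>`` with
        ``j`` increasing along the anchor region path.
    """
    region_paths: dict = {}
    covered: set = set()
    for name, path in g.main_paths.items():
        region_paths[name] = list(path)
        for b in path:
            if b in covered:
                raise PartitionError(f"block {b!r} appears on two main paths")
            covered.add(b)
    for name, path in (alt_paths or {}).items():
        if name in region_paths:
            raise NameCollisionError(f"region path name {name!r} already used")
        for b in path:
            if b in covered:
                raise PartitionError(f"designated path {name!r} shares block {b!r} with another region path")
            covered.add(b)
        region_paths[name] = list(path)

    free = set(g.blocks) - covered
    block_rp = {b: rp for rp, path in region_paths.items() for b in path}
    chains = _chain_decomposition(g, free)
    # order chains by (anchor, attachment offset) so alt numbering is
    # monotone along the genome
    keyed = []
    for chain in chains:
        anchor, key = _anchor_of_chain(g, chain, block_rp)
        keyed.append((anchor or "", key, chain))
    keyed.sort(key=lambda t: (t[0], t[1], t[2][0]))
    counters: dict = {}
    for anchor, _key, chain in keyed:
        if anchor:
            counters[anchor] = counters.get(anchor, 0) + 1
            name = f"{anchor}-alt{counters[anchor]}"
        else:
            name = chain[0]
        if name in region_paths:
            raise NameCollisionError(f"auto-generated name {name!r} collides")
        region_paths[name] = chain
    return RegionPathPartition(HIERARCHICAL, region_paths, g)


def _split_runs(g: SequenceGraph, path: Sequence[str]):
    """Split a block path into segments wherever something attaches/detaches:
    a cut is placed between consecutive blocks unless the edge between them
    is the only edge out of the left and into the right block."""
    segments = [[path[0]]]
    for a, b in zip(path, path[1:]):
        if g.successors(a) == (b,) and g.predecessors(b) == (a,):
            segments[-1].append(b)
        else:
            segments.append([b])
    return segments


def sequential_partition(
    g: SequenceGraph,
    alt_paths: Optional[Mapping[str, Sequence[str]]] = None,
    alt_naming: str = "parallel",
) -> RegionPathPartition:
    """Divide the main paths wherever an alternative path starts or stops.

    Main-path segments are named ``<chrom>-<k>`` with ``k`` increasing
    along the genome (a chromosome with no split points keeps its plain
    name).  Alternative paths become their own region paths, named
    ``<parallel main segment>-alt<j>`` under the default policy
    (``alt_naming="parallel"``); pass ``alt_naming="keep"`` to retain the
    names given in ``alt_paths`` / derived from the hierarchical layout.
    Alternative paths are themselves divided where deeper alternatives
    attach, so every layer is partitioned the same way.
    """
    if alt_naming not in ("parallel", "keep"):
        raise ValueError(f"unknown alt_naming policy {alt_naming!r}")
    hier = hierarchical_partition(g, alt_paths=alt_paths)
    main_names = set(g.main_paths)

    region_paths: dict = {}
    # map: block id at segment start -> segment rp name (for parallel naming)
    seg_of_first_block: dict = {}
    seg_after_block: dict = {}  # block id -> name of segment starting right after it

    # split every hierarchical region path; process mains first so alt
    # names can refer to main segments, then alts anchored on them, etc.
    order = sorted(hier.region_paths, key=lambda n: (n not in main_names, n))
    split_segments: dict = {}
    for name in order:
        segs = _split_runs(g, hier.region_paths[name])
        split_segments[name] = segs

    named_segments: dict = {}  # hier rp name -> list of (seg_name, seg blocks)
    for name in order:
        segs = split_segments[name]
        if name in main_names or alt_naming == "keep":
            base = name
            if len(segs) == 1:
                seg_names = [base]
            else:
                seg_names = [f"{base}-{k}" for k in range(len(segs))]
            named_segments[name] = list(zip(seg_names, segs))

    # name alt chains by their parallel main segment
    if alt_naming == "parallel":
        # resolve in dependency order: an alt's anchor may itself be an alt
        pending = [n for n in order if n not in main_names]
        alt_counters: dict = {}
        guard = 0
        while pending:
            guard += 1
            if guard > 10000:
                raise PartitionError("could not resolve alt-path naming dependencies")
            name = pending.pop(0)
            segs = split_segments[name]
            parallel = _parallel_segment_name(g, hier.region_paths[name], named_segments, hier)
            if parallel is None:
                pending.append(name)
                continue
            alt_counters.setdefault(parallel, 0)
            alt_counters[parallel] += 1
            base = f"{parallel}-alt{alt_counters[parallel]}"
            if len(segs) == 1:
                seg_names = [base]
            else:
                seg_names = [f"{base}-{k}" for k in range(len(segs))]
            named_segments[name] = list(zip(seg_names, segs))

    for name in order:
        for seg_name, seg in named_segments[name]:
            if seg_name in region_paths:
                raise NameCollisionError(f"region path name {seg_name!r} collides")
            region_paths[seg_name] = seg
    return RegionPathPartition(SEQUENTIAL, region_paths, g)


def _parallel_segment_name(g, chain, named_segments, hier):
    """Name of the already-named segment parallel to ``chain``.

    The parallel segment of an alternative path is the anchor's segment
    beginning at the boundary where the alternative diverges (or, for a
    source chain, the segment ending where it re-joins).  Returns ``None``
    if the anchor has not been named yet, or the chain's own head block id
    for fully isolated chains.
    """
    block_rp = hier._block_rp
    preds = sorted(p for p in g.predecessors(chain[0]) if block_rp.get(p) not in (None, block_rp.get(chain[0])))
    if preds:
        anchor_block = preds[0]
        anchor_rp = block_rp[anchor_block]
        if anchor_rp not in named_segments:
            return None
        segs = named_segments[anchor_rp]
        anchor_path = hier.region_paths[anchor_rp]
        idx = anchor_path.index(anchor_block)
        # the segment starting at position idx+1 along the anchor path
        pos = 0
        for seg_name, seg in segs:
            if pos == idx + 1:
                return seg_name
            pos += len(seg)
        # diverges at the very end of the anchor: fall back to last segment
        return segs[-1][0]
    succs = sorted(s for s in g.successors(chain[-1]) if block_rp.get(s) not in (None, block_rp.get(chain[-1])))
    if succs:
        anchor_block = succs[0]
        anchor_rp = block_rp[anchor_block]
        if anchor_rp not in named_segments:
            return None
        segs = named_segments[anchor_rp]
        anchor_path = hier.region_paths[anchor_rp]
        idx = anchor_path.index(anchor_block)
        # segment ending exactly before idx is the parallel one
        pos = 0
        for seg_name, seg in segs:
            if pos + len(seg) == idx:
                return seg_name
            pos += len(seg)
        return segs[0][0]
    return chain[0]


def assign_names(
    p: RegionPathPartition,
    policy: Optional[Callable[[str, Sequence[str]], str]] = None,
) -> dict:
    """Map region-path ids to display names.

    The default policy is the identity: partition constructors already
    bake in the documented scheme (main segments ``<chrom>-<k>`` with k
    monotone along the genome; alternatives ``<parallel segment>-alt<j>``;
    hierarchical alternatives keep their given locus names).  A custom
    ``policy(rp_id, block_list) -> name`` may be supplied; collisions
    raise :class:`NameCollisionError`.
    """
    out = {}
    used = set()
    for rp_id in sorted(p.region_paths):
        name = policy(rp_id, p.region_paths[rp_id]) if policy else rp_id
        if name in used:
            raise NameCollisionError(f"naming policy produced duplicate name {name!r}")
        used.add(name)
        out[rp_id] = name
    return out


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------


def _check_same_graph(a: RegionPathPartition, b: RegionPathPartition):
    if a.graph is not b.graph and not a.graph.same_blocks(b.graph):
        raise CoordinateError("partitions are not over the same underlying graph")


def translate_position(
    pos: Position,
    from_partition: RegionPathPartition,
    to_partition: RegionPathPartition,
) -> Position:
    """Re-express a base position in another coordinate system over the
    same graph.  The result addresses the identical base (same block, same
    intra-block offset); the map is a bijection on base positions."""
    _check_same_graph(from_partition, to_partition)
    block, off = from_partition.locate(pos)
    return to_partition.position_of(block, off)


def translate_boundary(
    pos: Position,
    from_partition: RegionPathPartition,
    to_partition: RegionPathPartition,
) -> Position:
    """Translate an interval endpoint (offset may equal the path length)."""
    _check_same_graph(from_partition, to_partition)
    block, off = from_partition.locate_boundary(pos)
    rp = to_partition.rp_of_block(block)
    return Position(rp, to_partition.block_start_in_rp(block) + off)


# ---------------------------------------------------------------------------
# updates and backward compatibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UpdateMapping:
    """Records how one graph update rebased coordinates.

    ``parent_records`` maps each new region-path id to
    ``(old region-path id, offset of the new path's start within the old
    one)``.  ``valid_paths`` is the set of region-path ids valid after the
    update (used to detect unknown names).
    """

    parent_records: Mapping[str, tuple]
    valid_paths: frozenset

    def resolve(self, pos: Position) -> Position:
        """Image of an old-coordinate position after this update."""
        children = sorted(
            ((off, new_id) for new_id, (old_id, off) in self.parent_records.items()
             if old_id == pos.region_path_id),
        )
        if children:
            idx = bisect.bisect_right([off for off, _ in children], pos.offset) - 1
            if idx < 0:
                raise CoordinateError(
                    f"offset {pos.offset} precedes every child of {pos.region_path_id!r}"
                )
            off, new_id = children[idx]
            return Position(new_id, pos.offset - off)
        if pos.region_path_id in self.valid_paths:
            return pos
        raise CoordinateError(f"region path {pos.region_path_id!r} unknown in update mapping")

    def to_dict(self) -> dict:
        return {
            "parent_records": {k: list(v) for k, v in sorted(self.parent_records.items())},
            "valid_paths": sorted(self.valid_paths),
        }

    @classmethod
    def from_dict(cls, doc):
        return cls(
            {k: tuple(v) for k, v in doc["parent_records"].items()},
            frozenset(doc["valid_paths"]),
        )


def identity_mapping(p: RegionPathPartition) -> UpdateMapping:
    return UpdateMapping({}, frozenset(p.region_paths))


def _split_block_in_working(working, block_id, cut):
    """Split ``block_id`` at intra-offset ``cut`` inside the mutable working
    copy of a graph; returns the (left, right) child ids."""
    blocks, edges, paths_lists, source_maps = working
    blk = blocks[block_id]
    if not 0 < cut < blk.length:
        raise CoordinateError(f"cannot split block {block_id!r} at {cut}")
    root = blk.origin if blk.origin is not None else (block_id, 0)
    left = Block(
        id=f"{block_id}[:{cut}]",
        length=cut,
        sequence=blk.sequence[:cut] if blk.sequence else None,
        origin=(root[0], root[1]),
    )
    right = Block(
        id=f"{block_id}[{cut}:]",
        length=blk.length - cut,
        sequence=blk.sequence[cut:] if blk.sequence else None,
        origin=(root[0], root[1] + cut),
    )
    del blocks[block_id]
    blocks[left.id] = left
    blocks[right.id] = right
    new_edges = set()
    for f, t in edges:
        f2 = right.id if f == block_id else f
        t2 = left.id if t == block_id else t
        new_edges.add((f2, t2))
    new_edges.add((left.id, right.id))
    edges.clear()
    edges.update(new_edges)
    for path in paths_lists:
        for i, b in enumerate(list(path)):
            if b == block_id:
                path[i:i + 1] = [left.id, right.id]
    for name, segs in list(source_maps.items()):
        new_segs = []
        for seg in segs:
            if seg.block_id != block_id:
                new_segs.append(seg)
                continue
            lo, hi = seg.block_offset, seg.block_offset + (seg.end - seg.start)
            if hi <= cut:
                new_segs.append(SourceSegment(seg.start, seg.end, left.id, lo))
            elif lo >= cut:
                new_segs.append(SourceSegment(seg.start, seg.end, right.id, lo - cut))
            else:
                mid = seg.start + (cut - lo)
                new_segs.append(SourceSegment(seg.start, mid, left.id, lo))
                new_segs.append(SourceSegment(mid, seg.end, right.id, 0))
        source_maps[name] = new_segs
    return left.id, right.id


def apply_update(
    p: RegionPathPartition,
    new_blocks: Sequence[Block],
    target_rp: str,
    start_offset: int,
    end_offset: int,
    alt_name: Optional[str] = None,
) -> tuple:
    """Add a new alternative path parallel to ``target_rp[start:end)``.

    The new blocks form a chain attached from the base boundary
    ``start_offset`` to the boundary ``end_offset`` of ``target_rp``
    (boundaries falling mid-block split the block first; base identity is
    preserved through block ``origin`` records).

    Returns ``(new_partition, update_mapping)``:

    * hierarchical partition: all existing region paths are untouched and
      one new alternative region path appears — old coordinates stay valid
      verbatim, and the mapping is the identity.
    * sequential partition: ``target_rp`` is replaced by up to three region
      paths (before / parallel to / after the new alternative) and the
      mapping records the parent and start offset of each.
    """
    total = p.rp_length(target_rp)
    if not 0 <= start_offset <= end_offset <= total:
        raise CoordinateError(
            f"attachment offsets [{start_offset}, {end_offset}] out of range for "
            f"{target_rp!r} (length {total})"
        )
    if not new_blocks:
        raise ValidationError("new alternative path must contain at least one block")
    for blk in new_blocks:
        if blk.id in p.graph.blocks:
            raise ValidationError(f"new block id {blk.id!r} already exists in the graph")

    g = p.graph
    blocks = dict(g.blocks)
    edges = set(g._edges)
    main_paths = {k: list(v) for k, v in g.main_paths.items()}
    region_paths = {k: list(v) for k, v in p.region_paths.items()}
    source_maps = {k: list(v) for k, v in g.source_maps.items()}
    paths_lists = list(main_paths.values()) + list(region_paths.values())
    working = (blocks, edges, paths_lists, source_maps)

    def boundary_block_pair(offset):
        """(block ending at offset | None, block starting at offset | None),
        splitting a block if the boundary falls inside it."""
        path = region_paths[target_rp]
        if offset == 0:
            return None, path[0]
        pos = 0
        for i, b in enumerate(path):
            blen = blocks[b].length
            if pos + blen == offset:
                nxt = path[i + 1] if i + 1 < len(path) else None
                return b, nxt
            if pos < offset < pos + blen:
                left, right = _split_block_in_working(working, b, offset - pos)
                return left, right
            pos += blen
        return path[-1], None  # offset == total

    left_a, _ = boundary_block_pair(start_offset)
    _, right_b = boundary_block_pair(end_offset)

    for blk in new_blocks:
        blocks[blk.id] = blk
    for a, b in zip(new_blocks, new_blocks[1:]):
        edges.add((a.id, b.id))
    if left_a is not None:
        edges.add((left_a, new_blocks[0].id))
    if right_b is not None:
        edges.add((new_blocks[-1].id, right_b))

    new_graph = build_graph(list(blocks.values()), edges, main_paths, source_maps=source_maps)

    if alt_name is None:
        j = 1
        while f"{target_rp}-alt{j}" in region_paths:
            j += 1
        alt_name = f"{target_rp}-alt{j}"
    if alt_name in region_paths:
        raise NameCollisionError(f"region path name {alt_name!r} already exists")
    alt_chain = [b.id for b in new_blocks]

    if p.kind == HIERARCHICAL:
        region_paths[alt_name] = alt_chain
        new_p = RegionPathPartition(HIERARCHICAL, region_paths, new_graph)
        return new_p, identity_mapping(new_p)

    # sequential: replace target_rp by up to three region paths
    path = region_paths.pop(target_rp)
    cuts = sorted({0, start_offset, end_offset, total})
    seg_bounds = list(zip(cuts, cuts[1:]))
    segments = []
    pos = 0
    i = 0
    for lo, hi in seg_bounds:
        seg_blocks = []
        while pos < hi:
            b = path[i]
            seg_blocks.append(b)
            pos += blocks[b].length
            i += 1
        segments.append((lo, seg_blocks))
    parent_records = {}
    k = 0
    for lo, seg_blocks in segments:
        if not seg_blocks:
            continue
        name = f"{target_rp}/{k}"
        k += 1
        while name in region_paths:  # a prior update may have freed and reused names
            name += "'"
        region_paths[name] = seg_blocks
        parent_records[name] = (target_rp, lo)
    region_paths[alt_name] = alt_chain
    new_p = RegionPathPartition(SEQUENTIAL, region_paths, new_graph)
    mapping = UpdateMapping(parent_records, frozenset(region_paths))
    return new_p, mapping


def resolve_legacy(pos: Position, chain: Sequence[UpdateMapping]) -> Position:
    """Carry a position from an old graph version through a chain of
    updates (ordered oldest to newest); the result addresses the same
    underlying base in the newest version."""
    cur = pos
    for mapping in chain:
        cur = mapping.resolve(cur)
    return cur
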