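"""Core sequence-graph data model.

A genome is modelled as a directed acyclic graph of *blocks* (linear DNA
segments of one or more base pairs) connected by unlabeled, strandless
adjacency edges.  One or more *main paths* — one per chromosome — are
designated through the graph; everything off a main path is alternative
sequence.

Blocks may carry an explicit sequence or only a length: all coordinate
arithmetic works on topology alone, and sequence-requiring operations
fail loudly instead of fabricating bases.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .errors import (
    CycleError,
    MissingSequenceError,
    PathOverflowError,
    UnknownBlockError,
    ValidationError,
)

_SEQ_RE = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class Block:
    """A named linear DNA segment, the unit of offset-based addressing.

    Parameters
    ----------
    id:
        Unique identifier.
    length:
        Number of base pairs; at least 1.
    sequence:
        Optional DNA string over ``{A, C, G, T, N}``; if present its
        length must equal ``length``.
    origin:
        Optional ``(root_block_id, offset)`` provenance for blocks created
        by splitting an earlier block.  Used to track base identity across
        graph updates; ``None`` for original blocks.
    """

    id: str
    length: int
    sequence: Optional[str] = None
    origin: Optional[tuple] = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("block id must be a non-empty string")
        if self.length < 1:
            raise ValidationError(f"block {self.id!r}: length must be >= 1, got {self.length}")
        if self.sequence is not None:
            seq = self.sequence.upper()
            if seq != self.sequence:
                object.__setattr__(self, "sequence", seq)
            if len(seq) != self.length:
                raise ValidationError(
                    f"block {self.id!r}: sequence length {len(seq)} != declared length {self.length}"
                )
            if not _SEQ_RE.match(seq):
                raise ValidationError(f"block {self.id!r}: sequence contains non-ACGTN characters")

    def base_key(self, offset: int) -> tuple:
        """Stable identity of the base at ``offset``, surviving block splits."""
        if not 0 <= offset < self.length:
            raise ValidationError(f"offset {offset} out of range for block {self.id!r}")
        if self.origin is not None:
            root, shift = self.origin
            return (root, shift + offset)
        return (self.id, offset)


@dataclass(frozen=True)
class SourceSegment:
    """Maps a linear source-coordinate range onto part of one block.

    Source positions ``[start, end)`` correspond to block positions
    ``[block_offset, block_offset + end - start)``.
    """

    start: int
    end: int
    block_id: str
    block_offset: int = 0

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(f"bad source segment range [{self.start}, {self.end})")
        if self.block_offset < 0:
            raise ValidationError("negative block_offset in source segment")


class SequenceGraph:
    """Directed acyclic graph of blocks with designated main paths.

    Use :func:`build_graph` to construct a validated instance.  Iteration
    order is deterministic everywhere (sorted by id) so that all outputs
    are reproducible byte-for-byte.
    """

    def __init__(self, blocks, edges, main_paths, source_maps=None, _validated=False):
        self.blocks: dict = dict(blocks)
        self._edges: frozenset = frozenset(edges)
        self.main_paths: dict = {k: list(v) for k, v in main_paths.items()}
        self.source_maps: dict = {k: list(v) for k, v in (source_maps or {}).items()}
        for f, t in self._edges:
            for b in (f, t):
                if b not in self.blocks:
                    raise UnknownBlockError(f"edge ({f!r}, {t!r}) references unknown block {b!r}")
        succ: dict = {b: [] for b in self.blocks}
        pred: dict = {b: [] for b in self.blocks}
        for f, t in self._edges:
            succ[f].append(t)
            pred[t].append(f)
        self._succ = {k: tuple(sorted(v)) for k, v in succ.items()}
        self._pred = {k: tuple(sorted(v)) for k, v in pred.items()}
        self._desc_cache: dict = {}
        if not _validated:
            self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self):
        nxg = self.to_networkx()
        if not nx.is_directed_acyclic_graph(nxg):
            cyc = nx.find_cycle(nxg)
            raise CycleError(f"graph contains a cycle: {cyc}")
        for name, path in self.main_paths.items():
            if not path:
                raise ValidationError(f"main path {name!r} is empty")
            for b in path:
                if b not in self.blocks:
                    raise UnknownBlockError(f"main path {name!r} references unknown block {b!r}")
            for a, b in zip(path, path[1:]):
                if (a, b) not in self._edges:
                    raise ValidationError(
                        f"main path {name!r}: consecutive blocks {a!r} -> {b!r} are not joined by an edge"
                    )
        for name, segs in self.source_maps.items():
            pos = 0
            for seg in segs:
                if seg.block_id not in self.blocks:
                    raise UnknownBlockError(f"source map {name!r} references unknown block {seg.block_id!r}")
                if seg.start != pos:
                    raise ValidationError(f"source map {name!r} has a gap at position {pos}")
                blk = self.blocks[seg.block_id]
                if seg.block_offset + (seg.end - seg.start) > blk.length:
                    raise ValidationError(f"source map {name!r} overruns block {seg.block_id!r}")
                pos = seg.end

    # -- simple accessors ----------------------------------------------

    @property
    def edges(self):
        return sorted(self._edges)

    def has_edge(self, a: str, b: str) -> bool:
        return (a, b) in self._edges

    def successors(self, b: str):
        return self._succ[b]

    def predecessors(self, b: str):
        return self._pred[b]

    def block_ids(self):
        return sorted(self.blocks)

    def block_length(self, b: str) -> int:
        return self.blocks[b].length

    def main_path_blocks(self):
        """Set of block ids lying on any main path."""
        out = set()
        for path in self.main_paths.values():
            out.update(path)
        return out

    def to_networkx(self) -> nx.DiGraph:
        nxg = nx.DiGraph()
        nxg.add_nodes_from(sorted(self.blocks))
        nxg.add_edges_from(sorted(self._edges))
        return nxg

    def topological_order(self):
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def is_reachable(self, a: str, b: str) -> bool:
        """True iff ``b`` is reachable from ``a`` (a path of length >= 0)."""
        if a == b:
            return True
        return b in self.descendants(a)

    def descendants(self, a: str):
        if a not in self._desc_cache:
            self._desc_cache[a] = nx.descendants(self.to_networkx(), a)
        return self._desc_cache[a]

    def same_blocks(self, other: "SequenceGraph") -> bool:
        return self.blocks.keys() == other.blocks.keys() and self._edges == other._edges

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        blocks = []
        for bid in sorted(self.blocks):
            blk = self.blocks[bid]
            rec = {"id": blk.id, "length": blk.length}
            if blk.sequence is not None:
                rec["sequence"] = blk.sequence
            if blk.origin is not None:
                rec["origin"] = list(blk.origin)
            blocks.append(rec)
        doc = {
            "blocks": blocks,
            "edges": [list(e) for e in self.edges],
            "main_paths": {k: list(v) for k, v in sorted(self.main_paths.items())},
        }
        if self.source_maps:
            doc["source_maps"] = {
                name: [[s.start, s.end, s.block_id, s.block_offset] for s in segs]
                for name, segs in sorted(self.source_maps.items())
            }
        return doc

    @classmethod
    def from_dict(cls, doc: Mapping) -> "SequenceGraph":
        blocks = [
            Block(
                id=rec["id"],
                length=rec["length"],
                sequence=rec.get("sequence"),
                origin=tuple(rec["origin"]) if rec.get("origin") else None,
            )
            for rec in doc["blocks"]
        ]
        source_maps = {
            name: [SourceSegment(*row) for row in segs]
            for name, segs in doc.get("source_maps", {}).items()
        }
        return build_graph(
            blocks,
            [tuple(e) for e in doc["edges"]],
            doc["main_paths"],
            source_maps=source_maps,
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_gfa(self) -> str:
        """Export as GFA1: S-lines with LN tags, L-lines with 0M overlap,
        P-lines for the main paths."""
        lines = ["H\tVN:Z:1.0"]
        for bid in sorted(self.blocks):
            blk = self.blocks[bid]
            seq = blk.sequence if blk.sequence is not None else "*"
            lines.append(f"S\t{bid}\t{seq}\tLN:i:{blk.length}")
        for f, t in self.edges:
            lines.append(f"L\t{f}\t+\t{t}\t+\t0M")
        for name in sorted(self.main_paths):
            segs = ",".join(f"{b}+" for b in self.main_paths[name])
            lines.append(f"P\t{name}\t{segs}\t*")
        return "\n".join(lines) + "\n"


def build_graph(
    blocks: Iterable[Block],
    edges: Iterable[tuple],
    main_paths,
    source_maps=None,
) -> SequenceGraph:
    """Validate and assemble a :class:`SequenceGraph`.

    Parameters
    ----------
    blocks:
        Blocks with unique ids.
    edges:
        ``(from_id, to_id)`` pairs; duplicates are rejected.
    main_paths:
        Either a mapping ``{name: [block ids]}`` or a plain list of block-id
        lists.  Unnamed paths are named after their first block when that is
        unambiguous, else ``path<i>``.

    Raises
    ------
    UnknownBlockError
        If an edge or path references an undeclared id.
    CycleError
        If the edge set contains a directed cycle.
    ValidationError
        On duplicate ids/edges or a disconnected main path.
    """
    block_list = list(blocks)
    block_map = {}
    for blk in block_list:
        if blk.id in block_map:
            raise ValidationError(f"duplicate block id {blk.id!r}")
        block_map[blk.id] = blk

    edge_list = [tuple(e) for e in edges]
    edge_set = set()
    for e in edge_list:
        if e in edge_set:
            raise ValidationError(f"duplicate edge {e!r}")
        if e[0] == e[1]:
            raise CycleError(f"self-loop on block {e[0]!r}")
        edge_set.add(e)

    if isinstance(main_paths, Mapping):
        mp = {str(k): list(v) for k, v in main_paths.items()}
    else:
        mp = {}
        paths = [list(p) for p in main_paths]
        for i, path in enumerate(paths):
            name = path[0] if path else f"path{i}"
            if name in mp:
                name = f"path{i}"
            mp[name] = path
    return SequenceGraph(block_map, edge_set, mp, source_maps=source_maps)


def enumerate_paths(g: SequenceGraph, start: str, end: str, max_paths: int = 10000):
    """All directed block paths from ``start`` to ``end``.

    Returns the complete list in lexicographic order (by block id at each
    branch).  ``start == end`` yields the single zero-length walk
    ``[[start]]``; an unreachable ``end`` yields ``[]``.

    Raises
    ------
    PathOverflowError
        If more than ``max_paths`` paths exist — never silent truncation.
    """
    for b in (start, end):
        if b not in g.blocks:
            raise UnknownBlockError(f"unknown block {b!r}")
    if not g.is_reachable(start, end):
        return []
    # restrict the walk to vertices that can still reach the end
    feasible = set(nx.ancestors(g.to_networkx(), end)) | {end}
    results = []
    stack = [(start, [start])]
    while stack:
        node, path = stack.pop()
        if node == end:
            results.append(path)
            if len(results) > max_paths:
                raise PathOverflowError(
                    f"more than {max_paths} paths from {start!r} to {end!r}"
                )
            continue
        # reversed so that the lexicographically smallest branch pops first
        for nxt in reversed(g.successors(node)):
            if nxt in feasible:
                stack.append((nxt, path + [nxt]))
    results.sort()
    return results


def path_sequence(
    g: SequenceGraph,
    path: Sequence[str],
    start_offset: int,
    end_offset: int,
) -> str:
    """Spell the DNA along ``path``, slicing the first block from
    ``start_offset`` and the last block to ``end_offset`` (half-open).

    Raises :class:`MissingSequenceError` if any block on the path lacks
    sequence.
    """
    if not path:
        return ""
    for a, b in zip(path, path[1:]):
        if not g.has_edge(a, b):
            raise ValidationError(f"{a!r} -> {b!r} is not an edge; not a valid path")
    for b in path:
        if b not in g.blocks:
            raise UnknownBlockError(f"unknown block {b!r}")
        if g.blocks[b].sequence is None:
            raise MissingSequenceError(f"block {b!r} carries no sequence")
    first, last = g.blocks[path[0]], g.blocks[path[-1]]
    if not 0 <= start_offset <= first.length:
        raise ValidationError(f"start_offset {start_offset} out of range for block {first.id!r}")
    if not 0 <= end_offset <= last.length:
        raise ValidationError(f"end_offset {end_offset} out of range for block {last.id!r}")
    if len(path) == 1:
        if start_offset > end_offset:
            raise ValidationError("start_offset > end_offset on a single-block path")
        return first.sequence[start_offset:end_offset]
    parts = [first.sequence[start_offset:]]
    parts.extend(g.blocks[b].sequence for b in path[1:-1])
    parts.append(last.sequence[:end_offset])
    return "".join(parts)
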