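"""Shared fixtures: small worked-example graphs and independent oracles.

The oracles here are deliberately naive re-implementations (recursive
DFS, exponential-recursion edit distance, linear-scan offset arithmetic)
kept independent of the package code paths they check.
"""

import random

import pytest

from graphcoords import Block, build_graph
from graphcoords.coordinates import Position, RegionPathPartition


# ---------------------------------------------------------------------------
# worked-example graphs
# ---------------------------------------------------------------------------


@pytest.fixture
def branch_graph():
    """A -> {B, D}; B,D -> C; C -> {E, F}.  Main path A,B,C,E.

    The interval from A:1 to F:0 through D is forced through C, so its
    full form lists C while the minimal form does not.
    """
    blocks = [Block(x, 4, "ACGT") for x in "ABCDEF"]
    edges = [("A", "B"), ("A", "D"), ("B", "C"), ("D", "C"), ("C", "E"), ("C", "F")]
    return build_graph(blocks, edges, {"main": ["A", "B", "C", "E"]})


@pytest.fixture
def branch_partition(branch_graph):
    return RegionPathPartition.from_region_paths(
        branch_graph, {x: [x] for x in "ABCDEF"}
    )


@pytest.fixture
def bubble_graph():
    """Two parallel bubbles between A and E.

    B/B* differ by one substitution (edit distance 1); C/F have edit
    distance 3.  Paths A->E: {B, B*} x {C, F}.
    """
    blocks = [
        Block("A", 4, "ACGT"),
        Block("B", 2, "AA"),
        Block("Bs", 2, "AC"),
        Block("C", 3, "GGG"),
        Block("F", 1, "T"),
        Block("D", 2, "TT"),
        Block("E", 2, "GG"),
    ]
    edges = [
        ("A", "B"), ("A", "Bs"),
        ("B", "C"), ("B", "F"), ("Bs", "C"), ("Bs", "F"),
        ("C", "D"), ("F", "D"), ("D", "E"),
    ]
    return build_graph(blocks, edges, {"main": ["A", "B", "C", "D", "E"]})


@pytest.fixture
def bubble_partition(bubble_graph):
    return RegionPathPartition.from_region_paths(
        bubble_graph, {x: [x] for x in ["A", "B", "Bs", "C", "F", "D", "E"]}
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def dfs_paths_oracle(succ, start, end):
    """All start->end paths by plain recursion over a successor map."""
    out = []

    def rec(node, path):
        if node == end:
            out.append(path)
            return
        for nxt in succ.get(node, ()):
            if nxt not in path:  # DAG, but cheap guard
                rec(nxt, path + [nxt])

    rec(start, [start])
    return sorted(out)


def edit_distance_oracle(a, b):
    """Exponential-time recursive Levenshtein, for strings <= ~8 chars."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    cost = 0 if a[0] == b[0] else 1
    return min(
        edit_distance_oracle(a[1:], b) + 1,
        edit_distance_oracle(a, b[1:]) + 1,
        edit_distance_oracle(a[1:], b[1:]) + cost,
    )


def offset_oracle(partition, rp_id, offset):
    """Linear-scan resolution of (region path, offset) -> (block, intra)."""
    pos = 0
    for b in partition.region_paths[rp_id]:
        length = partition.graph.block_length(b)
        if pos <= offset < pos + length:
            return b, offset - pos
        pos += length
    raise AssertionError(f"offset {offset} not on {rp_id}")


@pytest.fixture
def oracles():
    return {
        "dfs_paths": dfs_paths_oracle,
        "edit_distance": edit_distance_oracle,
        "offset": offset_oracle,
    }


def succ_map(graph):
    return {b: list(graph.successors(b)) for b in graph.blocks}


def random_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_linear_alt_graph(rng, with_sequences=True, max_alts=3):
    """A random chromosome with parallel alt blocks — the shape the
    builders produce, assembled directly for property tests."""
    n_main = rng.randint(2, 6)
    blocks = []
    edges = []
    main = []
    for i in range(n_main):
        length = rng.randint(1, 6)
        blocks.append(
            Block(f"m{i}", length, random_dna(rng, length) if with_sequences else None)
        )
        main.append(f"m{i}")
    edges.extend(zip(main, main[1:]))
    n_alts = rng.randint(0, max_alts)
    for j in range(n_alts):
        i0 = rng.randint(0, n_main - 2)
        i1 = rng.randint(i0 + 1, n_main - 1)
        length = rng.randint(1, 6)
        bid = f"a{j}"
        blocks.append(
            Block(bid, length, random_dna(rng, length) if with_sequences else None)
        )
        edges.append((main[i0], bid))
        edges.append((bid, main[i1]))
    edges = list(dict.fromkeys(edges))
    return build_graph(blocks, edges, {"chr1": main})
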