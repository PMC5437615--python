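import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphcoords import Block, build_graph
from graphcoords.coordinates import (
    HIERARCHICAL,
    SEQUENTIAL,
    Position,
    RegionPathPartition,
    UpdateMapping,
    apply_update,
    assign_names,
    hierarchical_partition,
    parse_position,
    resolve_legacy,
    sequential_partition,
    translate_position,
)
from graphcoords.errors import (
    CoordinateError,
    NameCollisionError,
    ParseError,
    PartitionError,
)

from conftest import offset_oracle, random_linear_alt_graph


def linear_graph():
    return build_graph(
        [Block(x, 10) for x in "ABC"], [("A", "B"), ("B", "C")], {"chr1": ["A", "B", "C"]}
    )


def one_alt_graph():
    """chr14 of three segments with one alt parallel to the middle one."""
    blocks = [Block("s0", 100), Block("s1", 50), Block("s2", 80), Block("alt", 60)]
    edges = [("s0", "s1"), ("s1", "s2"), ("s0", "alt"), ("alt", "s2")]
    return build_graph(blocks, edges, {"chr14": ["s0", "s1", "s2"]})


def layered_graph():
    """Main bottom, alt middle, alt-of-alt top (three layers)."""
    blocks = [Block(x, 5) for x in ["M1", "M2", "M3", "A1", "A2", "A3", "T1"]]
    edges = [
        ("M1", "M2"), ("M2", "M3"),
        ("M1", "A1"), ("A1", "A2"), ("A2", "A3"), ("A3", "M3"),
        ("A1", "T1"), ("T1", "A3"),
    ]
    return build_graph(blocks, edges, {"chr1": ["M1", "M2", "M3"]})


class TestPositionText:
    def test_str(self):
        assert str(Position("chr14", 105)) == "chr14:105"

    def test_parse_plain(self):
        assert parse_position("chr14:105") == Position("chr14", 105)

    def test_parse_si_suffixes(self):
        assert parse_position("chr14:150m") == Position("chr14", 150_000_000)
        assert parse_position("x:2k") == Position("x", 2000)

    def test_parse_garbage(self):
        with pytest.raises(ParseError):
            parse_position("chr14")
        with pytest.raises(ParseError):
            parse_position("chr14:abc")


class TestHierarchicalPartition:
    def test_linear_genome_single_region_path(self):
        p = hierarchical_partition(linear_graph())
        assert list(p.region_paths) == ["chr1"]
        assert p.region_paths["chr1"] == ["A", "B", "C"]

    def test_layered_three_region_paths(self):
        p = hierarchical_partition(layered_graph(), alt_paths={"mid": ["A1", "A2", "A3"]})
        assert len(p.region_paths) == 3
        assert p.region_paths["mid"] == ["A1", "A2", "A3"]
        assert p.region_paths["mid-alt1"] == ["T1"]

    def test_two_disjoint_alts(self):
        blocks = [Block(f"m{i}", 10) for i in range(5)] + [Block("x", 4), Block("y", 4)]
        main = [f"m{i}" for i in range(5)]
        edges = list(zip(main, main[1:])) + [
            ("m0", "x"), ("x", "m2"), ("m2", "y"), ("y", "m4")
        ]
        g = build_graph(blocks, edges, {"chr1": main})
        p = hierarchical_partition(g)
        assert len(p.region_paths) == 3
        assert p.region_paths["chr1-alt1"] == ["x"]
        assert p.region_paths["chr1-alt2"] == ["y"]

    def test_alt_sharing_blocks_rejected(self):
        g = layered_graph()
        with pytest.raises(PartitionError):
            hierarchical_partition(g, alt_paths={"bad": ["M2", "A1"]})

    def test_partition_covers_all_blocks_exactly_once(self):
        for seed in range(25):
            g = random_linear_alt_graph(random.Random(seed), with_sequences=False)
            p = hierarchical_partition(g)
            covered = [b for path in p.region_paths.values() for b in path]
            assert sorted(covered) == g.block_ids()


class TestSequentialPartition:
    def test_one_alt_four_region_paths(self):
        p = sequential_partition(one_alt_graph())
        assert sorted(p.region_paths) == ["chr14-0", "chr14-1", "chr14-1-alt1", "chr14-2"]
        assert p.region_paths["chr14-1-alt1"] == ["alt"]

    def test_layered_division(self):
        p = sequential_partition(layered_graph(), alt_paths={"mid": ["A1", "A2", "A3"]})
        # bottom and middle layers are each divided into three region paths
        bottoms = [n for n in p.region_paths if n.startswith("chr1-")
                   and "alt" not in n]
        assert len(bottoms) == 3
        mids = [n for n, path in p.region_paths.items() if set(path) <= {"A1", "A2", "A3"}]
        assert len(mids) == 3

    def test_linear_identical_to_hierarchical(self):
        g = linear_graph()
        ps = sequential_partition(g)
        ph = hierarchical_partition(g)
        assert ps.region_paths == ph.region_paths

    def test_cover_property(self):
        for seed in range(25):
            g = random_linear_alt_graph(random.Random(seed), with_sequences=False)
            p = sequential_partition(g)
            covered = [b for path in p.region_paths.values() for b in path]
            assert sorted(covered) == g.block_ids()


class TestAssignNames:
    def test_default_identity(self):
        p = sequential_partition(one_alt_graph())
        names = assign_names(p)
        assert names == {n: n for n in p.region_paths}

    def test_hierarchical_keeps_locus_names(self):
        g = one_alt_graph()
        p = hierarchical_partition(g, alt_paths={"IGH-alt1": ["alt"]})
        assert "IGH-alt1" in assign_names(p)
        assert "chr14" in assign_names(p)

    def test_single_path_keeps_chromosome_name(self):
        p = hierarchical_partition(linear_graph())
        assert assign_names(p) == {"chr1": "chr1"}

    def test_collision_detected(self):
        p = sequential_partition(one_alt_graph())
        with pytest.raises(NameCollisionError):
            assign_names(p, policy=lambda rp, blocks: "same")


class TestTranslatePosition:
    def test_before_first_split(self):
        g = one_alt_graph()
        hier = hierarchical_partition(g)
        seq = sequential_partition(g)
        assert translate_position(Position("chr14", 5), hier, seq) == Position("chr14-0", 5)

    def test_after_split_offset_oracle(self):
        g = one_alt_graph()
        hier = hierarchical_partition(g)
        seq = sequential_partition(g)
        # alt attaches at offset 100 on the hierarchical chromosome path
        got = translate_position(Position("chr14", 105), hier, seq)
        assert got == Position("chr14-1", 5)
        block, intra = offset_oracle(hier, "chr14", 105)
        assert seq.position_of(block, intra) == got

    def test_identity(self):
        g = one_alt_graph()
        hier = hierarchical_partition(g)
        pos = Position("chr14", 42)
        assert translate_position(pos, hier, hier) == pos

    def test_out_of_range(self):
        g = one_alt_graph()
        hier = hierarchical_partition(g)
        seq = sequential_partition(g)
        with pytest.raises(CoordinateError):
            translate_position(Position("chr14", 230), hier, seq)

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_bijection(self, seed):
        g = random_linear_alt_graph(random.Random(seed), with_sequences=False)
        hier = hierarchical_partition(g)
        seq = sequential_partition(g)
        seen = set()
        for pos in hier.all_base_positions():
            there = translate_position(pos, hier, seq)
            back = translate_position(there, seq, hier)
            assert back == pos
            seen.add(there)
        # bijection: all sequential base positions are hit exactly once
        assert seen == set(seq.all_base_positions())


class TestApplyUpdate:
    def test_hierarchical_backward_compatible_verbatim(self):
        g = one_alt_graph()
        hier = hierarchical_partition(g)
        before = {pos: hier.base_key(pos) for pos in hier.all_base_positions()}
        new_p, mapping = apply_update(hier, [Block("n1", 7)], "chr14", 30, 60)
        for pos, key in before.items():
            assert new_p.base_key(pos) == key  # old coordinates still valid
        assert mapping.parent_records == {}
        # old valid pairs are a subset of the new valid pairs
        assert set(hier.region_paths) <= set(new_p.region_paths)

    def test_sequential_three_new_region_paths(self):
        g = linear_graph()
        p = sequential_partition(g)
        new_p, mapping = apply_update(p, [Block("n1", 5)], "chr1", 7, 23)
        assert mapping.parent_records == {
            "chr1/0": ("chr1", 0),
            "chr1/1": ("chr1", 7),
            "chr1/2": ("chr1", 23),
        }
        assert new_p.rp_length("chr1/0") == 7
        assert new_p.rp_length("chr1/1") == 16
        assert new_p.rp_length("chr1/2") == 7

    def test_piecewise_resolution(self):
        g = linear_graph()
        p = sequential_partition(g)
        _, mapping = apply_update(p, [Block("n1", 5)], "chr1", 7, 23)
        a, b = 7, 23
        for x in range(30):
            img = mapping.resolve(Position("chr1", x))
            if x < a:
                assert img == Position("chr1/0", x)
            elif x < b:
                assert img == Position("chr1/1", x - a)
            else:
                assert img == Position("chr1/2", x - b)

    def test_attachment_out_of_range(self):
        p = sequential_partition(linear_graph())
        with pytest.raises(CoordinateError):
            apply_update(p, [Block("n1", 5)], "chr1", 10, 99)

    def test_midblock_attachment_splits_block(self):
        p = sequential_partition(linear_graph())
        new_p, _ = apply_update(p, [Block("n1", 5)], "chr1", 12, 17)
        # same bases, new block boundaries
        assert new_p.rp_length("chr1/1") == 5
        assert sum(new_p.rp_length(r) for r in new_p.region_paths
                   if r.startswith("chr1/")) == 30


class TestResolveLegacy:
    def test_empty_chain_identity(self):
        pos = Position("chr1", 3)
        assert resolve_legacy(pos, []) == pos

    def test_unknown_region_path(self):
        mapping = UpdateMapping({}, frozenset({"chr1"}))
        with pytest.raises(CoordinateError):
            resolve_legacy(Position("nope", 0), [mapping])

    def test_two_updates_compose(self):
        g = linear_graph()
        p = sequential_partition(g)
        p1, m1 = apply_update(p, [Block("n1", 5)], "chr1", 7, 23)
        p2, m2 = apply_update(p1, [Block("n2", 4)], "chr1/1", 2, 9)
        # oracle: compose the two piecewise maps by hand
        for x in range(30):
            step1 = m1.resolve(Position("chr1", x))
            expected = m2.resolve(step1)
            assert resolve_legacy(Position("chr1", x), [m1, m2]) == expected
            assert p2.base_key(expected) == p.base_key(Position("chr1", x))

    @given(seed=st.integers(0, 2000))
    @settings(max_examples=25, deadline=None)
    def test_random_update_chains_preserve_bases(self, seed):
        rng = random.Random(seed)
        g = random_linear_alt_graph(rng, with_sequences=False)
        p = sequential_partition(g)
        original = {pos: p.base_key(pos) for pos in p.all_base_positions()}
        chain = []
        for k in range(3):
            rp = rng.choice(sorted(p.region_paths))
            total = p.rp_length(rp)
            a = rng.randint(0, total)
            b = rng.randint(a, total)
            new_blocks = [Block(f"u{seed}_{k}_{i}", rng.randint(1, 4))
                          for i in range(rng.randint(1, 2))]
            p, mapping = apply_update(p, new_blocks, rp, a, b)
            chain.append(mapping)
        for pos, key in original.items():
            assert p.base_key(resolve_legacy(pos, chain)) == key
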