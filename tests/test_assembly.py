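import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphcoords.assembly import (
    AlignmentRecord,
    AltLocusPlacement,
    FixtureParams,
    alt_region_paths,
    build_merged_graph,
    build_simple_graph,
    build_trimmed_graph,
    count_alt_scaffolds,
    detect_flanks,
    generate_fixture,
    read_alignments,
    read_placements,
    write_alignments,
    write_placements,
)
from graphcoords.coordinates import hierarchical_partition, sequential_partition
from graphcoords.errors import (
    AlignmentError,
    FixtureParamError,
    ParseError,
    PlacementError,
)
from graphcoords.graph import enumerate_paths, path_sequence

from conftest import random_dna


class TestPlacementTables:
    def test_round_trip(self):
        rows = [AltLocusPlacement("R1", "chr1", 40, 60, "alt1", 25)]
        text = write_placements(rows)
        assert read_placements(text.splitlines()) == rows

    def test_comments_skipped(self):
        assert read_placements(["# comment", "", "R1\tchr1\t0\t5\ta\t7"]) == [
            AltLocusPlacement("R1", "chr1", 0, 5, "a", 7)
        ]

    def test_ncbi_dialect(self):
        line = (
            "ALT_REF_LOCI_1\tGRCh38\tHSCHR1_1_CTG3\tKI270759.1\tCHROMOSOME\t1\t"
            "CM000663.2\tREGION108\t+\t1\t425501\t2448811\t2791270\t0\t0"
        )
        (p,) = read_placements([line])
        assert p.chrom == "1"
        assert p.chrom_start == 2448810  # 1-based inclusive converted
        assert p.chrom_stop == 2791270
        assert p.alt_name == "HSCHR1_1_CTG3"
        assert p.alt_length == 425501

    def test_bad_column_count(self):
        with pytest.raises(ParseError):
            read_placements(["a\tb\tc"])

    def test_alignment_round_trip(self):
        rows = [
            AlignmentRecord("alt1", 0, 10, "chr1", 40, 50, True),
            AlignmentRecord("alt1", 10, 11, "chr1", 50, 51, False),
        ]
        assert read_alignments(write_alignments(rows).splitlines()) == rows

    def test_count_alt_scaffolds(self):
        report = [
            "# Assembly name: x",
            "1\tassembled-molecule\t1\tChromosome\tCM000663.2\t=\tNC_000001.11\tPrimary Assembly\t248956422\tchr1",
            "HSCHR1_1_CTG3\talt-scaffold\t1\tChromosome\tKI270759.1\t=\tNT_187515.1\tALT_REF_LOCI_1\t425501\tchr1_KI270759v1_alt",
            "HSCHR2_1_CTG1\talt-scaffold\t2\tChromosome\tKI270769.1\t=\tNT_187523.1\tALT_REF_LOCI_1\t120616\tchr2_KI270769v1_alt",
        ]
        assert count_alt_scaffolds(report) == 2


class TestBuildSimpleGraph:
    def test_one_alt_block_and_edge_count(self):
        g = build_simple_graph(
            [AltLocusPlacement("R", "chr", 40, 60, "alt", 25)], {"chr": 100}
        )
        lengths = {b: g.block_length(b) for b in g.block_ids()}
        assert lengths == {"chr-0": 40, "chr-1": 20, "chr-2": 40, "alt": 25}
        assert len(g.edges) == 4
        assert ("chr-0", "alt") in g.edges and ("alt", "chr-2") in g.edges

    def test_no_placements_is_linear(self):
        g = build_simple_graph([], {"chr1": 100})
        assert g.block_ids() == ["chr1"]
        assert g.edges == []

    def test_alt_at_chromosome_start_is_source(self):
        g = build_simple_graph(
            [AltLocusPlacement("R", "chr", 0, 60, "alt", 25)], {"chr": 100}
        )
        assert g.predecessors("alt") == ()
        assert ("alt", "chr-1") in g.edges

    def test_overlapping_placements_rejected(self):
        rows = [
            AltLocusPlacement("R", "chr", 10, 50, "a1", 25),
            AltLocusPlacement("R", "chr", 30, 70, "a2", 25),
        ]
        with pytest.raises(PlacementError):
            build_simple_graph(rows, {"chr": 100})

    def test_base_conservation(self):
        for seed in range(10):
            f = generate_fixture(FixtureParams(n_alts=2, chrom_len=900), seed=seed)
            g = f.build_simple()
            for chrom, length in f.chrom_lengths.items():
                assert sum(g.block_length(b) for b in g.main_paths[chrom]) == length
            for p in f.placements:
                assert g.block_length(p.alt_name) == p.alt_length


class TestDetectFlanks:
    def test_identical_sequences_prefix_first(self):
        assert detect_flanks("ACGT", "ACGT") == (4, 0)

    def test_prefix_then_suffix_of_remainders(self):
        assert detect_flanks("AAACGTTT", "AAATTTT") == (3, 3)

    def test_no_shared_ends(self):
        assert detect_flanks("AAAA", "CCCC") == (0, 0)

    def test_bound(self):
        rng = random.Random(0)
        for _ in range(200):
            a = random_dna(rng, rng.randint(1, 12))
            b = random_dna(rng, rng.randint(1, 12))
            left, right = detect_flanks(a, b)
            assert left + right <= min(len(a), len(b))
            assert a[:left] == b[:left]
            if right:
                assert a[len(a) - right:] == b[len(b) - right:]


class TestBuildTrimmedGraph:
    def test_planted_flanks_recovered(self):
        f = generate_fixture(seed=7)
        build = f.build_trimmed()
        for alt, (fl, fr) in f.ground_truth["flanks"].items():
            info = build.alt_info[alt]
            assert (info.left_flank, info.right_flank) == (fl, fr)
            placement = info.placement
            assert build.graph.block_length(alt) == placement.alt_length - fl - fr

    def test_identical_alt_contributes_no_block(self):
        chrom = random_dna(random.Random(1), 100)
        sequences = {"chr": chrom, "alt": chrom[40:60]}
        build = build_trimmed_graph(
            [AltLocusPlacement("R", "chr", 40, 60, "alt", 20)], sequences
        )
        assert "alt" not in build.graph.blocks
        assert build.alt_info["alt"].alt_blocks == ()

    def test_two_alts_sharing_one_region(self):
        rng = random.Random(2)
        chrom = random_dna(rng, 120)
        main_seg = chrom[40, 80] if False else chrom[40:80]
        a1 = main_seg[:10] + "T" + main_seg[11:]
        a2 = main_seg[:25] + "G" + main_seg[26:]
        a1 = _force_mismatch(a1, main_seg, 10)
        a2 = _force_mismatch(a2, main_seg, 25)
        sequences = {"chr": chrom, "alt1": a1, "alt2": a2}
        rows = [
            AltLocusPlacement("R", "chr", 40, 80, "alt1", len(a1)),
            AltLocusPlacement("R", "chr", 40, 80, "alt2", len(a2)),
        ]
        build = build_trimmed_graph(rows, sequences)
        i1, i2 = build.alt_info["alt1"], build.alt_info["alt2"]
        assert i1.left_flank == 10 and i2.left_flank == 25
        # conservation: flanks + varying block = alt length
        for alt, info in build.alt_info.items():
            assert (
                info.left_flank
                + info.right_flank
                + build.graph.block_length(alt)
                == info.placement.alt_length
            )

    def test_conservation_property(self):
        for seed in range(10):
            f = generate_fixture(FixtureParams(n_alts=2, chrom_len=900), seed=seed)
            build = f.build_trimmed()
            for alt, info in build.alt_info.items():
                varying = (
                    build.graph.block_length(alt) if alt in build.graph.blocks else 0
                )
                assert info.left_flank + info.right_flank + varying == info.placement.alt_length


def _force_mismatch(alt, main, pos):
    if alt[pos] == main[pos]:
        repl = "A" if main[pos] != "A" else "C"
        alt = alt[:pos] + repl + alt[pos + 1:]
    return alt


class TestBuildMergedGraph:
    def _single_snp_setup(self):
        rng = random.Random(3)
        chrom = random_dna(rng, 100)
        alt = chrom[40:50] + _other(chrom[50]) + chrom[51:60]
        sequences = {"chr": chrom, "alt": alt}
        placements = [AltLocusPlacement("R", "chr", 40, 60, "alt", 20)]
        alignments = [
            AlignmentRecord("alt", 0, 10, "chr", 40, 50, True),
            AlignmentRecord("alt", 10, 11, "chr", 50, 51, False),
            AlignmentRecord("alt", 11, 20, "chr", 51, 60, True),
        ]
        return sequences, placements, alignments, chrom, alt

    def test_single_snp_bubble(self):
        sequences, placements, alignments, chrom, alt = self._single_snp_setup()
        build = build_merged_graph(placements, sequences, alignments)
        g = build.graph
        # shared-left, main-base, alt-base, shared-right + flanking chrom blocks
        assert build.alt_info["alt"].alt_blocks == ("alt-v0",)
        assert g.block_length("alt-v0") == 1
        paths = enumerate_paths(g, g.main_paths["chr"][0], g.main_paths["chr"][-1])
        assert len(paths) == 2

    def test_paths_spell_main_or_alt_sequence(self):
        sequences, placements, alignments, chrom, alt = self._single_snp_setup()
        build = build_merged_graph(placements, sequences, alignments)
        g = build.graph
        main = g.main_paths["chr"]
        expected_alt_genome = chrom[:40] + alt + chrom[60:]
        spelled = {
            path_sequence(g, path, 0, g.block_length(path[-1]))
            for path in enumerate_paths(g, main[0], main[-1])
        }
        assert spelled == {chrom, expected_alt_genome}

    def test_deletion_creates_bypass_edge(self):
        rng = random.Random(4)
        chrom = random_dna(rng, 100)
        alt = chrom[40:50] + chrom[53:60]  # 3bp deletion
        sequences = {"chr": chrom, "alt": alt}
        placements = [AltLocusPlacement("R", "chr", 40, 60, "alt", len(alt))]
        alignments = [
            AlignmentRecord("alt", 0, 10, "chr", 40, 50, True),
            AlignmentRecord("alt", 10, 10, "chr", 50, 53, False),
            AlignmentRecord("alt", 10, 17, "chr", 53, 60, True),
        ]
        build = build_merged_graph(placements, sequences, alignments)
        g = build.graph
        main = g.main_paths["chr"]
        assert len(enumerate_paths(g, main[0], main[-1])) == 2
        assert build.alt_info["alt"].alt_blocks == ()

    def test_identical_alt_gives_linear_graph(self):
        rng = random.Random(5)
        chrom = random_dna(rng, 100)
        sequences = {"chr": chrom, "alt": chrom[40:60]}
        placements = [AltLocusPlacement("R", "chr", 40, 60, "alt", 20)]
        alignments = [AlignmentRecord("alt", 0, 20, "chr", 40, 60, True)]
        build = build_merged_graph(placements, sequences, alignments)
        g = build.graph
        main = g.main_paths["chr"]
        assert len(enumerate_paths(g, main[0], main[-1])) == 1

    def test_inconsistent_alignments_rejected(self):
        sequences, placements, alignments, *_ = self._single_snp_setup()
        with pytest.raises(AlignmentError):
            build_merged_graph(placements, sequences, alignments[:-1])

    def test_identity_segment_sequence_checked(self):
        sequences, placements, alignments, chrom, alt = self._single_snp_setup()
        sequences = dict(sequences)
        sequences["alt"] = _other(alt[0]) + alt[1:]
        with pytest.raises(AlignmentError):
            build_merged_graph(placements, sequences, alignments)


def _other(base):
    return "A" if base != "A" else "C"


class TestBuildersAdmitPartitions:
    @pytest.mark.parametrize("mode", ["simple", "trimmed", "merged"])
    def test_both_partitionings(self, mode):
        for seed in range(5):
            f = generate_fixture(FixtureParams(n_chroms=2, n_alts=2), seed=seed)
            if mode == "simple":
                g = f.build_simple()
                alt_paths = {p.alt_name: [p.alt_name] for p in f.placements}
            else:
                build = f.build_trimmed() if mode == "trimmed" else f.build_merged()
                g = build.graph
                alt_paths = alt_region_paths(build)
            hier = hierarchical_partition(g, alt_paths=alt_paths)
            seq = sequential_partition(g, alt_paths=alt_paths)
            for p in (hier, seq):
                covered = sorted(b for path in p.region_paths.values() for b in path)
                assert covered == g.block_ids()


class TestGenerateFixture:
    def test_deterministic(self):
        a = generate_fixture(seed=11)
        b = generate_fixture(seed=11)
        assert a.sequences == b.sequences
        assert a.placements == b.placements
        assert a.alignments == b.alignments
        assert a.transcripts == b.transcripts
        assert a.ground_truth == b.ground_truth

    def test_seed_changes_output(self):
        assert generate_fixture(seed=1).sequences != generate_fixture(seed=2).sequences

    def test_flanks_recovered_by_detection(self):
        for seed in range(10):
            f = generate_fixture(seed=seed)
            for p in f.placements:
                main_seg = f.sequences[p.chrom][p.chrom_start:p.chrom_stop]
                got = detect_flanks(main_seg, f.sequences[p.alt_name])
                assert list(got) == f.ground_truth["flanks"][p.alt_name]

    def test_infeasible_params_fail_before_output(self):
        with pytest.raises(FixtureParamError):
            generate_fixture(FixtureParams(chrom_len=50))
        with pytest.raises(FixtureParamError):
            generate_fixture(FixtureParams(flank_range=(2, 4)))
        with pytest.raises(FixtureParamError):
            generate_fixture(FixtureParams(category_counts={"Z": 1}))

    def test_write_is_text_only_and_reloadable(self, tmp_path):
        f = generate_fixture(seed=3)
        f.write(str(tmp_path))
        placements = read_placements(str(tmp_path / "placements.tsv"))
        assert placements == f.placements
        alignments = read_alignments(str(tmp_path / "alignments.tsv"))
        assert alignments == f.alignments
        from graphcoords.assembly import read_fasta

        assert read_fasta(str(tmp_path / "sequences.fa")) == f.sequences
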