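import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methconcord import annotation as anno
from methconcord.intervals import contains, merge, subtract, total_length


# ---------------------------------------------------------------------------
# brute-force per-base labelling oracles
# ---------------------------------------------------------------------------


def oracle_cpg_context(islands, n, shore=2000, shelf=4000):
    """Label every base by min distance to an island, priority order."""
    labels = ["open_sea"] * n
    for pos in range(n):
        best = None
        for s, e in islands:
            if s <= pos < e:
                best = 0
                break
            dist = s - pos if pos < s else pos - e + 1
            best = dist if best is None else min(best, dist)
        if best == 0:
            labels[pos] = "island"
        elif best is not None and best <= shore:
            labels[pos] = "shore"
        elif best is not None and best <= shelf:
            labels[pos] = "shelf"
    return labels


def oracle_repeats(tandem, line, sine, n):
    labels = ["non_repetitive"] * n
    for pos in range(n):
        if any(s <= pos < e for s, e in tandem):
            labels[pos] = "tandem"
        elif any(s <= pos < e for s, e in line):
            labels[pos] = "LINE"
        elif any(s <= pos < e for s, e in sine):
            labels[pos] = "SINE"
    return labels


def catalog_label_per_base(catalog, chrom, n):
    return [catalog.label_of(chrom, p) for p in range(n)]


class TestCpGContext:
    def test_isolated_island_geometry(self):
        cat = anno.build_cpg_context(
            {"chr1": [(10_000, 11_000)]}, {"chr1": 100_000}
        )
        assert cat.tracks["shore"]["chr1"] == [(8_000, 10_000),
                                               (11_000, 13_000)]
        assert cat.tracks["shelf"]["chr1"] == [(6_000, 8_000),
                                               (13_000, 15_000)]
        assert cat.tracks["open_sea"]["chr1"] == [(0, 6_000), (15_000, 100_000)]

    def test_shore_and_shelf_widths(self):
        cat = anno.build_cpg_context(
            {"chr1": [(50_000, 51_000)]}, {"chr1": 100_000}
        )
        left_shore = cat.tracks["shore"]["chr1"][0]
        assert left_shore[1] - left_shore[0] == 2_000
        left_shelf = cat.tracks["shelf"]["chr1"][0]
        assert left_shelf[1] - left_shelf[0] == 2_000
        # outer shelf edge sits 4 kb from the island boundary
        assert 50_000 - left_shelf[0] == 4_000

    def test_two_close_islands_gap_is_shore(self):
        islands = [(10_000, 11_000), (12_000, 13_000)]  # 1 kb apart
        cat = anno.build_cpg_context({"chr1": islands}, {"chr1": 50_000})
        expected = oracle_cpg_context(islands, 50_000)
        got = catalog_label_per_base(cat, "chr1", 50_000)
        assert got == expected
        assert all(lab == "shore" for lab in got[11_000:12_000])

    def test_island_at_chromosome_start_truncated(self):
        cat = anno.build_cpg_context({"chr1": [(0, 500)]}, {"chr1": 20_000})
        assert cat.tracks["shore"]["chr1"] == [(500, 2_500)]
        cat.validate_partition()

    def test_partition_oracle_random_islands(self):
        rng = np.random.default_rng(5)
        n = 100_000
        starts = np.sort(rng.choice(n - 2_000, size=6, replace=False))
        islands = merge((int(s), int(s) + int(rng.integers(200, 1_500)))
                        for s in starts)
        cat = anno.build_cpg_context({"chr1": islands}, {"chr1": n})
        cat.validate_partition()
        # spot-check the per-base oracle on a coarse grid plus boundaries
        expected = oracle_cpg_context(islands, n)
        probe = set(range(0, n, 97))
        for s, e in islands:
            probe.update(
                p for off in (-4001, -4000, -2001, -2000, -1, 0)
                for p in (s + off, e - 1 - off) if 0 <= p < n
            )
        for pos in sorted(probe):
            assert cat.label_of("chr1", pos) == expected[pos], pos

    def test_idempotent_under_island_merging(self):
        raw = {"chr1": [(10_000, 10_500), (10_400, 11_000)]}
        merged = {"chr1": merge(raw["chr1"])}
        a = anno.build_cpg_context(raw, {"chr1": 50_000})
        b = anno.build_cpg_context(merged, {"chr1": 50_000})
        assert a.tracks == b.tracks


class TestGCDensity:
    def test_paper_examples(self):
        cat = anno.build_gc_density({"chr1": "ACGTA"})
        assert cat.label_of("chr1", 0) == "40"
        cat = anno.build_gc_density({"chr1": "GCGCG"})
        assert cat.label_of("chr1", 0) == "100"

    def test_zero_gc_tile_unlabelled(self):
        cat = anno.build_gc_density({"chr1": "AATTA"})
        assert cat.labels_at("chr1", 2) == []

    def test_all_n_tile_unlabelled(self):
        cat = anno.build_gc_density({"chr1": "NNNNN"})
        assert cat.labels_at("chr1", 0) == []

    def test_exhaustive_all_tiles(self):
        """All 4^5 tiles: label equals 20 * (#G + #C)."""
        tiles = ["".join(t) for t in itertools.product("ACGT", repeat=5)]
        seq = "".join(tiles)
        cat = anno.build_gc_density({"chr1": seq})
        for i, tile in enumerate(tiles):
            gc = sum(1 for b in tile if b in "GC")
            got = cat.labels_at("chr1", 5 * i)
            if gc == 0:
                assert got == []
            else:
                assert got == [str(20 * gc)], tile

    def test_tiles_anchored_at_zero(self):
        cat = anno.build_gc_density({"chr1": "AAAAAGGGGG"})
        assert cat.labels_at("chr1", 4) == []
        assert cat.label_of("chr1", 5) == "100"


class TestRepeats:
    def test_priority_tandem_over_sine(self):
        cat = anno.build_repeats(
            {"chr1": [(100, 200)]},
            {"SINE": {"chr1": [(150, 300)]}},
            {"chr1": 1_000},
        )
        assert cat.label_of("chr1", 175) == "tandem"
        assert cat.label_of("chr1", 250) == "SINE"
        cat.validate_partition()

    def test_ltr_maps_to_other_repeat(self):
        cat = anno.build_repeats(
            {}, {"LTR": {"chr1": [(10, 20)]}}, {"chr1": 100}
        )
        assert cat.label_of("chr1", 15) == "other_repeat"

    def test_no_repeats_all_non_repetitive(self):
        cat = anno.build_repeats({}, {}, {"chr1": 500})
        assert cat.tracks["non_repetitive"]["chr1"] == [(0, 500)]

    def test_partition_oracle(self):
        tandem = [(100, 300), (5_000, 5_500)]
        line = [(250, 800)]
        sine = [(700, 900), (5_400, 6_000)]
        n = 10_000
        cat = anno.build_repeats(
            {"chr1": tandem},
            {"LINE": {"chr1": line}, "SINE": {"chr1": sine}},
            {"chr1": n},
        )
        cat.validate_partition()
        expected = oracle_repeats(tandem, line, sine, n)
        assert catalog_label_per_base(cat, "chr1", n) == expected


GTF_HEADER = "#!genome-build test\n"


def write_gtf(tmp_path, rows):
    p = tmp_path / "t.gtf"
    lines = [GTF_HEADER]
    for chrom, feat, start0, end, strand, attrs in rows:
        lines.append(
            f"{chrom}\tsrc\t{feat}\t{start0 + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"
        )
    p.write_text("".join(lines))
    return p


class TestGeneFeatures:
    def test_plus_strand_intron_and_promoter(self, tmp_path):
        attrs = 'gene_id "g1"; transcript_id "g1.t"; gene_type "protein_coding";'
        gtf = write_gtf(tmp_path, [
            ("chr1", "gene", 50_000, 60_000, "+", attrs),
            ("chr1", "transcript", 50_000, 60_000, "+", attrs),
            ("chr1", "exon", 50_000, 50_500, "+", attrs),
            ("chr1", "exon", 59_000, 60_000, "+", attrs),
        ])
        cat = anno.build_gene_features(gtf, {"chr1": 100_000})
        assert cat.tracks["intron"]["chr1"] == [(50_500, 59_000)]
        assert cat.tracks["promoter"]["chr1"] == [(48_000, 50_000)]

    def test_minus_strand_promoter(self, tmp_path):
        attrs = 'gene_id "g1"; transcript_id "g1.t";'
        gtf = write_gtf(tmp_path, [
            ("chr1", "gene", 50_000, 60_000, "-", attrs),
            ("chr1", "exon", 50_000, 60_000, "-", attrs),
        ])
        cat = anno.build_gene_features(gtf, {"chr1": 100_000})
        assert cat.tracks["promoter"]["chr1"] == [(60_000, 62_000)]

    def test_promoter_length_is_2000(self, tmp_path):
        attrs = 'gene_id "g1"; transcript_id "g1.t";'
        gtf = write_gtf(tmp_path, [
            ("chr1", "gene", 50_000, 60_000, "+", attrs),
            ("chr1", "exon", 50_000, 60_000, "+", attrs),
        ])
        cat = anno.build_gene_features(gtf, {"chr1": 100_000})
        (s, e), = cat.tracks["promoter"]["chr1"]
        assert e - s == 2_000

    def test_intergenic_is_complement_oracle(self, tmp_path):
        attrs = 'gene_id "g1"; transcript_id "g1.t";'
        gtf = write_gtf(tmp_path, [
            ("chr1", "gene", 30_000, 40_000, "+", attrs),
            ("chr1", "exon", 30_000, 40_000, "+", attrs),
        ])
        n = 60_000
        cat = anno.build_gene_features(gtf, {"chr1": n})
        blocked = [(28_000, 40_000)]  # promoter + gene
        for pos in range(0, n, 53):
            in_blocked = any(s <= pos < e for s, e in blocked)
            got = "intergenic" in cat.labels_at("chr1", pos)
            assert got == (not in_blocked), pos

    def test_transcript_without_exons_warns(self, tmp_path):
        attrs_g = 'gene_id "g1"; transcript_id "g1.t1";'
        gtf = write_gtf(tmp_path, [
            ("chr1", "gene", 10, 100, "+", attrs_g),
            ("chr1", "transcript", 10, 100, "+", attrs_g),
        ])
        with pytest.warns(UserWarning, match="without exons"):
            anno.build_gene_features(gtf, {"chr1": 1_000})

    def test_overlay_semantics_exon_and_cds_and_gene(self, tmp_path):
        attrs = 'gene_id "g1"; transcript_id "g1.t";'
        gtf = write_gtf(tmp_path, [
            ("chr1", "gene", 100, 400, "+", attrs),
            ("chr1", "exon", 100, 200, "+", attrs),
            ("chr1", "CDS", 120, 180, "+", attrs),
        ])
        cat = anno.build_gene_features(gtf, {"chr1": 1_000})
        labels = set(cat.labels_at("chr1", 150))
        assert {"gene", "exon", "CDS"} <= labels


class TestRegulatory:
    def test_merge_and_overlay(self):
        cat = anno.build_regulatory(
            {"chr1": merge([(10, 50), (40, 90)])},
            {"chr1": [(80, 120)]},
            {"chr1": 1_000},
        )
        assert cat.tracks["open_chromatin"]["chr1"] == [(10, 90)]
        assert set(cat.labels_at("chr1", 85)) == {"open_chromatin", "enhancer"}

    def test_empty_track(self):
        cat = anno.build_regulatory({}, {}, {"chr1": 100})
        assert cat.tracks["enhancer"] == {}


class TestReferenceCpGIndex:
    def test_simple_sequence(self):
        pos = anno.find_cpg_positions("AACGTCGA")
        assert list(pos) == [2, 5]

    def test_overlapping_cg_runs(self):
        # sliding-window oracle over "CGCG"
        seq = "CGCG"
        expected = [i for i in range(len(seq) - 1) if seq[i:i + 2] == "CG"]
        assert list(anno.find_cpg_positions(seq)) == expected == [0, 2]

    def test_partition_counts_conserve_total(self):
        seq = "AACGTCGA" + "T" * 100
        cat = anno.build_cpg_context({"chr1": [(0, 4)]}, {"chr1": len(seq)})
        idx = anno.index_reference_cpgs({"chr1": seq}, [cat])
        total = sum(idx.count("cpg_context", lab) for lab in cat.labels)
        assert total == idx.total == 2

    def test_counts_on_simulated_genome(self, small_sim):
        cfg, genome = small_sim
        cat = anno.build_cpg_context(genome.islands, genome.genome_sizes)
        idx = anno.index_reference_cpgs(genome.sequences, [cat])
        assert sum(
            idx.count("cpg_context", lab) for lab in cat.labels
        ) == idx.total
        assert idx.total > 0

    def test_chromosome_mismatch_raises(self):
        cat = anno.build_cpg_context({"chr9": [(0, 10)]}, {"chr9": 100})
        with pytest.raises(ValueError, match="absent from FASTA"):
            anno.index_reference_cpgs({"chr1": "ACGT"}, [cat])


class TestTableReaders:
    def test_islands_with_and_without_bin_column(self, tmp_path):
        with_bin = tmp_path / "a.txt"
        with_bin.write_text("585\tchr1\t100\t200\tCpG\n")
        without = tmp_path / "b.txt"
        without.write_text("chr1\t100\t200\tCpG\n")
        assert anno.read_cpg_islands(with_bin) == {"chr1": [(100, 200)]}
        assert anno.read_cpg_islands(without) == {"chr1": [(100, 200)]}

    def test_rmsk_classes(self, tmp_path):
        p = tmp_path / "rmsk.txt"
        p.write_text(
            "0\t0\t0\t0\t0\tchr1\t10\t20\t0\t+\tL1\tLINE\n"
            "0\t0\t0\t0\t0\tchr1\t30\t40\t0\t-\tAlu\tSINE\n"
        )
        rmsk = anno.read_rmsk(p)
        assert rmsk["LINE"] == {"chr1": [(10, 20)]}
        assert rmsk["SINE"] == {"chr1": [(30, 40)]}

    def test_read_bed_merges(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t10\t50\nchr1\t40\t90\n")
        assert anno.read_bed(p) == {"chr1": [(10, 90)]}


class TestIntervalAlgebra:
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=12,
        ),
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=12,
        ),
    )
    @settings(max_examples=60, deadline=None)
    def test_subtract_matches_per_base_oracle(self, a_raw, b_raw):
        a, b = merge(a_raw), merge(b_raw)
        result = subtract(a, b)
        for pos in range(0, 600):
            expected = contains(a, pos) and not contains(b, pos)
            assert contains(result, pos) == expected

    @given(
        st.lists(
            st.tuples(st.integers(0, 300), st.integers(1, 50)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=10,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_merge_preserves_covered_bases(self, raw):
        covered = {p for s, e in raw for p in range(s, e)}
        merged = merge(raw)
        assert total_length(merged) == len(covered)
        for pos in range(0, 400):
            assert contains(merged, pos) == (pos in covered)
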