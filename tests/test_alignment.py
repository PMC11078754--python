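"""SAM loading, CIGAR reference blocks, filters, random selection, trimming."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from ambiquant.alignment import (
    FilterConfig,
    FragmentMappingSet,
    Mapping,
    ReadMappingSet,
    classify_counts,
    load_fragment_mappings,
    load_read_mappings,
    random_select,
    reference_blocks,
    trim_reads_3prime,
)
from ambiquant.core import GenomicInterval, InputError, ParseError

from conftest import paired_records, sam_line, single_end_records, write_sam

CHIP_FILTERS = FilterConfig()  # default chr1..N/X/Y pattern
NO_FILTERS = FilterConfig(keep_reference_pattern=None)


class TestReferenceBlocks:
    @pytest.mark.parametrize("cigar,pos,expected", [
        ("100M", 10, [(10, 110)]),
        ("50M200N50M", 0, [(0, 50), (250, 300)]),
        ("40M2D60M", 0, [(0, 102)]),
        ("5S90M5S", 100, [(100, 190)]),
        ("10M5I10M", 0, [(0, 20)]),
        ("20M10N5M2D5M", 1000, [(1000, 1020), (1030, 1042)]),
    ])
    def test_reference_consuming_semantics(self, cigar, pos, expected):
        assert reference_blocks(cigar, pos) == expected

    def test_invalid_cigar_raises(self):
        with pytest.raises(ParseError):
            reference_blocks("10M3Q", 0)
        with pytest.raises(ParseError):
            reference_blocks("", 0)

    @given(st.lists(st.tuples(st.integers(1, 50), st.sampled_from("MIDNS=X")),
                    min_size=1, max_size=8))
    @settings(derandomize=True, max_examples=100)
    def test_blocks_sorted_disjoint_and_cover_reference_span(self, ops):
        cigar = "".join(f"{n}{op}" for n, op in ops)
        blocks = reference_blocks(cigar, 100)
        ref_consumed = sum(n for n, op in ops if op in "MDN=X")
        block_bases = sum(e - s for s, e in blocks)
        skipped = sum(n for n, op in ops if op == "N")
        assert block_bases <= ref_consumed
        assert block_bases >= ref_consumed - skipped - 1  # trailing D edge
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            assert e1 < s2  # sorted with a gap (the N skip)


class TestLoadReadMappings:
    def test_single_record_is_unimapper(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", single_end_records("r1", [(100, "50M")]))
        (rs,) = load_read_mappings(sam, CHIP_FILTERS)
        assert rs.multiplicity == 1 and not rs.is_multimapper
        assert rs.read_length == 50
        assert rs.mappings[0].aligned_blocks == ((100, 150),)

    def test_chrm_record_removed_before_multiplicity(self, tmp_path):
        header = ("@HD\tVN:1.6\tSO:unsorted\n"
                  "@SQ\tSN:chr1\tLN:1000000\n@SQ\tSN:chrM\tLN:16000\n")
        lines = [sam_line("r1", 0, "chr1", 100, "50M"),
                 sam_line("r1", 256, "chrM", 5, "50M")]
        sam = write_sam(tmp_path / "a.sam", lines, header)
        stats = {}
        (rs,) = load_read_mappings(sam, CHIP_FILTERS, stats)
        assert rs.multiplicity == 1 and not rs.is_multimapper
        assert stats["records_filtered_reference"] == 1

    def test_scaffold_filter_uses_default_pattern(self, tmp_path):
        header = ("@HD\tVN:1.6\tSO:unsorted\n"
                  "@SQ\tSN:chr1\tLN:1000000\n@SQ\tSN:chrUn_KI270442v1\tLN:400000\n")
        lines = [sam_line("r1", 0, "chrUn_KI270442v1", 10, "50M")]
        sam = write_sam(tmp_path / "a.sam", lines, header)
        assert list(load_read_mappings(sam, CHIP_FILTERS)) == []

    def test_three_records_are_multimapper(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam",
                        single_end_records("r1", [(100, "50M"), (900, "50M"),
                                                  (5000, "50M")]))
        (rs,) = load_read_mappings(sam, CHIP_FILTERS)
        assert rs.multiplicity == 3 and rs.is_multimapper

    def test_duplicate_records_collapse_with_warning_count(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam",
                        single_end_records("r1", [(100, "50M"), (100, "50M")]))
        stats = {}
        (rs,) = load_read_mappings(sam, CHIP_FILTERS, stats)
        assert rs.multiplicity == 1
        assert stats["records_duplicate"] == 1

    def test_headerless_sam_rejected(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(sam_line("r1", 0, "chr1", 100, "50M"))
        with pytest.raises(Exception):
            list(load_read_mappings(sam, CHIP_FILTERS))

    def test_classification_partitions_reads(self, tmp_path):
        lines = (single_end_records("u1", [(100, "50M")])
                 + single_end_records("m1", [(200, "50M"), (300, "50M")])
                 + single_end_records("u2", [(400, "50M")]))
        sam = write_sam(tmp_path / "a.sam", lines)
        stats = {}
        reads = list(load_read_mappings(sam, CHIP_FILTERS, stats))
        counts = classify_counts(reads)
        assert counts["total"] == 3
        assert counts["unimappers"] + counts["multimappers"] == counts["total"]
        assert stats["unimappers"] == 2 and stats["multimappers"] == 1


class TestLoadFragmentMappings:
    def test_single_proper_pair_is_unimapper(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam", paired_records("f1", [(100, 300)]))
        (fs,) = load_fragment_mappings(sam)
        assert fs.multiplicity == 1 and not fs.is_multimapper
        m1, m2 = fs.mappings[0]
        assert m1.start == 100 and m2.start == 300

    def test_two_concordant_pairs_are_multimapper(self, tmp_path):
        sam = write_sam(tmp_path / "a.sam",
                        paired_records("f1", [(100, 300), (5000, 5200)]))
        (fs,) = load_fragment_mappings(sam)
        assert fs.multiplicity == 2 and fs.is_multimapper

    def test_non_proper_records_excluded(self, tmp_path):
        # paired flags without the proper-pair bit (0x2)
        lines = [sam_line("f1", 97, "chr1", 100, "50M", "=", 900, 850),
                 sam_line("f1", 145, "chr1", 900, "50M", "=", 100, -850)]
        sam = write_sam(tmp_path / "a.sam", lines)
        assert list(load_fragment_mappings(sam)) == []

    def test_mate_missing_dropped_with_counter(self, tmp_path):
        lines = paired_records("f1", [(100, 300)])[:1]  # drop the mate2 record
        sam = write_sam(tmp_path / "a.sam", lines)
        stats = {}
        assert list(load_fragment_mappings(sam, stats=stats)) == []
        assert stats["records_mate_missing"] == 1


class TestRandomSelect:
    def mk_read(self, n):
        maps = [Mapping(GenomicInterval("chr1", i * 100, i * 100 + 50),
                        ((i * 100, i * 100 + 50),), 50) for i in range(n)]
        return ReadMappingSet("r", 50, maps)

    def test_unimapper_returned_unchanged(self):
        rs = self.mk_read(1)
        assert random_select(rs, np.random.default_rng(0)) is rs

    def test_deterministic_under_fixed_seed(self):
        rs = self.mk_read(5)
        a = random_select(rs, np.random.default_rng(42))
        b = random_select(rs, np.random.default_rng(42))
        assert a.mappings == b.mappings
        assert a.multiplicity == 1

    def test_selection_uniform_chi_squared(self):
        """Empirical selection frequencies over 10,000 seeded draws fit the
        uniform law on four mappings (GOF not rejected at alpha = 0.001)."""
        rs = self.mk_read(4)
        rng = np.random.default_rng(123)
        counts = np.zeros(4)
        for _ in range(10_000):
            sel = random_select(rs, rng)
            counts[sel.mappings[0].start // 100] += 1
        stat, p = scipy.stats.chisquare(counts)
        assert p > 0.001

    def test_fragment_selection(self):
        m = Mapping(GenomicInterval("chr1", 0, 50), ((0, 50),), 50)
        fs = FragmentMappingSet("f", [(m, m), (m, m)])
        sel = random_select(fs, np.random.default_rng(0))
        assert isinstance(sel, FragmentMappingSet) and sel.multiplicity == 1


class TestTrimReads:
    def write_fastq(self, path, records):
        path.write_text("".join(f"@{n}\n{s}\n+\n{q}\n" for n, s, q in records))
        return path

    def test_long_read_truncated_to_5prime_prefix(self, tmp_path):
        fq = self.write_fastq(tmp_path / "in.fq", [("r1", "A" * 60 + "C" * 40,
                                                    "I" * 100)])
        out = tmp_path / "out.fq"
        trim_reads_3prime(fq, 25, out)
        lines = out.read_text().splitlines()
        assert lines[1] == "A" * 25 and lines[3] == "I" * 25

    def test_short_read_unchanged(self, tmp_path):
        fq = self.write_fastq(tmp_path / "in.fq", [("r1", "ACGTACGTACGTACGTACGT",
                                                    "I" * 20)])
        out = tmp_path / "out.fq"
        trim_reads_3prime(fq, 25, out)
        assert out.read_text().splitlines()[1] == "ACGTACGTACGTACGTACGT"

    def test_pair_ids_preserved(self, tmp_path):
        fq1 = self.write_fastq(tmp_path / "in1.fq", [("frag1/1", "A" * 50, "I" * 50)])
        fq2 = self.write_fastq(tmp_path / "in2.fq", [("frag1/2", "C" * 50, "I" * 50)])
        o1, o2 = tmp_path / "o1.fq", tmp_path / "o2.fq"
        n = trim_reads_3prime((fq1, fq2), 25, (o1, o2))
        assert n == 1
        assert o1.read_text().splitlines()[0] == "@frag1/1"
        assert o2.read_text().splitlines()[0] == "@frag1/2"

    def test_quality_length_mismatch_names_record(self, tmp_path):
        fq = self.write_fastq(tmp_path / "in.fq", [("badrec", "ACGT", "II")])
        with pytest.raises(InputError, match="record 1"):
            trim_reads_3prime(fq, 2, tmp_path / "o.fq")

    def test_nonpositive_target_rejected(self, tmp_path):
        with pytest.raises(InputError):
            trim_reads_3prime(tmp_path / "x.fq", 0, tmp_path / "y.fq")


def test_reference_filter_commutes_with_grouping(tmp_path):
    """Applying the reference filter before or after grouping yields the same
    multiplicities: simulate 'after' by filtering mappings of unfiltered sets."""
    header = ("@HD\tVN:1.6\tSO:unsorted\n"
              "@SQ\tSN:chr1\tLN:1000000\n@SQ\tSN:chrM\tLN:16000\n")
    lines = [sam_line("r1", 0, "chr1", 100, "50M"),
             sam_line("r1", 256, "chrM", 5, "50M"),
             sam_line("r2", 0, "chrM", 10, "50M"),
             sam_line("r3", 0, "chr1", 900, "50M"),
             sam_line("r3", 256, "chr1", 2000, "50M")]
    sam = write_sam(tmp_path / "a.sam", lines, header)
    before = {r.read_id: r.multiplicity
              for r in load_read_mappings(sam, CHIP_FILTERS)}
    after = {}
    for r in load_read_mappings(sam, NO_FILTERS):
        kept = [m for m in r.mappings if CHIP_FILTERS.keeps_reference(m.chrom)]
        if kept:
            after[r.read_id] = len(kept)
    assert before == after
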