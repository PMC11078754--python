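"""Gene counting strategies, the ambiguity rule, expression values and flags."""

import numpy as np
import pandas as pd
import pytest

from ambiquant.alignment import FragmentMappingSet, Mapping
from ambiquant.core import GeneModel, GenomicInterval, InputError
from ambiquant.gene_quant import (
    FragmentAssignments,
    build_exon_index,
    count_multimapper_aware,
    count_random_strategy,
    count_unique_only,
    expression_and_flags,
    overlapping_genes,
    top_n_protein_coding,
)


def gene(gene_id, start, end, exons=None, biotype="protein_coding"):
    exons = exons if exons is not None else [(start, end)]
    return GeneModel(
        gene_id=gene_id,
        span=GenomicInterval("chr1", start, end),
        exons=[GenomicInterval("chr1", s, e) for s, e in exons],
        biotype=biotype,
    )


def pair(pos1, pos2, read_len=50, chrom="chr1"):
    m1 = Mapping(GenomicInterval(chrom, pos1, pos1 + read_len),
                 ((pos1, pos1 + read_len),), read_len)
    m2 = Mapping(GenomicInterval(chrom, pos2, pos2 + read_len),
                 ((pos2, pos2 + read_len),), read_len)
    return (m1, m2)


def fragment(fid, pairs):
    return FragmentMappingSet(fid, pairs)


GENES = [
    gene("A", 1000, 3000),
    gene("B", 5000, 7000),
    # intron gene: two exons with an intronic hole
    gene("D", 10_000, 12_000, exons=[(10_000, 10_500), (11_500, 12_000)]),
]


class TestOverlappingGenes:
    def test_pair_within_one_gene(self):
        idx = build_exon_index(GENES)
        assert overlapping_genes(pair(1100, 1500), idx) == {"A"}

    def test_mates_in_different_genes_union(self):
        idx = build_exon_index(GENES)
        assert overlapping_genes(pair(1100, 5100), idx) == {"A", "B"}

    def test_intronic_pair_is_empty(self):
        idx = build_exon_index(GENES)
        assert overlapping_genes(pair(10_700, 10_900), idx) == set()

    def test_intergenic_pair_is_empty(self):
        idx = build_exon_index(GENES)
        assert overlapping_genes(pair(40_000, 40_200), idx) == set()

    def test_single_base_exon_overlap_counts(self):
        idx = build_exon_index(GENES)
        # block [951, 1001) overlaps exon [1000, 3000) by exactly one base
        assert overlapping_genes(pair(951, 30_000), idx) == {"A"}


class TestCountUniqueOnly:
    def test_unimapper_singleton_counts(self):
        h = count_unique_only([fragment("f1", [pair(1100, 1500)])], GENES)
        assert h["A"] == 1 and h["B"] == 0

    def test_ambiguous_unimapper_discarded(self):
        h = count_unique_only([fragment("f1", [pair(1100, 5100)])], GENES)
        assert (h == 0).all()

    def test_multimapper_contributes_nothing(self):
        frags = [fragment("f1", [pair(1100, 1500), pair(1200, 1600)])]
        h = count_unique_only(frags, GENES)
        assert (h == 0).all()


class TestCountMultimapperAware:
    def test_split_between_two_genes(self):
        frags = [fragment("f1", [pair(1100, 1500), pair(5100, 5500)])]
        c = count_multimapper_aware(frags, GENES)
        assert c["A"] == pytest.approx(0.5) and c["B"] == pytest.approx(0.5)

    def test_ambiguous_mapping_contributes_nothing(self):
        frags = [fragment("f1", [pair(1100, 1500), pair(1100, 5100)])]
        c = count_multimapper_aware(frags, GENES)
        assert c["A"] == pytest.approx(0.5) and c["B"] == 0.0

    def test_unimapper_equals_unique_contribution(self):
        frags = [fragment("f1", [pair(1100, 1500)])]
        c = count_multimapper_aware(frags, GENES)
        h = count_unique_only(frags, GENES)
        assert (c == h).all()

    def test_per_fragment_mass_in_unit_interval(self):
        frags = [
            fragment("f1", [pair(1100, 1500), pair(5100, 5500)]),    # mass 1
            fragment("f2", [pair(1100, 5100), pair(40_000, 40_200)]),  # mass 0
            fragment("f3", [pair(1100, 1500), pair(40_000, 40_200)]),  # mass 0.5
        ]
        a = FragmentAssignments(frags, GENES)
        for f in a.fragments:
            mass = sum(1.0 / f.multiplicity for g in f.assigned if g is not None)
            assert 0.0 <= mass <= 1.0


class TestCountRandomStrategy:
    def test_deterministic_under_seed(self):
        frags = [fragment("f1", [pair(1100, 1500), pair(5100, 5500)])]
        r1 = count_random_strategy(frags, GENES, seed=11)
        r2 = count_random_strategy(frags, GENES, seed=11)
        assert (r1 == r2).all()
        assert r1.sum() == 1

    def test_ambiguity_rule_still_applies(self):
        frags = [fragment("f1", [pair(1100, 5100), pair(1150, 5150)])]
        for seed in range(5):
            r = count_random_strategy(frags, GENES, seed=seed)
            assert (r == 0).all()

    def test_mean_over_seeds_approaches_fractional(self):
        """E[R] = C: the random strategy is unbiased for the fractional one."""
        frags = [fragment(f"f{i}", [pair(1100, 1500), pair(5100, 5500)])
                 for i in range(40)]
        a = FragmentAssignments(frags, GENES)
        c = a.fractional_counts()
        n_seeds = 2000
        acc = np.zeros(len(c))
        for seed in range(n_seeds):
            acc += a.random_counts(np.random.default_rng(seed)).to_numpy()
        mean = acc / n_seeds
        # each fragment is Bernoulli(0.5) for gene A: SE = sqrt(40*0.25/2000)
        se = np.sqrt(40 * 0.25) / np.sqrt(n_seeds)
        assert abs(mean[0] - c["A"]) < 4 * se
        assert abs(mean[1] - c["B"]) < 4 * se


class TestExpressionAndFlags:
    def make_table(self, h, c):
        genes = [gene("G", 0, 1000)]
        H = pd.Series({"G": h})
        C = pd.Series({"G": c})
        return expression_and_flags(genes, H, C)

    @pytest.mark.parametrize("h,c,expected", [
        (10, 25, True),    # ratio 2.5 > 2
        (10, 20, False),   # ratio exactly 2: strict inequality
        (0, 7, True),      # infinite ratio
        (0, 0, False),     # nothing observed
        (5, 5, False),
    ])
    def test_under_quantified_rule(self, h, c, expected):
        t = self.make_table(h, c)
        assert bool(t["under_quantified"].iloc[0]) is expected

    def test_expression_values_divide_by_span_length(self):
        t = self.make_table(10, 25)
        assert t["expr_H"].iloc[0] == pytest.approx(0.01)
        assert t["expr_C"].iloc[0] == pytest.approx(0.025)

    def test_expressed_iff_fractional_count_positive(self):
        assert bool(self.make_table(0, 0.25)["expressed"].iloc[0]) is True
        assert bool(self.make_table(0, 0)["expressed"].iloc[0]) is False

    def test_rounding_half_up_at_export(self):
        t = self.make_table(0, 2.5)
        assert t["C_rounded"].iloc[0] == 3

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            self.make_table(-1, 0)


class TestTopNProteinCoding:
    def table(self):
        genes = [gene("g1", 0, 1000), gene("g2", 0, 1000), gene("g3", 0, 1000),
                 gene("rna1", 0, 1000, biotype="lncRNA")]
        H = pd.Series({"g1": 5, "g2": 2, "g3": 9, "rna1": 100})
        C = pd.Series({"g1": 5, "g2": 2, "g3": 9, "rna1": 100})
        return expression_and_flags(genes, H, C)

    def test_ranked_descending_and_filtered(self):
        top = top_n_protein_coding(self.table(), 2, "expr_C")
        assert list(top["gene_id"]) == ["g3", "g1"]

    def test_tie_break_lexicographic(self):
        genes = [gene("zz", 0, 1000), gene("aa", 0, 1000), gene("mm", 0, 1000)]
        counts = pd.Series({"zz": 5, "aa": 5, "mm": 5})
        t = expression_and_flags(genes, counts, counts)
        top = top_n_protein_coding(t, 2, "expr_C")
        assert list(top["gene_id"]) == ["aa", "mm"]

    def test_fewer_than_n_returns_all_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="ambiquant.gene_quant"):
            top = top_n_protein_coding(self.table(), 50, "expr_C")
        assert len(top) == 3
        assert any("50" in r.message for r in caplog.records)

    def test_invalid_ranking_column_rejected(self):
        with pytest.raises(InputError):
            top_n_protein_coding(self.table(), 2, "H")


class TestMonotonicityAndConservation:
    def test_fractional_dominates_unique_on_paralog_fixture(self, paralog_bundle):
        from ambiquant.alignment import load_fragment_mappings
        from ambiquant.annotation import parse_gene_models

        b = paralog_bundle
        genes = parse_gene_models(b.paths["gtf"])
        frags = list(load_fragment_mappings(b.paths["sam"]))
        a = FragmentAssignments(frags, genes)
        H, C = a.unique_counts(), a.fractional_counts()
        assert (C >= H).all()
        assert H.sum() <= C.sum() <= len(frags)

    def test_nested_genes_count_to_none(self):
        """A gene nested inside another makes all its reads ambiguous; both
        strategies agree and C >= H still holds."""
        genes = [gene("outer", 0, 10_000), gene("inner", 4000, 5000)]
        frags = [fragment("f1", [pair(4200, 4400)]),          # S = {outer, inner}
                 fragment("f2", [pair(100, 300)]),            # S = {outer}
                 fragment("f3", [pair(4200, 4400), pair(100, 300)])]
        a = FragmentAssignments(frags, genes)
        H, C = a.unique_counts(), a.fractional_counts()
        assert H["outer"] == 1 and H["inner"] == 0
        assert C["outer"] == pytest.approx(1.5) and C["inner"] == 0
        assert (C >= H).all()

    def test_paralog_top_lists_differ_only_by_paralogs(self, paralog_bundle):
        """Genes present in the C-ranked top-N but absent from the H-ranked
        one are exactly members of the designed paralog family."""
        from ambiquant.alignment import load_fragment_mappings
        from ambiquant.annotation import parse_gene_models

        b = paralog_bundle
        genes = parse_gene_models(b.paths["gtf"])
        frags = list(load_fragment_mappings(b.paths["sam"]))
        a = FragmentAssignments(frags, genes)
        t = expression_and_flags(genes, a.unique_counts(), a.fractional_counts())
        top_h = set(top_n_protein_coding(t, 4, "expr_H")["gene_id"])
        top_c = set(top_n_protein_coding(t, 4, "expr_C")["gene_id"])
        c_only = top_c - top_h
        assert c_only  # the rankings genuinely differ at the top
        assert all(g.startswith("PARA") for g in c_only)
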