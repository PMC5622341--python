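import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regrank import expression as expr
from regrank.model import ExpressionRecord, GeneModel, Summit


def record(gene_id, fpkms, p=0.01, length=500):
    return ExpressionRecord(gene_id, dict(fpkms), p, length)


class TestDeFilter:
    def test_boundaries_are_strict(self):
        recs = [
            record("p_at_cut", {"s1": 50}, p=0.05),
            record("len_at_cut", {"s1": 50}, p=0.01, length=200),
            record("fpkm_at_cut", {"s1": 10.0}, p=0.01),
            record("passes", {"s1": 10.5, "s2": 1.0}, p=0.01, length=201),
        ]
        assert expr.de_filter(recs) == ["passes"]

    def test_matches_predicate_oracle_on_random_table(self):
        rng = np.random.default_rng(0)
        recs = []
        for i in range(500):
            recs.append(
                record(
                    f"g{i}",
                    {"a": rng.uniform(0, 30), "b": rng.uniform(0, 30)},
                    p=float(rng.uniform(0, 0.2)),
                    length=int(rng.integers(50, 600)),
                )
            )
        got = set(expr.de_filter(recs))
        expected = {
            r.gene_id
            for r in recs
            if r.p_value < 0.05
            and r.transcript_length > 200
            and max(r.fpkm_by_sample.values()) > 10
        }
        assert got == expected

    @given(
        st.floats(0.01, 0.2), st.integers(100, 400), st.floats(1.0, 20.0)
    )
    @settings(max_examples=50, deadline=None)
    def test_relaxing_thresholds_is_monotone(self, p_max, min_len, min_fpkm):
        rng = np.random.default_rng(42)
        recs = [
            record(
                f"g{i}",
                {"a": float(rng.uniform(0, 30))},
                p=float(rng.uniform(0, 0.2)),
                length=int(rng.integers(50, 600)),
            )
            for i in range(100)
        ]
        tight = set(expr.de_filter(recs, p_max=p_max, min_length=min_len, min_fpkm=min_fpkm))
        loose = set(
            expr.de_filter(
                recs, p_max=p_max * 1.5, min_length=int(min_len * 0.8), min_fpkm=min_fpkm * 0.8
            )
        )
        assert tight <= loose


class TestNearestGene:
    GENES = [
        GeneModel("left", "chr1", 1000, 2000, "+"),
        GeneModel("right", "chr1", 4000, 5000, "+"),
        GeneModel("other", "chr2", 100, 900, "-"),
    ]

    def test_containment_wins(self):
        link = expr.nearest_gene(Summit("chr1", 1500), self.GENES)
        assert (link.gene_id, link.link_rule, link.distance) == ("left", "contains_peak", 0)

    def test_equidistant_tie_goes_upstream(self):
        # summit at 2499: left ends at 1999 (distance 500), right starts 4000...
        # craft a true tie: distance to left boundary == distance to right
        summit = Summit("chr1", 2999)  # left: 2999-1999=1000; right: 4000-2999=1001
        link = expr.nearest_gene(summit, self.GENES)
        assert link.gene_id == "left"
        tie = Summit("chr1", 2999)
        genes = [
            GeneModel("up", "chr1", 1000, 2500, "+"),
            GeneModel("down", "chr1", 3500, 4000, "+"),
        ]
        # distances: 2999-2499=500 and 3500-2999=501 -> up; shift to exact tie
        genes2 = [
            GeneModel("up", "chr1", 1000, 2500, "+"),
            GeneModel("down", "chr1", 3499, 4000, "+"),
        ]
        assert expr.nearest_gene(tie, genes2).gene_id == "up"
        assert expr.nearest_gene(tie, genes2).link_rule == "nearest_5prime"

    def test_no_gene_on_chromosome_flagged(self):
        link = expr.nearest_gene(Summit("chrX", 100), self.GENES)
        assert link.gene_id is None and link.link_rule == "none"

    def test_matches_bruteforce_minimisation(self):
        rng = np.random.default_rng(1)
        genes = []
        for i in range(30):
            start = int(rng.integers(0, 90_000))
            genes.append(
                GeneModel(f"g{i}", "chr1", start, start + int(rng.integers(200, 3000)),
                          rng.choice(["+", "-"]))
            )
        for pos in rng.integers(0, 95_000, size=100):
            link = expr.nearest_gene(Summit("chr1", int(pos)), genes)
            containing = [g for g in genes if g.start <= pos < g.end]
            if containing:
                best = min(containing, key=lambda g: (g.end - g.start, g.start, g.gene_id))
                assert link.gene_id == best.gene_id and link.distance == 0
            else:
                dmin = min(
                    g.start - pos if pos < g.start else pos - (g.end - 1) for g in genes
                )
                assert link.distance == dmin

    def test_translation_invariance(self):
        shift = 7919
        genes_shifted = [
            GeneModel(g.gene_id, g.chrom, g.start + shift, g.end + shift, g.strand)
            for g in self.GENES
        ]
        for pos in (1200, 2999, 4500, 6000):
            a = expr.nearest_gene(Summit("chr1", pos), self.GENES)
            b = expr.nearest_gene(Summit("chr1", pos + shift), genes_shifted)
            assert (a.gene_id, a.link_rule, a.distance) == (b.gene_id, b.link_rule, b.distance)


class TestFoldChangeTables:
    def two_tables(self, pairs):
        a = [record(g, {"WT_rep1": va}) for g, va, _ in pairs]
        b = [record(g, {"KO_rep1": vb}) for g, _, vb in pairs]
        return a, b

    def test_equal_fpkm_gives_zero_column(self):
        from regrank.model import GenomicInterval, PeakSet, GeneLink

        ps = PeakSet(
            "X",
            [GenomicInterval("chr1", 0, 10)],
            [Summit("chr1", 5)],
            signal=np.array([3.0]),
        )
        links = [expr.GeneLink("chr1:5", "g1", "nearest_3prime", 10)]
        table = expr.fc_by_rank_table(
            ps, links,
            {"S": [record("g1", {"WT_rep1": 7.0, "KO_rep1": 7.0})]},
            "WT", "KO", pseudocount=0.0,
        )
        assert table["log2fc_S"].iloc[0] == 0.0

    def test_analytic_ratio_without_pseudocount(self):
        from regrank.model import GenomicInterval, PeakSet

        ps = PeakSet("X", [GenomicInterval("chr1", 0, 10)], [Summit("chr1", 5)])
        links = [expr.GeneLink("chr1:5", "g1", "nearest_3prime", 10)]
        table = expr.fc_by_rank_table(
            ps, links,
            {"S": [record("g1", {"WT_rep1": 8.0, "KO_rep1": 2.0})]},
            "WT", "KO", pseudocount=0.0,
        )
        assert table["log2fc_S"].iloc[0] == 2.0

    def test_direction_all_higher_in_x(self):
        a, b = self.two_tables([("g1", 5, 1), ("g2", 9, 2)])
        res = expr.direction_fraction(["g1", "g2"], a, b)
        assert res["fraction_x_higher"] == 1.0

    def test_direction_antisymmetric_under_swap(self):
        rng = np.random.default_rng(2)
        pairs = [(f"g{i}", float(rng.uniform(0, 10)), float(rng.uniform(0, 10)))
                 for i in range(50)]
        a, b = self.two_tables(pairs)
        genes = [g for g, _, _ in pairs]
        fwd = expr.direction_fraction(genes, a, b)
        rev = expr.direction_fraction(genes, b, a)
        assert fwd["fraction_x_higher"] == rev["fraction_y_higher"]
        assert fwd["fraction_tied"] == rev["fraction_tied"]

    def test_direction_matches_tally(self):
        rng = np.random.default_rng(3)
        pairs = [(f"g{i}", float(rng.integers(0, 5)), float(rng.integers(0, 5)))
                 for i in range(50)]
        a, b = self.two_tables(pairs)
        genes = [g for g, _, _ in pairs]
        res = expr.direction_fraction(genes, a, b)
        n_x = sum(va > vb for _, va, vb in pairs)
        n_tie = sum(va == vb for _, va, vb in pairs)
        assert res["fraction_x_higher"] == n_x / 50
        assert res["fraction_tied"] == n_tie / 50

    def test_empty_gene_list_rejected(self):
        a, b = self.two_tables([("g1", 1, 1)])
        with pytest.raises(ValueError):
            expr.direction_fraction([], a, b)

    def test_fourfold_boundary_counts_neither(self):
        a, b = self.two_tables([("g1", 4.0, 1.0)])
        res = expr.fold_change_tally(["g1"], a, b, fold=4, pseudocount=0.0)
        assert res == {"n_up": 0, "n_down": 0, "n": 1}

    def test_all_eightfold_count_up(self):
        pairs = [(f"g{i}", 8.0, 1.0) for i in range(10)]
        a, b = self.two_tables(pairs)
        res = expr.fold_change_tally([g for g, _, _ in pairs], a, b, pseudocount=0.0)
        assert res == {"n_up": 10, "n_down": 0, "n": 10}

    def test_tally_matches_predicate_oracle(self):
        rng = np.random.default_rng(4)
        pairs = [(f"g{i}", float(rng.uniform(0, 20)), float(rng.uniform(0, 20)))
                 for i in range(80)]
        a, b = self.two_tables(pairs)
        pc = 0.1
        res = expr.fold_change_tally([g for g, _, _ in pairs], a, b, pseudocount=pc)
        assert res["n_up"] == sum(va / (vb + pc) > 4 for _, va, vb in pairs)
        assert res["n_down"] == sum(vb / (va + pc) > 4 for _, va, vb in pairs)
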