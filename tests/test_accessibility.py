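import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from regrank import accessibility as acc
from regrank.model import Summit, TagTrack


def brute_count(track, chrom, center, halfwidth):
    vec = track[chrom]
    return sum(
        int(vec[p])
        for p in range(center - halfwidth, center + halfwidth + 1)
        if 0 <= p < len(vec)
    )


class TestCountTags:
    def test_empty_track(self):
        track = TagTrack.zeros({"chr1": 1000})
        assert acc.count_tags(track, "chr1", 500, 100) == 0

    def test_single_tag_at_center(self):
        vec = np.zeros(1000, dtype=int)
        vec[500] = 1
        track = TagTrack({"chr1": vec})
        assert acc.count_tags(track, "chr1", 500, 100) == 1

    def test_window_inclusive_on_both_ends(self):
        vec = np.zeros(1000, dtype=int)
        vec[400] = 1
        vec[600] = 1
        vec[399] = 5
        vec[601] = 5
        track = TagTrack({"chr1": vec})
        assert acc.count_tags(track, "chr1", 500, 100) == 2

    def test_matches_bruteforce_on_random_tracks(self):
        rng = np.random.default_rng(0)
        vec = np.zeros(500, dtype=int)
        for _ in range(50):
            vec[rng.integers(0, 500)] += 1
        track = TagTrack({"chr1": vec})
        for _ in range(25):
            center = int(rng.integers(0, 500))
            h = int(rng.integers(0, 60))
            assert acc.count_tags(track, "chr1", center, h) == brute_count(
                track, "chr1", center, h
            )

    def test_unknown_chromosome_rejected(self):
        track = TagTrack.zeros({"chr1": 100})
        with pytest.raises(KeyError):
            acc.count_tags(track, "chrX", 10, 5)


def brute_merge(summits, merge_distance, counts):
    """O(n^2) reference: repeatedly collapse the closest pair within range."""
    current = list(summits)
    while True:
        best = None
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                a, b = current[i], current[j]
                if a.chrom == b.chrom and abs(a.pos - b.pos) <= merge_distance:
                    d = abs(a.pos - b.pos)
                    if best is None or d < best[0]:
                        best = (d, i, j)
        if best is None:
            return current
        _, i, j = best
        a, b = current[i], current[j]
        keep = max([a, b], key=lambda s: (counts.get((s.chrom, s.pos), 0), -s.pos))
        current = [s for k, s in enumerate(current) if k not in (i, j)] + [keep]


class TestSummitUnion:
    def test_empty_side_is_identity(self):
        b = [Summit("chr1", 10), Summit("chr1", 500)]
        assert acc.build_summit_union([], b) == b

    def test_disjoint_concatenation_counts(self):
        a = [Summit("chr1", p) for p in (10, 1000, 2000)]
        b = [Summit("chr2", p) for p in (10, 1000, 2000, 3000)]
        assert len(acc.build_summit_union(a, b, merge_distance=0)) == 7

    def test_merge_matches_pairwise_oracle(self):
        vec = np.zeros(5000, dtype=int)
        for pos, c in [(100, 5), (250, 9), (1000, 3), (1120, 7), (3000, 2)]:
            vec[pos] = c
        track = TagTrack({"chr1": vec})
        counts = {("chr1", p): int(vec[p]) for p in (100, 250, 1000, 1120, 3000)}
        a = [Summit("chr1", 100), Summit("chr1", 1000), Summit("chr1", 3000)]
        b = [Summit("chr1", 250), Summit("chr1", 1120)]
        got = acc.build_summit_union(a, b, merge_distance=200, track=track, halfwidth=0)
        expected = brute_merge(a + b, 200, counts)
        assert sorted((s.chrom, s.pos) for s in got) == sorted(
            (s.chrom, s.pos) for s in expected
        )


class TestRankSites:
    def make_tracks(self, n=400):
        vec = np.zeros(n, dtype=int)
        return TagTrack({"chr1": vec.copy()}), TagTrack({"chr1": vec.copy()})

    def test_equal_counts_give_zero_fc_in_coordinate_order(self):
        ta, tb = self.make_tracks()
        ta["chr1"][:] = 1
        tb["chr1"][:] = 1
        union = [Summit("chr1", p) for p in (300, 100, 200)]
        table = acc.rank_sites(union, ta, tb, halfwidth=10, normalize=False)
        assert (table["log2fc"] == 0).all()
        assert table["pos"].tolist() == [100, 200, 300]

    def test_analytic_fold_change(self):
        # counts A=31, B=7, pseudocount 1, no normalisation: log2(8/32) = -2
        ta, tb = self.make_tracks()
        ta["chr1"][100] = 31
        tb["chr1"][100] = 7
        table = acc.rank_sites([Summit("chr1", 100)], ta, tb, normalize=False)
        assert table["log2fc"].iloc[0] == -2.0

    def test_planted_classes_separate_in_rank(self, study, ranked_table):
        """A-specific truth sites must rank far above B-specific ones
        (one-sided Mann-Whitney on rank positions)."""
        truth = {(s.chrom, s.pos): s.class_truth for s in study.sites}
        ranks_a, ranks_b = [], []
        for _, row in ranked_table.iterrows():
            cls = truth.get((row["chrom"], row["pos"]))
            if cls == "A_specific":
                ranks_a.append(row["rank"])
            elif cls == "B_specific":
                ranks_b.append(row["rank"])
        res = stats.mannwhitneyu(ranks_a, ranks_b, alternative="less")
        assert res.pvalue < 1e-6

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(3)
        vec_a = rng.integers(0, 30, size=2000)
        vec_b = rng.integers(0, 30, size=2000)
        ta, tb = TagTrack({"chr1": vec_a}), TagTrack({"chr1": vec_b})
        union = [Summit("chr1", int(p)) for p in rng.integers(50, 1950, size=40)]
        fwd = acc.rank_sites(union, ta, tb, halfwidth=20, normalize=False)
        rev = acc.rank_sites(union, tb, ta, halfwidth=20, normalize=False)
        merged = fwd.merge(rev, on=["chrom", "pos"], suffixes=("_f", "_r"))
        assert np.allclose(merged["log2fc_f"], -merged["log2fc_r"])
        distinct = fwd["log2fc"].nunique() == len(fwd)
        if distinct:
            assert fwd.sort_values("rank")["pos"].tolist() == list(
                reversed(rev.sort_values("rank")["pos"].tolist())
            )


class TestClassify:
    def table(self, fcs):
        return pd.DataFrame(
            {"chrom": "chr1", "pos": range(len(fcs)), "log2fc": fcs}
        )

    def test_sign_and_magnitude_rules(self):
        out = acc.classify_sites(self.table([-1.5, 1.5, 0.5]))
        assert out["class_label"].tolist() == ["A_enriched", "B_enriched", "shared"]

    def test_exact_threshold_is_shared(self):
        out = acc.classify_sites(self.table([-1.0, 1.0]))
        assert out["class_label"].tolist() == ["shared", "shared"]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            acc.classify_sites(self.table([0.0]), log2_threshold=-1)

    @given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_classes_partition_every_input(self, fcs):
        out = acc.classify_sites(self.table(fcs))
        counts = acc.class_counts(out)
        assert sum(counts.values()) == len(fcs)

    def test_counts_invariant_under_common_depth_scaling(self):
        rng = np.random.default_rng(5)
        vec_a = rng.integers(0, 20, size=1000)
        vec_b = rng.integers(0, 20, size=1000)
        union = [Summit("chr1", int(p)) for p in rng.integers(50, 950, size=30)]
        base = acc.class_counts(
            acc.classify_sites(
                acc.rank_sites(
                    [*union], TagTrack({"chr1": vec_a}), TagTrack({"chr1": vec_b}),
                    halfwidth=20,
                )
            )
        )
        scaled = acc.class_counts(
            acc.classify_sites(
                acc.rank_sites(
                    [*union], TagTrack({"chr1": vec_a * 3}), TagTrack({"chr1": vec_b * 3}),
                    halfwidth=20,
                )
            )
        )
        assert base == scaled


class TestWindowMatrix:
    def test_empty_track_shape(self):
        track = TagTrack.zeros({"chr1": 5000})
        mat = acc.window_matrix(track, [("chr1", 2000), ("chr1", 3000)])
        assert mat.shape == (2, 200) and not mat.any()

    def test_delta_tag_lands_in_central_bin(self):
        vec = np.zeros(5000, dtype=int)
        vec[2000] = 1
        mat = acc.window_matrix(TagTrack({"chr1": vec}), [("chr1", 2000)])
        assert mat.sum() == 1 and mat[0, 100] == 1

    def test_row_sums_match_count_oracle(self):
        rng = np.random.default_rng(1)
        vec = rng.integers(0, 5, size=10_000)
        track = TagTrack({"chr1": vec})
        centers = [("chr1", int(p)) for p in rng.integers(1500, 8500, size=10)]
        mat = acc.window_matrix(track, centers, halfwidth=1000, binsize=10)
        for row, (chrom, pos) in zip(mat, centers):
            assert row.sum() == int(vec[pos - 1000 : pos + 1000].sum())
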