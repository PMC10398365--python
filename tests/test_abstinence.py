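import numpy as np
import pytest

import cessalex.abstinence as ab
from cessalex import BinnedEmotionTable
from tests.conftest import make_corpus


@pytest.fixture(scope="module")
def bins():
    return ab.default_bins()


def random_normalized_table(lexicon, seed, n_min=50, n_max=500):
    """A 15-bin table of multinomial counts with per-bin percentages."""
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(lexicon.K))
    counts = np.vstack([rng.multinomial(rng.integers(n_min, n_max), p)
                        for _ in range(15)])
    counts[counts.sum(axis=1) == 0, 0] = 1   # ensure no empty bin
    pct = 100.0 * counts / counts.sum(axis=1, keepdims=True)
    return BinnedEmotionTable("synth", lexicon.name, lexicon.category_names,
                              counts, pct, counts.sum(axis=1))


class TestBins:
    def test_default_structure(self, bins):
        assert len(bins.edges) == 16
        assert bins.edges[0] == 0.0
        assert bins.edges[1] == 1.0
        assert bins.edges[9] == 100.0
        assert bins.edges[-1] == 1000.0
        assert len(bins.short_bins) == 9 and len(bins.long_bins) == 6

    @pytest.mark.parametrize("day, expected", [
        (0.0, 0), (0.5, 0), (1.0, 1),       # day-0 bin is [0, 1)
        (99.9, 8), (100.0, 9),              # short/long boundary at 100
        (1000.0, 14),                       # cutoff day included, last bin
    ])
    def test_assignment(self, bins, day, expected):
        assert bins.assign(day) == expected

    def test_beyond_cutoff_excluded(self, bins):
        assert bins.assign(1001.0) is None

    def test_short_bins_below_100_long_at_or_above(self, bins):
        for b in bins.short_bins:
            assert bins.edges[b + 1] <= 100.0
        for b in bins.long_bins:
            assert bins.edges[b] >= 100.0

    def test_invalid_edges_rejected(self):
        with pytest.raises(ab.AbstinenceError):
            ab.AbstinenceBins(tuple(float(i) for i in range(16)))


class TestTagFiltering:
    def test_keeps_most_recent_tagged_text_posts(self):
        corpus = make_corpus([f"b{i}" for i in range(20)],
                             abstinence=list(range(20)))
        kept = ab.filter_abstinence_tagged(corpus.posts, 5)
        assert len(kept) == 5
        assert [p.body for p in kept] == [f"b{i}" for i in range(5)]

    def test_untagged_and_imageonly_excluded(self):
        corpus = make_corpus(["a", "", "c"], abstinence=[1.0, 2.0, None])
        kept = ab.filter_abstinence_tagged(corpus.posts, 10)
        assert [p.body for p in kept] == ["a"]

    def test_no_tagged_posts_warns_empty(self):
        corpus = make_corpus(["a", "b"])
        with pytest.warns(UserWarning):
            assert ab.filter_abstinence_tagged(corpus.posts, 5) == []

    def test_exactly_n_keep_unchanged(self):
        corpus = make_corpus(["a", "b"], abstinence=[1.0, 2.0])
        assert len(ab.filter_abstinence_tagged(corpus.posts, 2)) == 2


class TestFirstDay:
    def test_fraction(self):
        days = [0.5] * 7 + [5.0] * 93
        corpus = make_corpus(["x"] * 100, abstinence=days)
        assert ab.first_day_fraction(corpus.posts) == pytest.approx(7.0)

    @pytest.mark.parametrize("days, expected", [
        ([2.0, 3.0], 0.0), ([0.1, 0.9], 100.0)])
    def test_fraction_extremes(self, days, expected):
        corpus = make_corpus(["x"] * len(days), abstinence=days)
        assert ab.first_day_fraction(corpus.posts) == expected

    @pytest.mark.parametrize("range_days, expected", [
        (10000, 0.01), (100, 1.0), (1, 100.0)])
    def test_uniform_chance(self, range_days, expected):
        assert ab.uniform_chance_first_day(range_days) == expected

    def test_uniform_chance_rejects_below_one(self):
        with pytest.raises(ab.AbstinenceError):
            ab.uniform_chance_first_day(0.5)

    def test_profile_restricted_to_day0(self, tiny_lexicon):
        corpus = make_corpus(["anxious happy", "proud proud"],
                             abstinence=[0.2, 50.0])
        prof, top = ab.first_day_profile(corpus.posts, tiny_lexicon, 2)
        assert prof.frequencies["pride"] == 0.0
        assert {c for c, _ in top} == {"anxiety", "joy"}

    def test_single_match_gives_100(self, tiny_lexicon):
        corpus = make_corpus(["proud"], abstinence=[0.0])
        prof, top = ab.first_day_profile(corpus.posts, tiny_lexicon, 1)
        assert prof.frequencies["pride"] == 100.0
        assert top == [("pride", 100.0)]

    def test_dominant_categories_recovered(self, emotion_lexicon):
        # day-0 posts drawn with anxiety=0.3, optimism=0.25 dominant
        import cessalex.synthdata as sd
        names = emotion_lexicon.category_names
        p = np.full(21, 0.45 / 19)
        p[names.index("anxiety")] = 0.30
        p[names.index("optimism")] = 0.25
        spec = sd.ForumSpec(
            "f", 600, dict(zip(names, p)), emotion_rate=0.5,
            post_length_mean=20, image_only_frac=0.0,
            abstinence=sd.AbstinenceSpec(day0_mass=1.0, post100_shift={}))
        corpus, truth = sd.generate_corpus(spec, 9, emotion_lexicon)
        assert truth.n_emotion_tokens >= 5000
        _, top = ab.first_day_profile(corpus.posts, emotion_lexicon, 2)
        assert {c for c, _ in top} == {"anxiety", "optimism"}


class TestBinnedTable:
    def test_percentages_sum_to_100_per_nonempty_bin(self, emotion_lexicon,
                                                     bins):
        rng = np.random.default_rng(0)
        days = list(rng.uniform(0, 1200, 400))
        bodies = ["anxious proud grateful disgusting"] * 400
        corpus = make_corpus(bodies, abstinence=days)
        table = ab.bin_posts(corpus.posts, emotion_lexicon, bins)
        sums = table.percentages.sum(axis=1)
        nonempty = table.counts.sum(axis=1) > 0
        assert np.allclose(sums[nonempty], 100.0, atol=1e-9)

    def test_beyond_cutoff_posts_excluded(self, emotion_lexicon, bins):
        corpus = make_corpus(["anxious", "proud"],
                             abstinence=[1001.0, 5.0])
        table = ab.bin_posts(corpus.posts, emotion_lexicon, bins)
        assert table.counts.sum() == 1
        assert table.n_posts.sum() == 1


class TestAnova:
    def test_df_arithmetic(self, emotion_lexicon, bins):
        table = random_normalized_table(emotion_lexicon, 1)
        res = ab.two_way_anova(table, bins)
        assert res.emotion.df_num == 20
        assert res.abstinence.df_num == 1
        assert res.interaction.df_num == 20
        assert res.emotion.df_den == 21 * 15 - 42

    def test_abstinence_main_effect_forced_zero(self, emotion_lexicon,
                                                bins):
        # each bin's percentages sum to 100, so both level means are
        # pinned at 100/K and the abstinence main effect vanishes
        for seed in range(5):
            table = random_normalized_table(emotion_lexicon, seed)
            res = ab.two_way_anova(table, bins)
            assert abs(res.abstinence.F) < 1e-8
            assert res.abstinence.p > 0.999

    def test_all_equal_cells_give_zero_F(self, emotion_lexicon, bins):
        counts = np.full((15, 21), 10)
        pct = np.full((15, 21), 100 / 21)
        table = BinnedEmotionTable("c", emotion_lexicon.name,
                                   emotion_lexicon.category_names,
                                   counts, pct, counts.sum(axis=1))
        res = ab.two_way_anova(table, bins)
        assert res.emotion.F == pytest.approx(0.0, abs=1e-8)
        assert res.interaction.F == pytest.approx(0.0, abs=1e-8)

    def test_bin_relabelling_within_level_invariance(self, emotion_lexicon,
                                                     bins):
        table = random_normalized_table(emotion_lexicon, 7)
        perm = np.r_[np.random.default_rng(0).permutation(9),
                     9 + np.random.default_rng(1).permutation(6)]
        shuffled = BinnedEmotionTable(
            table.forum, table.lexicon_name, table.categories,
            table.counts[perm], table.percentages[perm],
            table.n_posts[perm])
        a = ab.two_way_anova(table, bins)
        b = ab.two_way_anova(shuffled, bins)
        assert a.interaction.F == pytest.approx(b.interaction.F, rel=1e-9)

    def test_interaction_detects_level_shift(self, emotion_lexicon, bins):
        # shift one emotion's share up by 10 points in the long bins,
        # compensated across the others; the interaction F must clearly
        # exceed the permutation null at alpha = .05
        rng = np.random.default_rng(11)
        pct = np.full((15, 21), 100 / 21)
        pct[9:, 0] += 10.0
        pct[9:, 1:] -= 10.0 / 20
        pct += rng.normal(0, 0.3, pct.shape)
        pct = 100 * pct / pct.sum(axis=1, keepdims=True)
        counts = np.round(pct * 10).astype(int)
        table = BinnedEmotionTable("s", emotion_lexicon.name,
                                   emotion_lexicon.category_names,
                                   counts, pct, counts.sum(axis=1))
        obs = ab.two_way_anova(table, bins).interaction.F
        null_F = []
        for i in range(99):
            perm = rng.permutation(15)
            t2 = BinnedEmotionTable("s", table.lexicon_name,
                                    table.categories, counts[perm],
                                    pct[perm], table.n_posts[perm])
            null_F.append(ab.two_way_anova(t2, bins).interaction.F)
        assert obs > np.quantile(null_F, 0.95)

    def test_empty_bin_errors_with_bin_name(self, emotion_lexicon, bins):
        table = random_normalized_table(emotion_lexicon, 2)
        counts = table.counts.copy()
        counts[3] = 0
        bad = BinnedEmotionTable(table.forum, table.lexicon_name,
                                 table.categories, counts,
                                 table.percentages, table.n_posts)
        with pytest.raises(ab.AbstinenceError, match="3"):
            ab.two_way_anova(bad, bins)


class TestPosthoc:
    def _table(self, lexicon, pct_matrix):
        counts = np.maximum(np.round(pct_matrix * 10).astype(int), 0)
        return BinnedEmotionTable("f", lexicon.name, lexicon.category_names,
                                  np.asarray(counts), np.asarray(pct_matrix),
                                  np.full(len(pct_matrix), 100))

    def test_hand_computed_pooled_t(self):
        # toy 3-vs-3: short {5,6,7}, long {1,2,3} -> t = 4.899, df = 4
        from scipy import stats
        res = stats.ttest_ind([5, 6, 7], [1, 2, 3], equal_var=True)
        assert res.statistic == pytest.approx(4.899, abs=1e-3)
        assert res.df == 4

    def test_pooled_df_is_13(self, emotion_lexicon, bins):
        table = random_normalized_table(emotion_lexicon, 3)
        tts = ab.posthoc_ttests(table, bins, ["anxiety"])
        assert tts[0].df == 13

    def test_identical_groups_give_t0_p1(self, emotion_lexicon, bins):
        pct = np.tile(np.full(21, 100 / 21), (15, 1))
        table = self._table(emotion_lexicon, pct)
        tts = ab.posthoc_ttests(table, bins, ["anxiety", "pride"])
        for tt in tts:
            assert tt.t == 0.0 and tt.p == 1.0 and not tt.significant

    def test_bonferroni_threshold(self, emotion_lexicon, bins):
        table = random_normalized_table(emotion_lexicon, 4)
        tts = ab.posthoc_ttests(table, bins,
                                ["anxiety", "disgust", "pride", "gratitude"],
                                alpha=0.05)
        for tt in tts:
            assert tt.alpha_adjusted == pytest.approx(0.0125)

    def test_welch_option(self, emotion_lexicon, bins):
        table = random_normalized_table(emotion_lexicon, 5)
        tts = ab.posthoc_ttests(table, bins, ["anxiety"], method="welch")
        assert tts[0].method == "welch"
        assert tts[0].df != 13   # Welch df is data-dependent

    def test_unknown_emotion_errors(self, emotion_lexicon, bins):
        table = random_normalized_table(emotion_lexicon, 6)
        with pytest.raises(ab.AbstinenceError):
            ab.posthoc_ttests(table, bins, ["nostalgia"])
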