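"""N-gram counting, probability measures, transforms, Zipf curves.

Counting and the conditional-probability conventions are checked against
independent brute-force recounts on random toy corpora.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from syllastats.ngram_stats import (
    FrequencyTable,
    conditional_probabilities,
    count_ngrams,
    probability_measures,
    rank_frequency,
    smooth_add_one,
    spearman_rho,
    top_ngram_report,
    transform_predictors,
    unigram_probability,
)

from conftest import build_corpus, random_toy_corpus


def brute_force_counts(corpus, n):
    """Sliding-window recount over breathgroups, independent of count_ngrams."""
    counts = {}
    groups = {}
    for tok in corpus.tokens:
        groups.setdefault((tok.recording_id, tok.breathgroup_index), []).append(
            (tok.position_in_breathgroup, tok.label)
        )
    for key in groups:
        labels = [lab for _, lab in sorted(groups[key])]
        for i in range(len(labels) - n + 1):
            gram = tuple(labels[i : i + n])
            counts[gram] = counts.get(gram, 0) + 1
    return counts


def brute_force_measures(corpus, mode="literal"):
    """Per-token probability measures straight from the formulas."""
    uni = brute_force_counts(corpus, 1)
    bi = brute_force_counts(corpus, 2)
    utot = sum(uni.values())
    btot = sum(bi.values())
    out = []
    for group in corpus.breathgroups():
        labels = [t.label for t in group]
        for i, cur in enumerate(labels):
            prev = labels[i - 1] if i > 0 else None
            nxt = labels[i + 1] if i < len(labels) - 1 else None
            row = {"p_s0": uni[(cur,)] / utot}

            def joint(a, b):
                return bi.get((a, b), 0) / btot if btot else math.nan

            def marg(a):
                return uni[(a,)] / utot

            if mode == "literal":
                row["p_s0_given_prev"] = joint(prev, cur) / marg(prev) if prev else math.nan
                row["p_s0_given_next"] = joint(cur, nxt) / marg(nxt) if nxt else math.nan
                row["p_next_given_s0"] = joint(cur, nxt) / marg(cur) if nxt else math.nan
            else:
                row["p_s0_given_prev"] = bi.get((prev, cur), 0) / uni[(prev,)] if prev else math.nan
                row["p_s0_given_next"] = bi.get((cur, nxt), 0) / uni[(nxt,)] if nxt else math.nan
                row["p_next_given_s0"] = bi.get((cur, nxt), 0) / uni[(cur,)] if nxt else math.nan
            out.append(row)
    return out


class TestCounting:
    def test_no_cross_breathgroup_ngrams(self):
        corpus = build_corpus({"r": [["na", "na", "ra"], ["na"]]})
        uni = count_ngrams(corpus, 1)
        bi = count_ngrams(corpus, 2)
        assert uni.counts == {("na",): 3, ("ra",): 1}
        assert bi.counts == {("na", "na"): 1, ("na", "ra"): 1}

    def test_cross_breathgroup_option(self):
        corpus = build_corpus({"r": [["na", "na", "ra"], ["na"]]})
        bi = count_ngrams(corpus, 2, cross_breathgroups=True)
        assert bi.counts[("ra", "na")] == 1

    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_matches_brute_force_on_random_corpora(self, rng, n):
        for _ in range(10):
            corpus = random_toy_corpus(rng)
            ft = count_ngrams(corpus, n)
            assert ft.counts == brute_force_counts(corpus, n)

    def test_count_conservation(self, rng):
        for _ in range(5):
            corpus = random_toy_corpus(rng)
            uni = count_ngrams(corpus, 1)
            bi = count_ngrams(corpus, 2)
            assert uni.total == len(corpus)
            assert bi.total == sum(max(len(g) - 1, 0) for g in corpus.breathgroups())

    def test_speaker_scope_restricts(self, small_synthetic):
        _, corpus, _ = small_synthetic
        sid = corpus.speakers()[0]
        ft = count_ngrams(corpus, 1, scope="Sp", speaker_id=sid)
        assert ft.total == len(corpus.tokens_for_speaker(sid))

    def test_n_longer_than_breathgroups_gives_empty(self):
        corpus = build_corpus({"r": [["na", "ra"]]})
        assert count_ngrams(corpus, 5).counts == {}


class TestProbabilities:
    def test_unigram_probability(self):
        ft = FrequencyTable(order_n=1, counts={("a",): 3, ("b",): 2})
        assert unigram_probability(ft, "a") == pytest.approx(0.6)
        assert math.isnan(unigram_probability(ft, "zz"))

    def test_single_type_probability_one(self):
        ft = FrequencyTable(order_n=1, counts={("a",): 7})
        assert unigram_probability(ft, "a") == 1.0

    def test_literal_conditional_hand_count(self):
        # breathgroup [a,b,a,b,a]: uni {a:3,b:2}/5, bi {(a,b):2,(b,a):2}/4
        corpus = build_corpus({"r": [["a", "b", "a", "b", "a"]]})
        uni = count_ngrams(corpus, 1)
        bi = count_ngrams(corpus, 2)
        m = conditional_probabilities(uni, bi, prev="a", cur="b", nxt=None)
        assert m["p_s0_given_prev"] == pytest.approx((2 / 4) / (3 / 5))
        m = conditional_probabilities(uni, bi, prev=None, cur="a", nxt="b")
        assert m["p_next_given_s0"] == pytest.approx((2 / 4) / (3 / 5))

    def test_single_bigram_literal_convention(self):
        corpus = build_corpus({"r": [["a", "a"]]})
        uni = count_ngrams(corpus, 1)
        bi = count_ngrams(corpus, 2)
        m = conditional_probabilities(uni, bi, prev="a", cur="a", nxt=None)
        assert m["p_s0_given_prev"] == pytest.approx((1 / 1) / (2 / 2))

    def test_boundary_tokens_missing_not_zero(self):
        corpus = build_corpus({"r": [["a", "b", "c"]]})
        uni = count_ngrams(corpus, 1)
        bi = count_ngrams(corpus, 2)
        meas = probability_measures(corpus, uni, bi)
        assert math.isnan(meas.loc[0, "p_s0_given_prev"])
        assert math.isnan(meas.loc[2, "p_s0_given_next"])
        assert math.isnan(meas.loc[2, "p_next_given_s0"])
        assert meas["p_s0"].notna().all()

    @pytest.mark.parametrize("mode", ["literal", "row"])
    def test_measures_match_brute_force(self, rng, mode):
        for _ in range(10):
            corpus = random_toy_corpus(rng)
            uni = count_ngrams(corpus, 1)
            bi = count_ngrams(corpus, 2)
            got = probability_measures(corpus, uni, bi, mode=mode)
            expected = brute_force_measures(corpus, mode=mode)
            assert len(got) == len(expected)
            for i, exp in enumerate(expected):
                for key, val in exp.items():
                    g = got.loc[i, key]
                    if math.isnan(val) or val == 0:
                        assert math.isnan(g)
                    else:
                        assert g == pytest.approx(val)

    def test_modes_proportional_within_context(self):
        corpus = build_corpus({"r": [["a", "b", "a", "b", "a", "a", "b"]]})
        uni = count_ngrams(corpus, 1)
        bi = count_ngrams(corpus, 2)
        lit = conditional_probabilities(uni, bi, "a", "b", None, mode="literal")
        row = conditional_probabilities(uni, bi, "a", "b", None, mode="row")
        ratio = uni.total / bi.total
        assert lit["p_s0_given_prev"] == pytest.approx(row["p_s0_given_prev"] * ratio)


class TestSmoothing:
    def test_add_one_over_declared_support(self):
        ft = FrequencyTable(order_n=2, counts={("a", "b"): 2, ("b", "a"): 2})
        support = {(x, y) for x in "ab" for y in "ab"}
        sm = smooth_add_one(ft, support)
        assert sm.counts == {("a", "b"): 3, ("b", "a"): 3, ("a", "a"): 1, ("b", "b"): 1}
        assert sm.total == 8
        assert sm.smoothed

    def test_empty_table_becomes_uniform(self):
        ft = FrequencyTable(order_n=1, counts={})
        sm = smooth_add_one(ft, {("a",), ("b",), ("c",), ("d",)})
        assert set(sm.counts.values()) == {1}
        assert sm.total == 4

    def test_support_must_cover_observed(self):
        ft = FrequencyTable(order_n=1, counts={("a",): 1})
        with pytest.raises(ValueError, match="support"):
            smooth_add_one(ft, {("b",)})

    def test_row_mode_conditionals_sum_to_one_after_smoothing(self):
        corpus = build_corpus({"r": [["a", "b", "a", "a", "b"]]})
        bi = count_ngrams(corpus, 2)
        labels = ["a", "b"]
        support = {(x, y) for x in labels for y in labels}
        bi_sm = smooth_add_one(bi, support)
        # proper conditional: row count over conditioning-context bigram mass
        for ctx in labels:
            row_total = sum(bi_sm[(ctx, y)] for y in labels)
            total = sum(bi_sm[(ctx, y)] / row_total for y in labels)
            assert total == pytest.approx(1.0)


class TestTransform:
    def test_log_then_z(self):
        vals = [math.e, math.e**2, math.e**3]
        np.testing.assert_allclose(transform_predictors(vals), [-1.0, 0.0, 1.0])

    def test_missing_propagates_and_moments_hold(self, rng):
        vals = rng.lognormal(size=200)
        vals[::17] = np.nan
        out = transform_predictors(vals)
        assert np.isnan(out[::17]).all()
        ok = out[~np.isnan(out)]
        assert abs(ok.mean()) < 1e-8
        assert abs(ok.std(ddof=1) - 1) < 1e-8

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            transform_predictors([1.0, 0.0, 2.0])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant|zero standard deviation"):
            transform_predictors([2.0, 2.0, 2.0])


class TestRankFrequency:
    def test_sorted_with_ties_lexicographic(self):
        ft = FrequencyTable(order_n=1, counts={("a",): 5, ("c",): 2, ("b",): 2})
        curve = rank_frequency(ft, top_k=3)
        assert list(curve.ranked_counts) == [5, 2, 2]
        assert curve.labels == [("a",), ("b",), ("c",)]

    def test_top_k_larger_than_types_returns_all(self):
        ft = FrequencyTable(order_n=1, counts={("a",): 5})
        assert len(rank_frequency(ft, top_k=10).ranked_counts) == 1

    def test_permutation_invariance(self, rng):
        corpus = random_toy_corpus(rng)
        ft = count_ngrams(corpus, 1)
        items = list(ft.counts.items())
        shuffled = dict(items[::-1])
        ft2 = FrequencyTable(order_n=1, counts=shuffled)
        c1, c2 = rank_frequency(ft), rank_frequency(ft2)
        assert c1.labels == c2.labels
        assert list(c1.ranked_counts) == list(c2.ranked_counts)

    def test_report_covers_orders_one_to_five(self, small_synthetic):
        _, corpus, _ = small_synthetic
        report = top_ngram_report(corpus)
        assert set(report["n"]) == {1, 2, 3, 4, 5}
        for _, grp in report.groupby("n"):
            assert (grp["count"].diff().dropna() <= 0).all()


class TestSpearman:
    def test_hand_ranked_example(self):
        assert spearman_rho([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_monotone_is_one(self):
        assert spearman_rho([1, 5, 9, 11], [2, 3, 40, 41]) == pytest.approx(1.0)

    def test_matches_rank_then_pearson(self, rng):
        from scipy.stats import rankdata

        x = rng.normal(size=50)
        y = rng.normal(size=50)
        expected = np.corrcoef(rankdata(x), rankdata(y))[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected)

    def test_pairwise_complete_and_minimum_pairs(self):
        x = [1.0, 2.0, np.nan, 4.0]
        y = [4.0, 3.0, 2.0, 1.0]
        assert spearman_rho(x, y) == pytest.approx(-1.0)
        with pytest.raises(ValueError, match="3 complete"):
            spearman_rho([1.0, np.nan, 3.0], [1.0, 2.0, np.nan])


@settings(max_examples=30, deadline=None)
@given(
    st.lists(
        st.lists(st.sampled_from(["na", "ra", "la"]), min_size=1, max_size=6),
        min_size=1,
        max_size=4,
    )
)
def test_bigram_total_property(groups):
    """Sum of bigram counts equals sum over breathgroups of max(len-1, 0)."""
    corpus = build_corpus({"r": groups})
    bi = count_ngrams(corpus, 2)
    assert bi.total == sum(max(len(g) - 1, 0) for g in groups)
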