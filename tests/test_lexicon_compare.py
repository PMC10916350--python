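"""Overlap coefficients, density overlap, attestation, full-word detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from syllastats.corpus_io import ReferencePhoneStream
from syllastats.lexicon_compare import (
    PhoneTokenizer,
    TokenizationError,
    attest_bigrams,
    attest_types,
    count_in_reference,
    density_overlap,
    find_full_words,
    overlap_coefficient,
    pairwise_duration_overlap,
    pairwise_probability_correlation,
    pairwise_speaker_overlap,
)
from syllastats.ngram_stats import FrequencyTable

from conftest import build_corpus


class TestOverlapCoefficient:
    def test_enumerated_example(self):
        assert overlap_coefficient({"x", "y", "z"}, {"y", "z", "w", "v"}) == pytest.approx(2 / 3)

    def test_subset_gives_one(self):
        assert overlap_coefficient({"a"}, {"a", "b", "c"}) == 1.0
        assert overlap_coefficient({"a", "b"}, {"a", "b"}) == 1.0

    def test_jaccard_option(self):
        assert overlap_coefficient({"a"}, {"a", "b"}, method="jaccard") == pytest.approx(0.5)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {"a"})

    @settings(max_examples=50, deadline=None)
    @given(
        st.sets(st.integers(0, 20), min_size=1, max_size=10),
        st.sets(st.integers(0, 20), min_size=1, max_size=10),
    )
    def test_symmetric_and_bounded(self, a, b):
        v = overlap_coefficient(a, b)
        assert v == overlap_coefficient(b, a)
        assert 0.0 <= v <= 1.0
        assert (v == 1.0) == (a <= b or b <= a)


class TestPairwiseOverlap:
    def test_hand_built_lexicons(self):
        corpus = build_corpus(
            {
                "r1": [["na", "ra", "la"]],
                "r2": [["na", "ra", "ba"]],
                "r3": [["xa", "za"]],
            }
        )
        df = pairwise_speaker_overlap(corpus)
        vals = {(r.unit_a, r.unit_b): r.value for r in df.itertuples()}
        assert vals[("r1", "r2")] == pytest.approx(2 / 3)
        assert vals[("r1", "r3")] == 0.0
        assert vals[("r2", "r3")] == 0.0

    def test_identical_lexicons_give_one(self):
        corpus = build_corpus({"r1": [["na", "ra"]], "r2": [["ra", "na"]]})
        df = pairwise_speaker_overlap(corpus)
        assert df["value"].tolist() == [1.0]

    def test_subsets_with_reference(self):
        corpus = build_corpus({"r1": [["na", "xa"]], "r2": [["na", "za"]]})
        reference = ReferencePhoneStream(chunks=[("n", "a",)])
        df = pairwise_speaker_overlap(corpus, reference=reference)
        by_subset = df.set_index("subset")["value"]
        assert by_subset["all"] == pytest.approx(0.5)
        assert by_subset["attested_in_reference"] == pytest.approx(1.0)  # {na} vs {na}
        assert by_subset["unattested_in_reference"] == pytest.approx(0.0)


class TestProbabilityCorrelation:
    @staticmethod
    def _table(counts):
        return FrequencyTable(order_n=1, counts={(k,): v for k, v in counts.items()})

    def test_identical_profiles_give_one(self):
        t = {"a": 10, "b": 5, "c": 2, "d": 1}
        df = pairwise_probability_correlation({"s1": self._table(t), "s2": self._table(t)})
        assert df["value"].tolist() == [pytest.approx(1.0)]

    def test_hand_built_matches_brute_force(self):
        from scipy.stats import rankdata

        ta = {"a": 4, "b": 3, "c": 2, "d": 1}
        tb = {"a": 1, "b": 2, "c": 3, "e": 4}
        df = pairwise_probability_correlation(
            {"s1": self._table(ta), "s2": self._table(tb)}
        )
        labels = sorted(set(ta) | set(tb))
        xa = np.array([ta.get(k, 0) / 10 for k in labels], float)
        xb = np.array([tb.get(k, 0) / 10 for k in labels], float)
        expected = np.corrcoef(rankdata(xa), rankdata(xb))[0, 1]
        assert df["value"].iloc[0] == pytest.approx(expected)

    def test_shared_support_mode_insufficient_pairs_missing(self):
        ta = {"a": 4, "b": 3}
        tb = {"a": 1, "c": 2}
        df = pairwise_probability_correlation(
            {"s1": self._table(ta), "s2": self._table(tb)}, support="shared"
        )
        assert math.isnan(df["value"].iloc[0])


class TestDensityOverlap:
    def test_sample_against_itself(self, rng):
        x = rng.normal(size=500)
        assert density_overlap(x, x) == pytest.approx(1.0, abs=0.01)

    def test_far_separated_samples(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(100, 1, 200)
        assert density_overlap(a, b) < 0.001

    def test_gaussian_closed_form(self, rng):
        a = rng.normal(0, 1, 5000)
        b = rng.normal(1, 1, 5000)
        assert density_overlap(a, b) == pytest.approx(2 * norm.cdf(-0.5), abs=0.03)

    def test_affine_invariance(self, rng):
        a = rng.normal(0, 1, 400)
        b = rng.normal(0.7, 1.3, 400)
        v1 = density_overlap(a, b)
        v2 = density_overlap(3 * a + 10, 3 * b + 10)
        assert v1 == pytest.approx(v2, abs=0.01)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            density_overlap(np.ones(20), np.linspace(0, 1, 20))

    def test_pairwise_duration_overlap_shared_distribution(self, rng):
        sequences = {}
        durations = {}
        labels = []
        for s in range(3):
            labs = [f"s{s}x{i}" for i in range(1000)]
            labels.append(labs)
            sequences[f"r{s}"] = [labs]
        corpus = build_corpus(sequences)
        # identical duration distribution for every speaker
        tokens = []
        for tok in corpus.tokens:
            d = float(np.clip(rng.normal(0.2, 0.04), 0.01, None))
            tokens.append(
                type(tok)(
                    label=tok.label,
                    start_s=tok.start_s,
                    end_s=tok.start_s + d,
                    speaker_id=tok.speaker_id,
                    recording_id=tok.recording_id,
                    breathgroup_index=tok.breathgroup_index,
                    position_in_breathgroup=tok.position_in_breathgroup,
                )
            )
        corpus.tokens = sorted(tokens, key=lambda t: (t.recording_id, t.start_s))
        mean, sd, df = pairwise_duration_overlap(corpus)
        assert mean >= 0.95
        assert len(df) == 3


class TestTokenizer:
    def test_multicharacter_symbols_longest_match(self):
        tok = PhoneTokenizer()
        assert tok("tSa") == ("tS", "a")
        assert tok("tsa") == ("ts", "a")
        assert tok("nat") == ("n", "a", "t")

    def test_diacritics_stripped(self):
        tok = PhoneTokenizer()
        assert tok("na:") == ("n", "a")
        assert tok("'na") == ("n", "a")

    def test_unknown_symbol_reported(self):
        tok = PhoneTokenizer(inventory=("n", "a"))
        with pytest.raises(TokenizationError, match="position"):
            tok("nax")


class TestAttestation:
    @staticmethod
    def brute_force_hits(seq, chunks):
        n = 0
        for chunk in chunks:
            for i in range(len(chunk) - len(seq) + 1):
                if tuple(chunk[i : i + len(seq)]) == tuple(seq):
                    n += 1
        return n

    def test_contiguous_subsequence_attests(self):
        ref = ReferencePhoneStream(chunks=[("b", "a", "n", "a", "n", "@")])
        att = attest_types(["na"], PhoneTokenizer(), ref)
        assert att.attested == {"na"}

    def test_missing_phone_unattested(self):
        ref = ReferencePhoneStream(chunks=[("b", "a", "n", "a")])
        att = attest_types(["xan"], PhoneTokenizer(), ref)
        assert att.unattested == {"xan"}

    def test_matches_brute_force_scan(self, rng):
        phones = list("bandrk") + ["a", "i", "u"]
        chunks = [
            tuple(rng.choice(phones, size=int(rng.integers(3, 12))))
            for _ in range(30)
        ]
        ref = ReferencePhoneStream(chunks=chunks)
        labels = ["ba", "na", "di", "ku", "dran", "ib"]
        tok = PhoneTokenizer(inventory=tuple(phones))
        att = attest_types(labels, tok, ref)
        counts = count_in_reference({lab: tok(lab) for lab in labels}, ref)
        for lab in labels:
            expected = self.brute_force_hits(tok(lab), chunks)
            assert counts[lab] == expected
            assert (lab in att.attested) == (expected > 0)

    def test_bigram_across_pause_not_attested(self):
        ref = ReferencePhoneStream(chunks=[("n", "a"), ("n", "a")])
        att = attest_bigrams([("na", "na")], PhoneTokenizer(), ref)
        assert att.unattested == {("na", "na")}
        ref2 = ReferencePhoneStream(chunks=[("n", "a", "n", "a")])
        att2 = attest_bigrams([("na", "na")], PhoneTokenizer(), ref2)
        assert att2.attested == {("na", "na")}

    def test_token_rate_uses_type_mass(self):
        ref = ReferencePhoneStream(chunks=[("n", "a")])
        att = attest_types(
            ["na", "xa"], PhoneTokenizer(), ref, token_counts={"na": 9, "xa": 1}
        )
        assert att.type_rate == pytest.approx(0.5)
        assert att.token_rate == pytest.approx(0.9)

    def test_partition_is_exact_and_monotone(self, rng):
        phones = ["n", "a", "b", "o"]
        tok = PhoneTokenizer(inventory=tuple(phones))
        labels = ["na", "no", "ba", "bo"]
        small = ReferencePhoneStream(chunks=[("n", "a")])
        large = ReferencePhoneStream(chunks=[("n", "a"), ("b", "o", "n", "o")])
        att_small = attest_types(labels, tok, small)
        att_large = attest_types(labels, tok, large)
        assert att_small.attested | att_small.unattested == set(labels)
        assert att_small.attested & att_small.unattested == set()
        assert att_small.attested <= att_large.attested


class TestFullWords:
    def test_exact_match_only(self):
        tok = PhoneTokenizer()
        lexicon = {
            ("d", "a", "N", "k", "@"): ("danke", 12),
            ("n", "a"): ("na", 3),
        }
        df = find_full_words([("da", "Nk@"), ("da", "N")], tok, lexicon)
        assert df["bigram"].tolist() == ["da Nk@"]
        assert df["reference_count"].tolist() == [12]

    def test_planted_matches_found_exactly(self):
        from syllastats.synthetic_data import ReferenceOptions, generate_reference_corpus

        planted = (("na", "ka"), ("do", "mi"))
        stream, _ = generate_reference_corpus(
            ["na", "ka", "do", "mi", "zu"],
            ReferenceOptions(shared_fraction=1.0, planted_word_bigrams=planted),
            seed=3,
        )
        df = find_full_words(
            [("na", "ka"), ("do", "mi"), ("na", "do")], PhoneTokenizer(), stream.word_lexicon
        )
        assert set(df["bigram"]) == {"na ka", "do mi"}
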