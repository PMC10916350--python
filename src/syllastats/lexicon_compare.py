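"""Cross-corpus attestation, speaker-overlap statistics and density overlap.

Speakers' syllable lexicons are compared with the Szymkiewicz–Simpson
overlap coefficient |A∩B| / min(|A|, |B|) (1 whenever one set contains the
other); per-speaker probability profiles with Spearman rank correlations;
and duration distributions with the kernel-density overlap coefficient
∫ min(f̂_a, f̂_b) dx.

Attestation against a reference phone stream ignores the reference's word
and syllable boundaries: a syllable (or syllable bigram) counts as attested
iff its phone sequence occurs contiguously inside at least one pause-
delimited chunk.  Pauses are hard boundaries — a sequence spanning one is
not a match.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import Corpus, ReferencePhoneStream
from .ngram_stats import FrequencyTable, spearman_rho

logger = logging.getLogger(__name__)

#: Diacritics stripped from labels before phone tokenization (length mark,
#: primary/secondary stress in X-SAMPA).
DEFAULT_STRIP_MARKS = (":", "'", '"', "%")

#: A workable X-SAMPA symbol inventory for German-like material; multi-
#: character symbols must be listed explicitly so the tokenizer can prefer
#: the longest match.
DEFAULT_PHONE_INVENTORY = tuple(
    "p b t d k g f v s z S Z C x h m n N l r R j w ts tS pf dZ "
    "a e i o u E I O U Y y 2 9 @ 6 aI aU OY ea Ia ua".split()
)


class TokenizationError(ValueError):
    """A label cannot be decomposed into inventory phones."""


@dataclass
class PhoneTokenizer:
    """Greedy longest-match decomposition of X-SAMPA labels into phones."""

    inventory: Sequence[str] = DEFAULT_PHONE_INVENTORY
    strip_marks: Sequence[str] = DEFAULT_STRIP_MARKS

    def __post_init__(self) -> None:
        self._by_length = sorted(set(self.inventory), key=len, reverse=True)

    def __call__(self, label: str) -> tuple[str, ...]:
        for mark in self.strip_marks:
            label = label.replace(mark, "")
        phones: list[str] = []
        i = 0
        while i < len(label):
            for sym in self._by_length:
                if label.startswith(sym, i):
                    phones.append(sym)
                    i += len(sym)
                    break
            else:
                raise TokenizationError(
                    f"cannot tokenize {label!r}: no inventory symbol matches at "
                    f"position {i} ({label[i:]!r})"
                )
        return tuple(phones)


# ---------------------------------------------------------------------------
# Set overlap
# ---------------------------------------------------------------------------

def overlap_coefficient(set_a: Iterable, set_b: Iterable, method: str = "szymkiewicz") -> float:
    """Szymkiewicz–Simpson coefficient |A∩B|/min(|A|,|B|) (or Jaccard)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    inter = len(a & b)
    if method == "szymkiewicz":
        return inter / min(len(a), len(b))
    if method == "jaccard":
        return inter / len(a | b)
    raise ValueError(f"unknown overlap method {method!r}")


@dataclass
class OverlapResult:
    unit_a: str
    unit_b: str
    statistic: str  # set_overlap | density_overlap | prob_spearman
    value: float
    subset: str = "all"  # all | attested_in_reference | unattested_in_reference


def speaker_lexicons(corpus: Corpus) -> dict[str, set[str]]:
    lex: dict[str, set[str]] = {}
    for tok in corpus.tokens:
        lex.setdefault(tok.speaker_id, set()).add(tok.label)
    return lex


def pairwise_speaker_overlap(
    corpus: Corpus,
    reference: ReferencePhoneStream | None = None,
    tokenizer: PhoneTokenizer | None = None,
    method: str = "szymkiewicz",
) -> pd.DataFrame:
    """One set-overlap value per unordered speaker pair and subset condition.

    With a reference stream, overlaps are additionally computed over the
    attested-in-reference and unattested-in-reference sub-lexicons.
    """
    lex = speaker_lexicons(corpus)
    if len(lex) < 2:
        raise ValueError("need at least 2 speakers")
    subsets: dict[str, dict[str, set[str]]] = {"all": lex}
    if reference is not None:
        tok = tokenizer or PhoneTokenizer()
        all_labels = set().union(*lex.values())
        att = attest_types(all_labels, tok, reference)
        subsets["attested_in_reference"] = {
            s: labs & att.attested for s, labs in lex.items()
        }
        subsets["unattested_in_reference"] = {
            s: labs & att.unattested for s, labs in lex.items()
        }
    rows: list[OverlapResult] = []
    for subset, sublex in subsets.items():
        for a, b in itertools.combinations(sorted(sublex), 2):
            if not sublex[a] or not sublex[b]:
                logger.warning("speaker %s or %s has empty lexicon in subset %s; pair skipped", a, b, subset)
                continue
            rows.append(
                OverlapResult(a, b, "set_overlap", overlap_coefficient(sublex[a], sublex[b], method), subset)
            )
    return pd.DataFrame([vars(r) for r in rows])


def pairwise_probability_correlation(
    tables: Mapping[str, FrequencyTable],
    support: str = "union",
) -> pd.DataFrame:
    """Pairwise Spearman correlations of per-speaker unigram probabilities.

    ``support="union"`` correlates over the union of the two lexicons with
    absent types assigned probability 0 (rank-tied at the bottom);
    ``support="shared"`` uses only types both speakers attest.  Pairs with
    fewer than 3 support types are reported as missing.
    """
    rows: list[OverlapResult] = []
    for a, b in itertools.combinations(sorted(tables), 2):
        ta, tb = tables[a], tables[b]
        if support == "union":
            labels = sorted({g[0] for g in ta.counts} | {g[0] for g in tb.counts})
            xa = [ta[(lab,)] / ta.total for lab in labels]
            xb = [tb[(lab,)] / tb.total for lab in labels]
        elif support == "shared":
            labels = sorted({g[0] for g in ta.counts} & {g[0] for g in tb.counts})
            xa = [ta[(lab,)] / ta.total for lab in labels]
            xb = [tb[(lab,)] / tb.total for lab in labels]
        else:
            raise ValueError(f"unknown support mode {support!r}")
        value = math.nan
        if len(labels) >= 3:
            value = spearman_rho(xa, xb)
        rows.append(OverlapResult(a, b, "prob_spearman", value))
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# Density overlap
# ---------------------------------------------------------------------------

def density_overlap(
    samples_a: Sequence[float],
    samples_b: Sequence[float],
    grid_points: int = 1024,
    pad_bandwidths: float = 3.0,
    bw_method: str = "silverman",
) -> float:
    """Overlap coefficient ∫ min(f̂_a, f̂_b) dx of two Gaussian KDEs.

    Densities are estimated with Silverman's bandwidth and evaluated on a
    common grid spanning the joint range padded by ``pad_bandwidths``
    bandwidths; the minimum is integrated by the trapezoidal rule.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ValueError("each sample must have at least 10 points")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance sample: KDE undefined")
    kde_a = stats.gaussian_kde(a, bw_method=bw_method)
    kde_b = stats.gaussian_kde(b, bw_method=bw_method)
    h = max(np.sqrt(kde_a.covariance[0, 0]), np.sqrt(kde_b.covariance[0, 0]))
    lo = min(a.min(), b.min()) - pad_bandwidths * h
    hi = max(a.max(), b.max()) + pad_bandwidths * h
    grid = np.linspace(lo, hi, grid_points)
    fmin = np.minimum(kde_a(grid), kde_b(grid))
    return float(np.trapezoid(fmin, grid))


def pairwise_duration_overlap(corpus: Corpus, **kde_kwargs) -> tuple[float, float, pd.DataFrame]:
    """Density overlap of syllable-duration distributions per speaker pair.

    Returns (mean, SD, per-pair table); SD is the sample SD over pairs.
    """
    durs: dict[str, list[float]] = {}
    for tok in corpus.tokens:
        durs.setdefault(tok.speaker_id, []).append(tok.duration_s)
    speakers = sorted(durs)
    if len(speakers) < 2:
        raise ValueError("need at least 2 speakers")
    rows = []
    for a, b in itertools.combinations(speakers, 2):
        value = density_overlap(durs[a], durs[b], **kde_kwargs)
        rows.append(OverlapResult(a, b, "density_overlap", value))
    df = pd.DataFrame([vars(r) for r in rows])
    return float(df["value"].mean()), float(df["value"].std(ddof=1)), df


# ---------------------------------------------------------------------------
# Attestation against a reference phone stream
# ---------------------------------------------------------------------------

class _InternedReference:
    """Chunks re-encoded as strings of one private-use char per phone symbol,
    so contiguous-subsequence counting runs on C string search."""

    def __init__(self, reference: ReferencePhoneStream):
        self.symbols: dict[str, str] = {}
        self.chunks: list[str] = [self._encode(c) for c in reference.chunks]

    def _encode(self, phones: Sequence[str]) -> str:
        chars = []
        for ph in phones:
            ch = self.symbols.get(ph)
            if ch is None:
                ch = chr(0xE000 + len(self.symbols))
                self.symbols[ph] = ch
            chars.append(ch)
        return "".join(chars)

    def encode_query(self, phones: Sequence[str]) -> str | None:
        try:
            return "".join(self.symbols[ph] for ph in phones)
        except KeyError:
            return None  # phone never occurs in the reference

    def count(self, phones: Sequence[str]) -> int:
        q = self.encode_query(phones)
        if q is None:
            return 0
        n = 0
        for chunk in self.chunks:
            start = chunk.find(q)
            while start != -1:
                n += 1
                start = chunk.find(q, start + 1)  # overlapping occurrences count
        return n


def count_in_reference(
    phone_seqs: Mapping[object, tuple[str, ...]],
    reference: ReferencePhoneStream,
) -> dict[object, int]:
    """Occurrences of each phone sequence as a contiguous chunk subsequence."""
    interned = _InternedReference(reference)
    return {key: interned.count(seq) for key, seq in phone_seqs.items()}


@dataclass
class AttestationResult:
    attested: set
    unattested: set
    hits: dict
    type_rate: float
    token_rate: float | None = None

    def to_frame(self, tokenized: Mapping[object, tuple[str, ...]] | None = None) -> pd.DataFrame:
        rows = []
        for key in sorted(self.attested | self.unattested, key=str):
            rows.append(
                {
                    "label": key if isinstance(key, str) else " ".join(key),
                    "tokenized_phones": " ".join(tokenized[key]) if tokenized else "",
                    "attested": key in self.attested,
                    "n_reference_hits": self.hits.get(key, 0),
                }
            )
        return pd.DataFrame(rows)


def attest_types(
    labels: Iterable[str],
    tokenizer: PhoneTokenizer,
    reference: ReferencePhoneStream,
    token_counts: Mapping[str, int] | None = None,
) -> AttestationResult:
    """Partition syllable types into attested / unattested in the reference.

    A type is attested iff its phone sequence occurs contiguously within at
    least one pause-delimited chunk.  With ``token_counts`` the token-level
    rate is the token mass of attested types over all tokens.
    """
    labels = set(labels)
    seqs = {lab: tokenizer(lab) for lab in labels}
    hits = count_in_reference(seqs, reference)
    attested = {lab for lab in labels if hits[lab] > 0}
    unattested = labels - attested
    type_rate = len(attested) / len(labels) if labels else math.nan
    token_rate = None
    if token_counts is not None:
        total = sum(token_counts.get(lab, 0) for lab in labels)
        mass = sum(token_counts.get(lab, 0) for lab in attested)
        token_rate = mass / total if total else math.nan
    return AttestationResult(attested, unattested, hits, type_rate, token_rate)


def attest_bigrams(
    bigrams: Iterable[tuple[str, str]],
    tokenizer: PhoneTokenizer,
    reference: ReferencePhoneStream,
    token_counts: Mapping[tuple[str, str], int] | None = None,
) -> AttestationResult:
    """As :func:`attest_types`, on concatenated two-syllable phone sequences."""
    bigrams = set(bigrams)
    seqs = {bg: tokenizer(bg[0]) + tokenizer(bg[1]) for bg in bigrams}
    hits = count_in_reference(seqs, reference)
    attested = {bg for bg in bigrams if hits[bg] > 0}
    unattested = bigrams - attested
    type_rate = len(attested) / len(bigrams) if bigrams else math.nan
    token_rate = None
    if token_counts is not None:
        total = sum(token_counts.get(bg, 0) for bg in bigrams)
        mass = sum(token_counts.get(bg, 0) for bg in attested)
        token_rate = mass / total if total else math.nan
    return AttestationResult(attested, unattested, hits, type_rate, token_rate)


def find_full_words(
    bigrams: Iterable[tuple[str, str]],
    tokenizer: PhoneTokenizer,
    word_lexicon: Mapping[tuple[str, ...], tuple[str, int]],
) -> pd.DataFrame:
    """Syllable bigrams whose concatenated phones exactly equal a reference word.

    Prefix or substring relations do not count; the match must be the whole
    word transcription.
    """
    rows = []
    for bg in sorted(set(bigrams)):
        seq = tokenizer(bg[0]) + tokenizer(bg[1])
        if seq in word_lexicon:
            form, count = word_lexicon[seq]
            rows.append(
                {
                    "bigram": " ".join(bg),
                    "phones": " ".join(seq),
                    "word_form": form,
                    "reference_count": count,
                }
            )
    return pd.DataFrame(rows, columns=["bigram", "phones", "word_form", "reference_count"])


# ---------------------------------------------------------------------------
# Reference-corpus frequency tables (the "Ger" scope)
# ---------------------------------------------------------------------------

def reference_frequency_tables(
    unigrams: Iterable[str],
    bigrams: Iterable[tuple[str, str]],
    tokenizer: PhoneTokenizer,
    reference: ReferencePhoneStream,
    smooth: bool = True,
) -> tuple[FrequencyTable, FrequencyTable]:
    """Reference-corpus counts of the queried syllables and syllable bigrams.

    Counts are contiguous-subsequence occurrences within reference chunks
    (word/syllable boundaries ignored).  Because some queried items never
    occur in the reference, add-one smoothing over the queried support is on
    by default; totals are sums over that support.
    """
    unigrams = sorted(set(unigrams))
    bigrams = sorted(set(bigrams))
    uni_hits = count_in_reference({u: tokenizer(u) for u in unigrams}, reference)
    bi_hits = count_in_reference(
        {bg: tokenizer(bg[0]) + tokenizer(bg[1]) for bg in bigrams}, reference
    )
    uni_counts = {(u,): uni_hits[u] for u in unigrams}
    bi_counts = {bg: bi_hits[bg] for bg in bigrams}
    if smooth:
        uni_counts = {g: c + 1 for g, c in uni_counts.items()}
        bi_counts = {g: c + 1 for g, c in bi_counts.items()}
    else:
        uni_counts = {g: c for g, c in uni_counts.items() if c > 0}
        bi_counts = {g: c for g, c in bi_counts.items() if c > 0}
    uni = FrequencyTable(order_n=1, counts=uni_counts, scope="Ger", smoothed=smooth)
    bi = FrequencyTable(order_n=2, counts=bi_counts, scope="Ger", smoothed=smooth)
    return uni, bi
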