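"""Syllable n-gram frequencies, probability measures, transforms and Zipf curves.

Four per-token probability measures are supported, at three scopes:

* ``p_s0`` — marginal probability of the current syllable, count / corpus size;
* ``p_s0_given_prev`` — P(S0|S-1) = P(S0,S-1) / P(S-1);
* ``p_s0_given_next`` — P(S0|S+1) = P(S0,S+1) / P(S+1);
* ``p_next_given_s0`` — P(S+1|S0) = P(S+1,S0) / P(S0).

Scopes are the pooled corpus (``All``), one speaker's subset (``Sp``), or a
reference corpus of the speakers' native language (``Ger``).  In the default
"literal" convention the joint probability is a bigram count divided by the
total of all bigram counts and the marginal is a unigram count divided by the
total of all unigram counts; the ratio can then exceed 1, and a
"row-normalized" convention (bigram count / conditioning-type count, a proper
conditional) is available.  After the log transform the two differ only by a
constant, so z-scaled predictors agree whenever the support is shared.

N-grams never cross a breathgroup boundary: pauses delimit sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .corpus_io import Corpus

logger = logging.getLogger(__name__)

MEASURE_NAMES = ("p_s0", "p_s0_given_prev", "p_s0_given_next", "p_next_given_s0")


@dataclass
class FrequencyTable:
    """N-gram counts for one scope, with totals and vocabulary."""

    order_n: int
    counts: dict[tuple[str, ...], int]
    scope: str = "All"
    smoothed: bool = False
    total: int = field(init=False)
    vocabulary: set[str] = field(init=False)

    def __post_init__(self) -> None:
        if not 1 <= self.order_n <= 5:
            raise ValueError(f"order_n must be in 1..5, got {self.order_n}")
        for gram in self.counts:
            if len(gram) != self.order_n:
                raise ValueError(f"n-gram {gram!r} has wrong length for order {self.order_n}")
        self.total = int(sum(self.counts.values()))
        self.vocabulary = {lab for gram in self.counts for lab in gram}

    def __getitem__(self, gram: tuple[str, ...] | str) -> int:
        if isinstance(gram, str):
            gram = (gram,)
        return self.counts.get(gram, 0)


def iter_breathgroup_sequences(corpus: Corpus, speaker_id: str | None = None):
    """Yield each breathgroup as a list of labels, in corpus order."""
    for group in corpus.breathgroups():
        if speaker_id is not None and group[0].speaker_id != speaker_id:
            continue
        yield [tok.label for tok in group]


def count_ngrams(
    corpus: Corpus,
    n: int,
    scope: str = "All",
    speaker_id: str | None = None,
    cross_breathgroups: bool = False,
) -> FrequencyTable:
    """Count syllable n-grams within breathgroups.

    ``scope="Sp"`` with a ``speaker_id`` restricts counting to that speaker's
    tokens.  With ``cross_breathgroups=True`` the whole recording is treated
    as one sequence (sensitivity analysis only).
    """
    if scope == "Sp" and speaker_id is None:
        raise ValueError("speaker scope requires speaker_id")
    seqs: list[list[str]]
    if cross_breathgroups:
        per_rec: dict[str, list[str]] = {}
        for tok in corpus.tokens:
            if speaker_id is not None and tok.speaker_id != speaker_id:
                continue
            per_rec.setdefault(tok.recording_id, []).append(tok.label)
        seqs = list(per_rec.values())
    else:
        seqs = list(iter_breathgroup_sequences(corpus, speaker_id))
    counts: dict[tuple[str, ...], int] = {}
    for seq in seqs:
        for i in range(len(seq) - n + 1):
            gram = tuple(seq[i : i + n])
            counts[gram] = counts.get(gram, 0) + 1
    if not counts:
        logger.warning("no %d-grams found (n exceeds longest breathgroup?)", n)
    tag = f"Sp({speaker_id})" if speaker_id is not None else scope
    return FrequencyTable(order_n=n, counts=counts, scope=tag)


def unigram_probability(ft: FrequencyTable, label: str) -> float:
    """count(label)/total; NaN (missing, not zero) for unattested labels."""
    if ft.order_n != 1:
        raise ValueError("unigram_probability requires an order-1 table")
    c = ft[(label,)]
    if c == 0:
        return math.nan
    return c / ft.total


def smooth_add_one(
    ft: FrequencyTable, support: Iterable[tuple[str, ...]]
) -> FrequencyTable:
    """Add-one (Laplace) smoothing over a declared support.

    Every n-gram in ``support`` receives count+1, so unattested events in the
    support get probability mass.  The support must contain every observed
    n-gram.
    """
    support = set(support)
    observed = set(ft.counts)
    if not observed <= support:
        raise ValueError(
            f"support misses {len(observed - support)} observed n-grams, "
            f"e.g. {sorted(observed - support)[:3]}"
        )
    counts = {gram: ft.counts.get(gram, 0) + 1 for gram in support}
    return FrequencyTable(order_n=ft.order_n, counts=counts, scope=ft.scope, smoothed=True)


def conditional_probabilities(
    uni: FrequencyTable,
    bi: FrequencyTable,
    prev: str | None,
    cur: str,
    nxt: str | None,
    mode: str = "literal",
) -> dict[str, float]:
    """The three conditional measures for one token in context.

    ``prev``/``nxt`` are the neighbouring labels within the same breathgroup,
    or None at a boundary, in which case the corresponding measures are
    missing (NaN), never zero.  A zero count or zero marginal without
    smoothing is likewise a missing value.
    """
    if uni.scope != bi.scope or uni.smoothed != bi.smoothed:
        raise ValueError("unigram and bigram tables must share scope and smoothing state")
    if mode not in ("literal", "row"):
        raise ValueError(f"unknown conditional mode {mode!r}")

    def joint(a: str, b: str) -> float:
        c = bi[(a, b)]
        return math.nan if c == 0 else c / bi.total

    def margin(a: str) -> float:
        c = uni[(a,)]
        return math.nan if c == 0 else c / uni.total

    def row(a: str, b: str, cond: str) -> float:
        """bigram count / count of the conditioning type ``cond``."""
        c = bi[(a, b)]
        m = uni[(cond,)]
        return math.nan if c == 0 or m == 0 else c / m

    out: dict[str, float] = {}
    if prev is None:
        out["p_s0_given_prev"] = math.nan
    elif mode == "literal":
        out["p_s0_given_prev"] = joint(prev, cur) / margin(prev)
    else:
        out["p_s0_given_prev"] = row(prev, cur, cond=prev)
    if nxt is None:
        out["p_s0_given_next"] = math.nan
        out["p_next_given_s0"] = math.nan
    elif mode == "literal":
        out["p_s0_given_next"] = joint(cur, nxt) / margin(nxt)
        out["p_next_given_s0"] = joint(cur, nxt) / margin(cur)
    else:
        out["p_s0_given_next"] = row(cur, nxt, cond=nxt)
        out["p_next_given_s0"] = row(cur, nxt, cond=cur)
    return out


def probability_measures(
    corpus: Corpus,
    uni: FrequencyTable,
    bi: FrequencyTable,
    speaker_id: str | None = None,
    mode: str = "literal",
) -> pd.DataFrame:
    """Per-token probability measures for every token (or one speaker's).

    Returns one row per token with the four raw measures; boundary tokens
    carry NaN where the context is missing.
    """
    rows = []
    for group in corpus.breathgroups():
        if speaker_id is not None and group[0].speaker_id != speaker_id:
            continue
        labels = [t.label for t in group]
        for i, tok in enumerate(group):
            prev = labels[i - 1] if i > 0 else None
            nxt = labels[i + 1] if i < len(labels) - 1 else None
            meas = conditional_probabilities(uni, bi, prev, tok.label, nxt, mode=mode)
            c = uni[(tok.label,)]
            meas["p_s0"] = math.nan if c == 0 else c / uni.total
            rows.append(
                {
                    "recording_id": tok.recording_id,
                    "breathgroup_index": tok.breathgroup_index,
                    "position_in_breathgroup": tok.position_in_breathgroup,
                    "speaker_id": tok.speaker_id,
                    "label": tok.label,
                    **{k: meas[k] for k in MEASURE_NAMES},
                }
            )
    return pd.DataFrame(rows)


def transform_predictors(values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Log-transform then z-scale; missing values (NaN) propagate.

    The sample mean/SD are computed over non-missing entries only.  Raises on
    non-positive values (log undefined) and on zero spread (z undefined).
    """
    arr = np.asarray(values, dtype=float)
    mask = ~np.isnan(arr)
    if (arr[mask] <= 0).any():
        bad = int(np.nonzero(mask & (arr <= 0))[0][0])
        raise ValueError(f"non-positive value {arr[bad]!r} at index {bad}; log undefined")
    out = np.full_like(arr, np.nan)
    logs = np.log(arr[mask])
    sd = logs.std(ddof=1) if logs.size > 1 else 0.0
    if logs.size == 0:
        return out
    if sd == 0:
        raise ValueError("zero standard deviation: cannot z-scale a constant predictor")
    out[mask] = (logs - logs.mean()) / sd
    return out


@dataclass
class RankFrequencyCurve:
    """Counts sorted descending with 1-based ranks (Zipf diagnostic)."""

    labels: list[tuple[str, ...]]
    ranked_counts: np.ndarray
    ranks: np.ndarray

    def loglog_slope(self) -> float:
        """OLS slope of log count on log rank (≈ -s for a Zipfian sample)."""
        res = stats.linregress(np.log(self.ranks), np.log(self.ranked_counts))
        return float(res.slope)


def rank_frequency(ft: FrequencyTable, top_k: int | None = None) -> RankFrequencyCurve:
    """Rank–frequency curve; ties broken by lexicographic label order."""
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be >= 1")
    items = sorted(ft.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        if top_k > len(items):
            logger.warning("top_k=%d exceeds %d types; returning all", top_k, len(items))
        items = items[:top_k]
    labels = [gram for gram, _ in items]
    counts = np.array([c for _, c in items], dtype=float)
    return RankFrequencyCurve(labels=labels, ranked_counts=counts, ranks=np.arange(1, len(items) + 1))


def top_ngram_report(corpus: Corpus, max_n: int = 5, top_k: int = 10) -> pd.DataFrame:
    """Most frequent n-grams for n = 1..max_n (tabular report)."""
    frames = []
    for n in range(1, max_n + 1):
        curve = rank_frequency(count_ngrams(corpus, n), top_k=top_k)
        frames.append(
            pd.DataFrame(
                {
                    "n": n,
                    "rank": curve.ranks,
                    "ngram": [" ".join(g) for g in curve.labels],
                    "count": curve.ranked_counts.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation with average ranks for ties.

    Pairs with a missing value in either vector are dropped; fewer than 3
    complete pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 3:
        raise ValueError(f"need >= 3 complete pairs, have {int(mask.sum())}")
    rho = stats.spearmanr(x[mask], y[mask]).statistic
    return float(rho)


def frequency_table_to_frame(ft: FrequencyTable) -> pd.DataFrame:
    """Export a frequency table as {ngram, count, probability} rows."""
    rows = [
        {"ngram": " ".join(gram), "count": c, "probability": c / ft.total}
        for gram, c in sorted(ft.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)
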