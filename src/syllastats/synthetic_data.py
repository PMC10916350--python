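"""Synthetic multi-speaker syllable corpora with known ground truth.

The generator emulates the structure of a small corpus of pause-segmented,
syllable-annotated recordings by several speakers of the same community:

* per-speaker syllable lexicons with a controllable mean pairwise
  Szymkiewicz–Simpson overlap (a shared core plus speaker-private types);
* Zipfian type probabilities, permuted independently per speaker so that
  individual probability profiles are distinct;
* first-order Markov transition structure within breathgroups (rows drawn
  from a Dirichlet and reweighted toward the Zipfian marginal), with
  breathgroups started from the chain's stationary distribution;
* syllable durations that shrink log-linearly with the true syllable
  probability and the true transition probability, with a Gaussian speaker
  intercept and Gaussian noise (negative draws are resampled, not clipped);
* a reference phone stream in which a stated fraction of the corpus's
  syllable types is planted, for attestation tests with a plant log.

Everything stochastic flows from a single integer seed; outputs are
bit-reproducible given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .corpus_io import (
    Corpus,
    RecordingInfo,
    ReferencePhoneStream,
    SyllableToken,
)
from scipy.stats import rankdata as stats_rankdata

from .lexicon_compare import PhoneTokenizer
from .ngram_stats import count_ngrams, spearman_rho


def _zscore(arr: np.ndarray) -> np.ndarray:
    sd = arr.std(ddof=0)
    return (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr)

logger = logging.getLogger(__name__)

DEFAULT_CONSONANTS = tuple("p b t d k g f v s z S x h m n l r j ts tS".split())
DEFAULT_VOWELS = tuple("a e i o u E I O U @ Y 2 9 6 aI aU".split())
#: Filler phones for reference-corpus material, disjoint from the syllable
#: inventory so that unplanted reference words cannot spell corpus syllables.
DEFAULT_FILLER_PHONES = tuple("P B T D K G F M L R W q c J X w9 yq".split())


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-scale defaults: 11 speakers, 15 recordings of ~500 syllables
    grouped into breathgroups of mean length ~16, Zipf exponent 1, partial
    lexicon overlap, and a weak negative probability effect on duration
    (about -10 ms per SD of log probability against 30 ms residual noise)."""

    n_speakers: int = 11
    lexicon_size: int = 80
    overlap_target: float = 0.2
    zipf_exponent: float = 1.0
    markov_concentration: float = 0.3
    #: extra probability mass on self-transitions ("echoism": immediate
    #: repetition of the same syllable is the dominant bigram pattern)
    repetition_boost: float = 0.25
    beta0: float = 0.20
    beta_p: float = -0.010
    beta_t: float = -0.004
    speaker_intercept_sd: float = 0.01
    noise_sd: float = 0.03
    breathgroup_length: float = 16.0
    tokens_per_recording: int = 500
    consonants: tuple[str, ...] = DEFAULT_CONSONANTS
    vowels: tuple[str, ...] = DEFAULT_VOWELS
    cv_preference: float = 0.8
    #: speakers (0-based indices) that contribute an extra "test" recording,
    #: mirroring a corpus with more recordings than speakers
    test_recording_speakers: tuple[int, ...] = (0, 1, 2, 3)
    pause_gap_s: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.overlap_target <= 1.0):
            raise ValueError("overlap_target must be in [0, 1]")
        if not (0.0 <= self.cv_preference <= 1.0):
            raise ValueError("cv_preference must be in [0, 1]")
        if self.breathgroup_length < 1:
            raise ValueError("breathgroup_length must be >= 1")
        for name in ("speaker_intercept_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if self.markov_concentration <= 0:
            raise ValueError("markov_concentration must be > 0")
        if not (0.0 <= self.repetition_boost < 1.0):
            raise ValueError("repetition_boost must be in [0, 1)")

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for key in ("consonants", "vowels", "test_recording_speakers"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Generator bookkeeping: everything a recovery test needs."""

    lexicons: dict[str, list[str]]
    zipf_probs: dict[str, dict[str, float]]
    stationary_probs: dict[str, dict[str, float]]
    transitions: dict[str, np.ndarray]
    beta0: float
    beta_p: float
    beta_t: float
    speaker_intercepts: dict[str, float]
    token_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    recording_summary: pd.DataFrame = field(default_factory=pd.DataFrame)
    plant_log: dict[str, bool] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "lexicons": self.lexicons,
            "zipf_probs": self.zipf_probs,
            "stationary_probs": self.stationary_probs,
            "transitions": {s: m.tolist() for s, m in self.transitions.items()},
            "beta0": self.beta0,
            "beta_p": self.beta_p,
            "beta_t": self.beta_t,
            "speaker_intercepts": self.speaker_intercepts,
            "token_truth": self.token_truth.to_dict(orient="list"),
            "recording_summary": self.recording_summary.to_dict(orient="list"),
            "plant_log": self.plant_log,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# Lexicons and probabilities
# ---------------------------------------------------------------------------

def _syllable_pool(config: SyntheticConfig, rng: np.random.Generator, n_needed: int) -> list[str]:
    """Draw ``n_needed`` distinct CV / CVC syllables (CV with probability
    ``cv_preference``, falling back to CVC once the CV space is exhausted).

    The pool is kept prefix-free at the phone level: a CV syllable and a CVC
    syllable sharing that CV onset never coexist.  This keeps the planted
    attestation fraction of the synthetic reference corpus sharp — otherwise
    planting a CVC type would accidentally attest its CV prefix.  When the
    prefix-free constraint cannot accommodate the requested CV share (large
    pools over a finite inventory), the CV count is capped at the largest
    feasible value and the remainder is CVC.
    """
    n_c, n_v = len(config.consonants), len(config.vowels)
    n_cv_total = n_c * n_v
    capacity = n_cv_total * (1 + n_c)  # every onset used for 1 CV or n_c CVCs
    if n_needed > n_cv_total * n_c:
        raise ValueError(
            f"phone inventory supports at most {n_cv_total * n_c} prefix-free "
            f"syllables, need {n_needed}"
        )
    # capacity(n_cv) = n_cv + (n_cv_total - n_cv) * n_c must cover n_needed
    n_cv_cap = (n_cv_total * n_c - n_needed) // (n_c - 1) if n_c > 1 else n_cv_total
    n_cv = min(round(config.cv_preference * n_needed), n_cv_total, max(0, n_cv_cap))
    n_cvc = n_needed - n_cv

    cv = [(c, v) for c in config.consonants for v in config.vowels]
    order = rng.permutation(n_cv_total)
    chosen_cv = [cv[i] for i in order[:n_cv]]
    free_onsets = [cv[i] for i in order[n_cv:]]
    cvc = [(c, v, c2) for (c, v) in free_onsets for c2 in config.consonants]
    cvc_order = rng.permutation(len(cvc))
    chosen_cvc = [cvc[i] for i in cvc_order[:n_cvc]]
    pool = ["".join(s) for s in chosen_cv] + ["".join(s) for s in chosen_cvc]
    perm = rng.permutation(len(pool))
    return [pool[i] for i in perm]


def generate_lexicons(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> dict[str, list[str]]:
    """Per-speaker syllable lexicons with the target mean pairwise overlap.

    All speakers share a core of ``round(overlap_target * lexicon_size)``
    types; the remainder of each lexicon is speaker-private.  With equal
    lexicon sizes every pairwise Szymkiewicz–Simpson coefficient equals
    core/size exactly.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L = config.lexicon_size
    core_size = round(config.overlap_target * L)
    n_needed = core_size + config.n_speakers * (L - core_size)
    cap = len(config.consonants) * len(config.vowels) * (1 + len(config.consonants))
    if n_needed > cap:
        max_private = (cap - core_size) // config.n_speakers
        feasible = max(0.0, (L - max_private) / L)
        raise ValueError(
            f"overlap_target {config.overlap_target} infeasible for "
            f"{config.n_speakers} speakers x {L} types with this inventory; "
            f"feasible targets >= {feasible:.3f}"
        )
    pool = _syllable_pool(config, rng, n_needed)
    core = pool[:core_size]
    rest = pool[core_size:]
    lexicons: dict[str, list[str]] = {}
    per = L - core_size
    for i in range(config.n_speakers):
        private = rest[i * per : (i + 1) * per]
        lexicons[f"S{i + 1:02d}"] = sorted(core + private)
    return lexicons


def assign_zipf_frequencies(
    lexicon: Sequence[str], s: float, rng: np.random.Generator
) -> dict[str, float]:
    """Zipfian probabilities p_r ∝ r^(-s) over a random permutation."""
    if s < 0:
        raise ValueError("zipf exponent must be >= 0")
    K = len(lexicon)
    weights = np.arange(1, K + 1, dtype=float) ** (-s)
    probs = weights / weights.sum()
    order = rng.permutation(K)
    return {lexicon[order[r]]: float(probs[r]) for r in range(K)}


def _transition_matrix(
    marginal: np.ndarray,
    concentration: float,
    repetition_boost: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rows ~ Dirichlet(concentration), elementwise reweighted toward the
    Zipfian marginal, renormalized, then mixed with ``repetition_boost``
    mass on the diagonal (immediate repetition of the current syllable)."""
    K = marginal.size
    rows = rng.dirichlet(np.full(K, concentration), size=K)
    T = rows * marginal[None, :]
    T /= T.sum(axis=1, keepdims=True)
    if repetition_boost > 0:
        T = (1.0 - repetition_boost) * T + repetition_boost * np.eye(K)
    return T


def _stationary(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible stochastic matrix."""
    vals, vecs = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    if pi.sum() < 0:
        pi = -pi
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def generate_corpus(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Full synthetic corpus plus the ground truth that generated it.

    Durations follow
    ``beta0 + u_speaker + beta_p * z(log P(S0)) + beta_t * z(log P(S0|S-1)) + eps``
    with the z-scores taken over the generated tokens (context term omitted
    for breathgroup-initial tokens, which have no within-group predecessor),
    ``eps ~ N(0, noise_sd)``, negative draws resampled.
    """
    rng = np.random.default_rng(config.seed)
    lexicons = generate_lexicons(config, rng)
    speakers = list(lexicons)

    zipf_probs: dict[str, dict[str, float]] = {}
    stationary_probs: dict[str, dict[str, float]] = {}
    transitions: dict[str, np.ndarray] = {}
    intercepts: dict[str, float] = {}
    for sid in speakers:
        lex = lexicons[sid]
        zipf = assign_zipf_frequencies(lex, config.zipf_exponent, rng)
        marginal = np.array([zipf[lab] for lab in lex])
        T = _transition_matrix(
            marginal, config.markov_concentration, config.repetition_boost, rng
        )
        pi = _stationary(T)
        zipf_probs[sid] = zipf
        transitions[sid] = T
        stationary_probs[sid] = {lab: float(pi[k]) for k, lab in enumerate(lex)}
        intercepts[sid] = float(rng.normal(0.0, config.speaker_intercept_sd))

    recordings: list[tuple[str, str, str]] = []  # (recording_id, speaker_id, condition)
    for i, sid in enumerate(speakers):
        recordings.append((f"{sid}_main", sid, "main"))
        if i in config.test_recording_speakers:
            recordings.append((f"{sid}_test", sid, "test"))

    draw_rows: list[dict] = []
    for rid, sid, cond in recordings:
        lex = lexicons[sid]
        index = {lab: k for k, lab in enumerate(lex)}
        T = transitions[sid]
        pi = np.array([stationary_probs[sid][lab] for lab in lex])
        remaining = config.tokens_per_recording
        bg = 0
        while remaining > 0:
            length = 1 + rng.poisson(config.breathgroup_length - 1)
            length = min(length, remaining)
            prev_k: int | None = None
            for pos in range(length):
                if prev_k is None:
                    k = int(rng.choice(len(lex), p=pi))
                    p_trans = math.nan
                else:
                    k = int(rng.choice(len(lex), p=T[prev_k]))
                    p_trans = float(T[prev_k, k])
                draw_rows.append(
                    {
                        "recording_id": rid,
                        "speaker_id": sid,
                        "condition": cond,
                        "breathgroup_index": bg,
                        "position_in_breathgroup": pos,
                        "label": lex[k],
                        "p_s0_true": stationary_probs[sid][lex[k]],
                        "p_trans_true": p_trans,
                    }
                )
                prev_k = k
            remaining -= length
            bg += 1

    truth = pd.DataFrame(draw_rows)
    logp = np.log(truth["p_s0_true"].to_numpy())
    z_p = (logp - logp.mean()) / logp.std(ddof=1)
    logt = np.log(truth["p_trans_true"].to_numpy())
    mask = ~np.isnan(logt)
    z_t = np.full_like(logt, np.nan)
    z_t[mask] = (logt[mask] - logt[mask].mean()) / logt[mask].std(ddof=1)
    truth["z_p_true"] = z_p
    truth["z_t_true"] = z_t

    mean_struct = (
        config.beta0
        + truth["speaker_id"].map(intercepts).to_numpy()
        + config.beta_p * z_p
        + config.beta_t * np.where(mask, z_t, 0.0)
    )
    durations = np.empty(len(truth))
    n_resampled = 0
    for i, mu in enumerate(mean_struct):
        d = rng.normal(mu, config.noise_sd)
        while d <= 0:
            n_resampled += 1
            d = rng.normal(mu, config.noise_sd)
        durations[i] = d
    if n_resampled > 0.01 * len(truth):
        logger.warning(
            "resampled %d/%d duration draws; heavy truncation bias likely",
            n_resampled,
            len(truth),
        )
    truth["duration_s"] = durations

    tokens: list[SyllableToken] = []
    rec_info: dict[str, RecordingInfo] = {}
    cursor: dict[str, float] = {}
    last_bg: dict[str, int] = {}
    for row, dur in zip(draw_rows, durations):
        rid = row["recording_id"]
        t0 = cursor.get(rid, 0.0)
        if rid in last_bg and row["breathgroup_index"] != last_bg[rid]:
            t0 += config.pause_gap_s
        last_bg[rid] = row["breathgroup_index"]
        tokens.append(
            SyllableToken(
                label=row["label"],
                start_s=t0,
                end_s=t0 + dur,
                speaker_id=row["speaker_id"],
                recording_id=rid,
                condition=row["condition"],
                breathgroup_index=row["breathgroup_index"],
                position_in_breathgroup=row["position_in_breathgroup"],
            )
        )
        cursor[rid] = t0 + dur
    for rid, sid, cond in recordings:
        rec_info[rid] = RecordingInfo(speaker_id=sid, condition=cond, duration_s=cursor[rid])
    corpus = Corpus(tokens=tokens, recordings=rec_info)

    summary = (
        truth.groupby("recording_id")
        .agg(
            syllable_tokens=("label", "size"),
            syllable_types=("label", "nunique"),
            breathgroups=("breathgroup_index", "nunique"),
        )
        .reset_index()
    )
    gt = GroundTruth(
        lexicons=lexicons,
        zipf_probs=zipf_probs,
        stationary_probs=stationary_probs,
        transitions=transitions,
        beta0=config.beta0,
        beta_p=config.beta_p,
        beta_t=config.beta_t,
        speaker_intercepts=intercepts,
        token_truth=truth,
        recording_summary=summary,
    )
    return corpus, gt


# ---------------------------------------------------------------------------
# Reference corpus generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceOptions:
    """Options for the synthetic reference (native-language) phone stream."""

    shared_fraction: float = 0.6
    vocabulary_size: int = 200
    n_utterances: int = 300
    words_per_utterance: float = 8.0
    zipf_exponent: float = 1.0
    filler_phones: tuple[str, ...] = DEFAULT_FILLER_PHONES
    planted_word_bigrams: tuple[tuple[str, str], ...] = ()
    #: strength of the rank coupling between a planted type's reference
    #: frequency and its corpus frequency (0 = independent); natural-language
    #: borrowing makes the two moderately rank-correlated
    frequency_coupling: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0, 1]")
        if not (0.0 <= self.frequency_coupling <= 1.0):
            raise ValueError("frequency_coupling must be in [0, 1]")


def generate_reference_corpus(
    corpus_labels: Iterable[str],
    options: ReferenceOptions,
    seed: int = 0,
    tokenizer: PhoneTokenizer | None = None,
    corpus_counts: Mapping[str, int] | None = None,
) -> tuple[ReferencePhoneStream, dict[str, bool]]:
    """A reference phone stream planting a fraction of the corpus's types.

    A ``shared_fraction`` of the given syllable types is embedded as words of
    the reference (so they are attested by construction); all other words are
    built from a disjoint filler phone inventory, and planted words are never
    adjacent, so accidental attestation can arise only from substrings inside
    or across planted material (and is visible in the plant log as a
    ``False`` entry that :func:`~syllastats.lexicon_compare.attest_types`
    nevertheless reports attested).

    Returns the stream and the plant log {label: planted?}.
    """
    rng = np.random.default_rng(seed)
    tok = tokenizer or PhoneTokenizer()
    labels = sorted(set(corpus_labels))
    n_plant = round(options.shared_fraction * len(labels))
    if corpus_counts is not None and 0 < n_plant < len(labels):
        # frequent types are the likelier borrowings: weight the plant
        # selection by corpus counts, so the token-level attestation rate
        # exceeds the type-level rate as in natural borrowing
        w = np.array([1.0 + corpus_counts.get(lab, 0) for lab in labels])
        planted = [
            labels[i]
            for i in rng.choice(len(labels), size=n_plant, replace=False, p=w / w.sum())
        ]
    else:
        planted = [labels[i] for i in rng.permutation(len(labels))[:n_plant]]
    plant_log = {lab: (lab in set(planted)) for lab in labels}

    fillers: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    guard = 0
    while len(fillers) < options.vocabulary_size and guard < 100_000:
        guard += 1
        length = int(rng.integers(2, 5))
        w = tuple(rng.choice(options.filler_phones, size=length))
        if w not in seen:
            seen.add(w)
            fillers.append(w)

    word_seqs: list[tuple[str, ...]] = [tok(lab) for lab in planted]
    word_forms: list[str] = list(planted)
    is_planted: list[bool] = [True] * len(planted)
    for bg in options.planted_word_bigrams:
        word_seqs.append(tok(bg[0]) + tok(bg[1]))
        word_forms.append(bg[0] + bg[1])
        is_planted.append(True)
    word_seqs += fillers
    word_forms += ["".join(w) for w in fillers]
    is_planted += [False] * len(fillers)

    n_words = len(word_seqs)
    weights = np.arange(1, n_words + 1, dtype=float) ** (-options.zipf_exponent)
    probs = weights / weights.sum()
    order = rng.permutation(n_words)
    word_probs = np.empty(n_words)
    word_probs[order] = probs
    if corpus_counts is not None and options.frequency_coupling > 0 and planted:
        # redistribute the planted words' weights among themselves so that
        # reference frequency rank-correlates with corpus frequency
        idx = np.arange(len(planted))
        counts = np.array([corpus_counts.get(lab, 0) for lab in planted], dtype=float)
        c_rank = stats_rankdata(counts)
        key = options.frequency_coupling * _zscore(c_rank) + (
            1.0 - options.frequency_coupling
        ) * rng.normal(size=len(planted))
        planted_weights = np.sort(word_probs[idx])  # ascending
        word_probs[idx[np.argsort(key)]] = planted_weights
        word_probs /= word_probs.sum()

    chunks: list[tuple[str, ...]] = []
    spans: list[list[tuple[int, int]]] = []
    lexicon: dict[tuple[str, ...], tuple[str, int]] = {}
    planted_idx = [i for i, p in enumerate(is_planted) if p]
    filler_idx = [i for i, p in enumerate(is_planted) if not p]
    must_place = list(planted_idx)  # every planted word appears at least once

    for u in range(options.n_utterances):
        n_in_utt = max(2, 1 + int(rng.poisson(options.words_per_utterance - 1)))
        chosen: list[int] = []
        prev_planted = False
        for _ in range(n_in_utt):
            if must_place:
                wi = must_place.pop()
                if prev_planted and filler_idx:
                    chosen.append(int(rng.choice(filler_idx)))
                chosen.append(wi)
                prev_planted = True
                continue
            wi = int(rng.choice(n_words, p=word_probs))
            if is_planted[wi] and prev_planted:
                if filler_idx:
                    chosen.append(int(rng.choice(filler_idx)))
            chosen.append(wi)
            prev_planted = is_planted[wi]
        phones: list[str] = []
        cur_spans: list[tuple[int, int]] = []
        for wi in chosen:
            start = len(phones)
            phones.extend(word_seqs[wi])
            cur_spans.append((start, len(phones)))
            key = word_seqs[wi]
            prev = lexicon.get(key, (word_forms[wi], 0))
            lexicon[key] = (prev[0], prev[1] + 1)
        chunks.append(tuple(phones))
        spans.append(cur_spans)

    if must_place:  # not enough utterance slots: append one utterance per leftover
        for wi in must_place:
            chunks.append(tuple(word_seqs[wi]))
            spans.append([(0, len(word_seqs[wi]))])
            key = word_seqs[wi]
            prev = lexicon.get(key, (word_forms[wi], 0))
            lexicon[key] = (prev[0], prev[1] + 1)

    stream = ReferencePhoneStream(chunks=chunks, word_spans=spans, word_lexicon=lexicon)
    return stream, plant_log


# ---------------------------------------------------------------------------
# Individual-vs-aggregate frequency simulation
# ---------------------------------------------------------------------------

def simulate_individual_vs_aggregate(
    config: SyntheticConfig,
    overlap_grid: Sequence[float] = (0.1, 0.5, 0.9),
    n_seeds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """How lexicon overlap degrades the individual-vs-pooled probability match.

    For each overlap level, corpora are generated with speaker-specific
    probability profiles, per-speaker and pooled empirical syllable
    probabilities are computed, and their Spearman correlation over each
    speaker's observed types is averaged.  With little overlap each speaker's
    lexicon forms its own cluster in the pooled counts, so pooled and
    individual probabilities agree; as overlap grows, distinct profiles mix
    and the correlation drops.
    """
    if len(overlap_grid) < 1:
        raise ValueError("need at least one overlap level")
    rows = []
    for level in overlap_grid:
        corrs = []
        for j in range(n_seeds):
            sub_seed = (seed * 1_000_003 + int(level * 1000) * 9_973 + j) % (2**31 - 1)
            cfg = replace(config, overlap_target=float(level), seed=sub_seed)
            corpus, _ = generate_corpus(cfg)
            pooled = count_ngrams(corpus, 1)
            sp_corrs = []
            for sid in corpus.speakers():
                sp = count_ngrams(corpus, 1, scope="Sp", speaker_id=sid)
                labels = sorted(g[0] for g in sp.counts)
                if len(labels) < 3:
                    continue
                x = [sp[(lab,)] / sp.total for lab in labels]
                y = [pooled[(lab,)] / pooled.total for lab in labels]
                if len(set(x)) < 2 or len(set(y)) < 2:
                    sp_corrs.append(1.0 if x == y else math.nan)
                else:
                    sp_corrs.append(spearman_rho(x, y))
            corrs.append(float(np.nanmean(sp_corrs)))
        rows.append(
            {
                "overlap_target": float(level),
                "mean_corr": float(np.mean(corrs)),
                "sd_corr": float(np.std(corrs, ddof=1)) if len(corrs) > 1 else math.nan,
                "n_seeds": n_seeds,
            }
        )
    df = pd.DataFrame(rows).sort_values("overlap_target").reset_index(drop=True)
    df.attrs["monotone_decreasing"] = bool(
        df["mean_corr"].iloc[-1] < df["mean_corr"].iloc[0]
    )
    return df
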