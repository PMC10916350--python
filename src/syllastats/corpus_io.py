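"""Reading, validating, segmenting and summarizing syllable-annotated corpora.

The canonical in-memory objects are :class:`Corpus` (an ordered collection of
:class:`SyllableToken`) and :class:`ReferencePhoneStream` (pause-delimited
phone sequences standing in for a large spontaneous-speech reference corpus).
Recordings come in as Praat TextGrids (one recording per file, a syllable
interval tier plus either a breathgroup tier or pause labels on the syllable
tier) or as a flat TSV table.

Time convention: seconds, intervals half-open [start, end); durations are
taken from the annotation times, never re-measured from audio.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Interval labels treated as pauses / breathing / hesitations by default.
DEFAULT_PAUSE_LABELS = frozenset({"", "<p>", "<usb>", "sil"})

CORPUS_COLUMNS = [
    "recording_id",
    "speaker_id",
    "condition",
    "breathgroup_index",
    "position_in_breathgroup",
    "label",
    "start_s",
    "end_s",
]

_TIME_ATOL = 1e-6


class CorpusValidationError(ValueError):
    """A corpus or table violates a structural invariant."""


class ConfigurationError(ValueError):
    """A requested tier, column or option does not exist."""


@dataclass(frozen=True)
class SyllableToken:
    """One annotated syllable interval.

    ``label`` is an opaque X-SAMPA string (no whitespace, no pause marker);
    ``breathgroup_index`` counts pause-delimited groups within the recording
    and ``position_in_breathgroup`` counts tokens within the group from 0.
    """

    label: str
    start_s: float
    end_s: float
    speaker_id: str
    recording_id: str
    condition: str = "main"
    breathgroup_index: int = 0
    position_in_breathgroup: int = 0

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __post_init__(self) -> None:
        if not self.label or re.search(r"\s", self.label):
            raise CorpusValidationError(
                f"invalid syllable label {self.label!r} "
                f"at {self.start_s:.6f}s in {self.recording_id}"
            )
        if self.end_s <= self.start_s:
            raise CorpusValidationError(
                f"degenerate interval [{self.start_s:.6f}, {self.end_s:.6f}] "
                f"for {self.label!r} in {self.recording_id}"
            )
        if self.start_s < 0:
            raise CorpusValidationError(
                f"negative start time {self.start_s:.6f} in {self.recording_id}"
            )


@dataclass(frozen=True)
class RecordingInfo:
    speaker_id: str
    condition: str = "main"
    duration_s: float | None = None


@dataclass
class Corpus:
    """Ordered syllable tokens plus per-recording metadata."""

    tokens: list[SyllableToken] = field(default_factory=list)
    recordings: dict[str, RecordingInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev: dict[str, SyllableToken] = {}
        positions: dict[tuple[str, int], int] = {}
        for tok in self.tokens:
            if tok.recording_id not in self.recordings:
                raise CorpusValidationError(
                    f"token {tok.label!r} references unknown recording "
                    f"{tok.recording_id!r}"
                )
            last = prev.get(tok.recording_id)
            if last is not None and tok.start_s < last.start_s - _TIME_ATOL:
                raise CorpusValidationError(
                    f"tokens out of temporal order in {tok.recording_id} "
                    f"near {tok.start_s:.6f}s"
                )
            prev[tok.recording_id] = tok
            key = (tok.recording_id, tok.breathgroup_index)
            expected = positions.get(key, 0)
            if tok.position_in_breathgroup != expected:
                raise CorpusValidationError(
                    f"non-consecutive position_in_breathgroup "
                    f"({tok.position_in_breathgroup}, expected {expected}) in "
                    f"{tok.recording_id} breathgroup {tok.breathgroup_index}"
                )
            positions[key] = expected + 1

    def __len__(self) -> int:
        return len(self.tokens)

    def speakers(self) -> list[str]:
        seen: dict[str, None] = {}
        for info in self.recordings.values():
            seen.setdefault(info.speaker_id, None)
        return list(seen)

    def tokens_for_speaker(self, speaker_id: str) -> list[SyllableToken]:
        return [t for t in self.tokens if t.speaker_id == speaker_id]

    def breathgroups(self) -> list[list[SyllableToken]]:
        """Tokens grouped into breathgroups, in corpus order."""
        groups: dict[tuple[str, int], list[SyllableToken]] = {}
        for tok in self.tokens:
            groups.setdefault((tok.recording_id, tok.breathgroup_index), []).append(tok)
        return list(groups.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "recording_id": t.recording_id,
                "speaker_id": t.speaker_id,
                "condition": t.condition,
                "breathgroup_index": t.breathgroup_index,
                "position_in_breathgroup": t.position_in_breathgroup,
                "label": t.label,
                "start_s": t.start_s,
                "end_s": t.end_s,
                "duration_s": t.duration_s,
            }
            for t in self.tokens
        ]
        return pd.DataFrame(rows, columns=CORPUS_COLUMNS + ["duration_s"])

    def merge(self, other: "Corpus") -> "Corpus":
        recs = dict(self.recordings)
        for rid, info in other.recordings.items():
            if rid in recs and recs[rid] != info:
                raise CorpusValidationError(f"conflicting metadata for recording {rid!r}")
            recs[rid] = info
        return Corpus(tokens=self.tokens + other.tokens, recordings=recs)


@dataclass
class ReferencePhoneStream:
    """Pause-delimited phone sequences of a reference (native-language) corpus.

    ``chunks`` are maximal stretches between pauses/breathing/hesitations;
    word boundaries inside a chunk, when known, are kept as index spans so
    that full-word lookups remain possible while sequence matching ignores
    them.  ``word_lexicon`` maps a word's phone string to its orthographic
    form and corpus count.
    """

    chunks: list[tuple[str, ...]] = field(default_factory=list)
    word_spans: list[list[tuple[int, int]]] = field(default_factory=list)
    word_lexicon: dict[tuple[str, ...], tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.word_spans and len(self.word_spans) != len(self.chunks):
            raise CorpusValidationError("word_spans must align with chunks")
        for chunk, spans in zip(self.chunks, self.word_spans or []):
            last_end = 0
            for s, e in spans:
                if not (0 <= s < e <= len(chunk)) or s < last_end:
                    raise CorpusValidationError(
                        f"invalid word span ({s}, {e}) in chunk of length {len(chunk)}"
                    )
                last_end = e

    @property
    def n_phones(self) -> int:
        return sum(len(c) for c in self.chunks)


# ---------------------------------------------------------------------------
# Praat TextGrid support (long and short text formats)
# ---------------------------------------------------------------------------

@dataclass
class TextGridInterval:
    xmin: float
    xmax: float
    text: str


@dataclass
class TextGridTier:
    name: str
    intervals: list[TextGridInterval]


def _decode_textgrid(path: Path) -> str:
    raw = Path(path).read_bytes()
    for enc in ("utf-8-sig", "utf-16"):
        try:
            text = raw.decode(enc)
        except (UnicodeDecodeError, UnicodeError):
            continue
        if "TextGrid" in text:
            return text
    return raw.decode("latin-1")


_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")
_QUOTED_RE = re.compile(r'"((?:[^"]|"")*)"')


def _parse_textgrid(text: str) -> list[TextGridTier]:
    """Parse interval tiers from a TextGrid in long or short text format.

    Both formats reduce to the same stream of quoted strings and numbers once
    the decorative ``item []:`` / ``key =`` scaffolding is ignored, so a
    single token-stream parser handles them.
    """
    # bracketed indices ("item [2]:", "intervals [13]:") are decoration, not data
    text = re.sub(r"\[\s*\d*\s*\]", " ", text)
    tokens: list[tuple[str, object]] = []
    pos = 0
    while pos < len(text):
        q = _QUOTED_RE.match(text, pos)
        if q:
            tokens.append(("str", q.group(1).replace('""', '"')))
            pos = q.end()
            continue
        n = _NUM_RE.match(text, pos)
        if n and (pos == 0 or not (text[pos - 1].isalnum() or text[pos - 1] in "._")):
            tokens.append(("num", float(n.group(0))))
            pos = n.end()
            continue
        pos += 1

    # stream: "ooTextFile" "TextGrid" xmin xmax <exists?> size then per tier:
    # "IntervalTier"|"TextTier" name xmin xmax n then n * (xmin xmax "text")
    idx = 0

    def next_of(kind: str):
        nonlocal idx
        while idx < len(tokens) and tokens[idx][0] != kind:
            idx += 1
        if idx >= len(tokens):
            raise CorpusValidationError("truncated TextGrid file")
        idx += 1
        return tokens[idx - 1][1]

    header = next_of("str")
    if header != "ooTextFile":
        raise CorpusValidationError("not a Praat text file")
    if next_of("str") != "TextGrid":
        raise CorpusValidationError("not a TextGrid")

    tiers: list[TextGridTier] = []
    while True:
        try:
            kind = next_of("str")
        except CorpusValidationError:
            break
        if kind not in ("IntervalTier", "TextTier"):
            continue
        name = str(next_of("str"))
        next_of("num")  # tier xmin
        next_of("num")  # tier xmax
        n_items = int(next_of("num"))
        intervals: list[TextGridInterval] = []
        if kind == "IntervalTier":
            for _ in range(n_items):
                xmin = float(next_of("num"))
                xmax = float(next_of("num"))
                text_ = str(next_of("str"))
                intervals.append(TextGridInterval(xmin, xmax, text_))
        else:  # point tier: skip its (time, mark) pairs
            for _ in range(n_items):
                next_of("num")
                next_of("str")
        tiers.append(TextGridTier(name=name, intervals=intervals))
    return tiers


def write_textgrid(
    path: str | Path,
    tiers: Mapping[str, Sequence[tuple[float, float, str]]],
    xmax: float | None = None,
) -> None:
    """Write interval tiers as a long-format TextGrid (test-fixture writer).

    Gaps between supplied intervals are filled with empty-label intervals so
    that Praat-style tier continuity holds.
    """
    all_times = [t for ivs in tiers.values() for iv in ivs for t in iv[:2]]
    gmax = xmax if xmax is not None else (max(all_times) if all_times else 1.0)
    out = io.StringIO()
    out.write('File type = "ooTextFile"\nObject class = "TextGrid"\n\n')
    out.write(f"xmin = 0\nxmax = {gmax:.6f}\ntiers? <exists>\nsize = {len(tiers)}\n")
    out.write("item []:\n")
    for i, (name, ivs) in enumerate(tiers.items(), start=1):
        filled: list[tuple[float, float, str]] = []
        cur = 0.0
        for s, e, lab in sorted(ivs):
            if s > cur + _TIME_ATOL:
                filled.append((cur, s, ""))
            filled.append((s, e, lab))
            cur = e
        if cur < gmax - _TIME_ATOL:
            filled.append((cur, gmax, ""))
        if not filled:
            filled = [(0.0, gmax, "")]
        out.write(f"    item [{i}]:\n")
        out.write('        class = "IntervalTier"\n')
        out.write(f'        name = "{name}"\n')
        out.write(f"        xmin = 0\n        xmax = {gmax:.6f}\n")
        out.write(f"        intervals: size = {len(filled)}\n")
        for j, (s, e, lab) in enumerate(filled, start=1):
            out.write(f"        intervals [{j}]:\n")
            out.write(f"            xmin = {s:.6f}\n            xmax = {e:.6f}\n")
            out.write(f'            text = "{lab}"\n')
    Path(path).write_text(out.getvalue(), encoding="utf-8")


def read_textgrid(
    path: str | Path,
    syllable_tier: str = "syllable",
    breathgroup_tier: str | None = None,
    pause_labels: Iterable[str] = DEFAULT_PAUSE_LABELS,
    recording_id: str | None = None,
    speaker_id: str | None = None,
    condition: str = "main",
) -> Corpus:
    """Read one recording from a Praat TextGrid.

    Non-empty, non-pause intervals on ``syllable_tier`` become tokens.
    Breathgroups come from ``breathgroup_tier`` intervals when given (a token
    belongs to the group containing its midpoint), otherwise from splitting
    the syllable tier at pause-labelled or empty intervals.  Consecutive
    pauses count as a single boundary.
    """
    path = Path(path)
    tiers = _parse_textgrid(_decode_textgrid(path))
    by_name = {t.name: t for t in tiers}
    if syllable_tier not in by_name:
        raise ConfigurationError(
            f"tier {syllable_tier!r} not found in {path.name}; "
            f"available tiers: {sorted(by_name)}"
        )
    pause_set = set(pause_labels)
    rid = recording_id or path.stem
    sid = speaker_id or rid
    syl = sorted(by_name[syllable_tier].intervals, key=lambda iv: iv.xmin)
    for a, b in zip(syl, syl[1:]):
        if b.xmin < a.xmax - _TIME_ATOL:
            raise CorpusValidationError(
                f"overlapping intervals on tier {syllable_tier!r}: "
                f"[{a.xmin:.6f}, {a.xmax:.6f}] and [{b.xmin:.6f}, {b.xmax:.6f}]"
            )

    bg_edges: list[float] | None = None
    if breathgroup_tier is not None:
        if breathgroup_tier not in by_name:
            raise ConfigurationError(
                f"tier {breathgroup_tier!r} not found in {path.name}; "
                f"available tiers: {sorted(by_name)}"
            )
        bg_ivs = [
            iv
            for iv in sorted(by_name[breathgroup_tier].intervals, key=lambda iv: iv.xmin)
            if iv.text.strip() not in pause_set
        ]
        bg_edges = [iv.xmin for iv in bg_ivs] + [float("inf")]

    tokens: list[SyllableToken] = []
    bg_index = 0
    pos = 0
    started = False
    for iv in syl:
        lab = iv.text.strip()
        if lab in pause_set:
            if started and pos > 0 and bg_edges is None:
                bg_index += 1
                pos = 0
            continue
        if bg_edges is not None:
            mid = 0.5 * (iv.xmin + iv.xmax)
            new_bg = max(0, sum(1 for edge in bg_edges[1:-1] if edge <= mid))
            # recompute position when the breathgroup changes
            if started and new_bg != bg_index:
                pos = 0
            bg_index = new_bg
        started = True
        tokens.append(
            SyllableToken(
                label=lab,
                start_s=iv.xmin,
                end_s=iv.xmax,
                speaker_id=sid,
                recording_id=rid,
                condition=condition,
                breathgroup_index=bg_index,
                position_in_breathgroup=pos,
            )
        )
        pos += 1
    if not tokens:
        logger.warning("no syllable tokens found in %s", path.name)
        return Corpus(tokens=[], recordings={})
    duration = max(iv.xmax for iv in syl)
    tokens = _renumber_breathgroups(tokens)
    return Corpus(
        tokens=tokens,
        recordings={rid: RecordingInfo(speaker_id=sid, condition=condition, duration_s=duration)},
    )


def _renumber_breathgroups(tokens: list[SyllableToken]) -> list[SyllableToken]:
    """Make breathgroup indices dense (0, 1, ...) per recording."""
    out: list[SyllableToken] = []
    mapping: dict[tuple[str, int], int] = {}
    counters: dict[str, int] = {}
    for tok in tokens:
        key = (tok.recording_id, tok.breathgroup_index)
        if key not in mapping:
            mapping[key] = counters.get(tok.recording_id, 0)
            counters[tok.recording_id] = mapping[key] + 1
        out.append(replace(tok, breathgroup_index=mapping[key]))
    return out


# ---------------------------------------------------------------------------
# Canonical TSV interchange
# ---------------------------------------------------------------------------

def read_corpus_table(path: str | Path) -> Corpus:
    """Read the canonical corpus TSV; rows are re-sorted by (recording, start)."""
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "recording_id": str, "speaker_id": str})
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"corpus table missing columns: {missing}")
    df = df.sort_values(["recording_id", "start_s"], kind="mergesort").reset_index(drop=True)
    dup = df.duplicated(subset=["recording_id", "start_s"])
    if dup.any():
        raise CorpusValidationError(
            f"duplicate (recording_id, start_s) at input row {int(df.index[dup][0]) + 2}"
        )
    tokens: list[SyllableToken] = []
    recordings: dict[str, RecordingInfo] = {}
    for i, row in df.iterrows():
        try:
            tok = SyllableToken(
                label=str(row["label"]),
                start_s=float(row["start_s"]),
                end_s=float(row["end_s"]),
                speaker_id=str(row["speaker_id"]),
                recording_id=str(row["recording_id"]),
                condition=str(row["condition"]),
                breathgroup_index=int(row["breathgroup_index"]),
                position_in_breathgroup=int(row["position_in_breathgroup"]),
            )
        except (CorpusValidationError, ValueError) as exc:
            raise CorpusValidationError(f"row {i + 2}: {exc}") from exc
        tokens.append(tok)
        rid = tok.recording_id
        if rid not in recordings:
            recordings[rid] = RecordingInfo(speaker_id=tok.speaker_id, condition=tok.condition)
    for rid in recordings:
        ends = [t.end_s for t in tokens if t.recording_id == rid]
        recordings[rid] = replace(recordings[rid], duration_s=max(ends))
    return Corpus(tokens=tokens, recordings=recordings)


def write_corpus_table(corpus: Corpus, path: str | Path) -> None:
    """Write the canonical TSV (UTF-8, '.' decimal separator, 6-decimal times)."""
    df = corpus.to_frame()[CORPUS_COLUMNS]
    df = df.copy()
    for col in ("start_s", "end_s"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def summarize_corpus(corpus: Corpus) -> pd.DataFrame:
    """Per-recording summary: duration (s), syllable types, tokens, breathgroups."""
    if not corpus.tokens:
        raise CorpusValidationError("cannot summarize an empty corpus")
    df = corpus.to_frame()
    rows = []
    for rid, grp in df.groupby("recording_id", sort=False):
        info = corpus.recordings[rid]
        duration = info.duration_s if info.duration_s is not None else grp["end_s"].max()
        rows.append(
            {
                "recording_id": rid,
                "speaker_id": info.speaker_id,
                "condition": info.condition,
                "duration_s": duration,
                "syllable_types": grp["label"].nunique(),
                "syllable_tokens": len(grp),
                "breathgroups": grp["breathgroup_index"].nunique(),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reference phone streams
# ---------------------------------------------------------------------------

def read_reference_stream(
    path: str | Path,
    pause_markers: Iterable[str] = DEFAULT_PAUSE_LABELS,
) -> ReferencePhoneStream:
    """Read a reference phone stream from TSV or a plain phone file.

    TSV columns: utterance_id, position, phone, and optionally word_id and
    word_form.  Plain files hold whitespace-separated phones, one utterance
    per line.  Chunks split at every pause marker; runs of pauses collapse
    to one boundary.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise CorpusValidationError(f"empty reference stream file: {path.name}")
    pause_set = set(pause_markers)

    first = text.lstrip().splitlines()[0]
    if "\t" in first and "phone" in first:
        return _reference_from_table(pd.read_csv(path, sep="\t", dtype=str), pause_set)

    chunks: list[tuple[str, ...]] = []
    for line in text.splitlines():
        cur: list[str] = []
        for ph in line.split():
            if ph in pause_set:
                if cur:
                    chunks.append(tuple(cur))
                    cur = []
            else:
                cur.append(ph)
        if cur:
            chunks.append(tuple(cur))
    if not chunks:
        raise CorpusValidationError(f"reference stream {path.name} contains no phones")
    return ReferencePhoneStream(chunks=chunks)


def _reference_from_table(df: pd.DataFrame, pause_set: set[str]) -> ReferencePhoneStream:
    has_words = "word_id" in df.columns
    chunks: list[tuple[str, ...]] = []
    spans: list[list[tuple[int, int]]] = []
    lexicon: dict[tuple[str, ...], tuple[str, int]] = {}
    df = df.copy()
    df["position"] = df["position"].astype(int)
    for _, utt in df.groupby("utterance_id", sort=False):
        utt = utt.sort_values("position")
        cur: list[str] = []
        cur_spans: list[tuple[int, int]] = []
        word_buf: list[str] = []
        word_id = None
        word_form = None

        def flush_word() -> None:
            nonlocal word_buf, word_id, word_form
            if word_buf:
                start = len(cur) - len(word_buf)
                cur_spans.append((start, len(cur)))
                key = tuple(word_buf)
                form = word_form if word_form is not None else "".join(word_buf)
                prev = lexicon.get(key, (form, 0))
                lexicon[key] = (prev[0], prev[1] + 1)
            word_buf, word_id, word_form = [], None, None

        def flush_chunk() -> None:
            nonlocal cur, cur_spans
            flush_word()
            if cur:
                chunks.append(tuple(cur))
                spans.append(cur_spans)
            cur, cur_spans = [], []

        for _, row in utt.iterrows():
            ph = str(row["phone"])
            if ph in pause_set:
                flush_chunk()
                continue
            if has_words:
                wid = row.get("word_id")
                wid = None if pd.isna(wid) or str(wid) == "" else str(wid)
                if wid != word_id:
                    flush_word()
                    word_id = wid
                    wf = row.get("word_form")
                    word_form = None if pd.isna(wf) or str(wf) == "" else str(wf)
                if wid is not None:
                    word_buf.append(ph)
            cur.append(ph)
        flush_chunk()
    if not chunks:
        raise CorpusValidationError("reference stream contains no phones")
    return ReferencePhoneStream(
        chunks=chunks,
        word_spans=spans if has_words else [],
        word_lexicon=lexicon,
    )


def write_reference_stream(stream: ReferencePhoneStream, path: str | Path) -> None:
    """Write a reference stream as TSV with optional word columns."""
    rows = []
    word_counter = 0
    for ci, chunk in enumerate(stream.chunks):
        spans = stream.word_spans[ci] if stream.word_spans else []
        span_of: dict[int, tuple[int, tuple[int, int]]] = {}
        for span in spans:
            word_counter += 1
            for k in range(span[0], span[1]):
                span_of[k] = (word_counter, span)
        for pi, ph in enumerate(chunk):
            wid, span = span_of.get(pi, (None, None))
            form = ""
            if span is not None:
                key = tuple(chunk[span[0] : span[1]])
                form = stream.word_lexicon.get(key, ("", 0))[0]
            rows.append(
                {
                    "utterance_id": f"u{ci:05d}",
                    "position": pi,
                    "phone": ph,
                    "word_id": "" if wid is None else f"w{wid:06d}",
                    "word_form": form,
                }
            )
        rows.append(
            {
                "utterance_id": f"u{ci:05d}",
                "position": len(chunk),
                "phone": "<p>",
                "word_id": "",
                "word_form": "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, encoding="utf-8")
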