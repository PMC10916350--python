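import warnings

import numpy as np
import pytest

from syllastats.corpus_io import Corpus, RecordingInfo, SyllableToken
from syllastats.synthetic_data import SyntheticConfig, generate_corpus

warnings.filterwarnings("ignore", module="statsmodels")


def build_corpus(sequences, speaker_ids=None, durations=None):
    """Corpus from explicit breathgroup label sequences.

    ``sequences`` maps recording_id -> list of breathgroups (lists of labels).
    """
    tokens = []
    recordings = {}
    for rid, groups in sequences.items():
        sid = (speaker_ids or {}).get(rid, rid)
        recordings[rid] = RecordingInfo(speaker_id=sid)
        t = 0.0
        for bg_idx, group in enumerate(groups):
            for pos, label in enumerate(group):
                dur = durations[label] if durations else 0.2
                tokens.append(
                    SyllableToken(
                        label=label,
                        start_s=t,
                        end_s=t + dur,
                        speaker_id=sid,
                        recording_id=rid,
                        breathgroup_index=bg_idx,
                        position_in_breathgroup=pos,
                    )
                )
                t += dur
            t += 0.4  # pause
    return Corpus(tokens=tokens, recordings=recordings)


def random_toy_corpus(rng, max_tokens=50, alphabet=("na", "ra", "la", "ba", "do")):
    """Small random corpus for brute-force oracle comparisons."""
    n_rec = int(rng.integers(1, 4))
    sequences = {}
    total = 0
    for r in range(n_rec):
        groups = []
        n_groups = int(rng.integers(1, 4))
        for _ in range(n_groups):
            length = int(rng.integers(1, 8))
            length = min(length, max_tokens - total)
            if length <= 0:
                break
            groups.append([str(rng.choice(alphabet)) for _ in range(length)])
            total += length
        if groups:
            sequences[f"rec{r}"] = groups
    if not sequences:
        sequences = {"rec0": [[str(rng.choice(alphabet))]]}
    return build_corpus(sequences)


@pytest.fixture(scope="session")
def small_synthetic():
    """One modest synthetic corpus with ground truth, reused across tests."""
    cfg = SyntheticConfig(
        n_speakers=4,
        lexicon_size=30,
        tokens_per_recording=300,
        test_recording_speakers=(0,),
        seed=42,
    )
    corpus, truth = generate_corpus(cfg)
    return cfg, corpus, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
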