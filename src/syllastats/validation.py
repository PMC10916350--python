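"""Parameter-recovery and error-control simulations for the whole pipeline.

Each driver regenerates synthetic corpora with known ground truth, runs the
estimation/modeling stages, and summarizes how well the known quantities are
recovered.  They are the package's evidence that the pipeline measures what
it claims to measure; the replicate counts and corpus sizes below are the
default study-scale conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import pandas as pd

from .corpus_io import Corpus
from .duration_model import (
    PREDICTOR_COLUMNS,
    build_model_table,
    fit_univariate_lmm,
    run_model_program,
)
from .lexicon_compare import PhoneTokenizer, attest_types, pairwise_speaker_overlap
from .synthetic_data import (
    ReferenceOptions,
    SyntheticConfig,
    generate_corpus,
    generate_reference_corpus,
)

#: 11 speakers, one ~455-token recording each: the ~5,000-token recovery scenario.
RECOVERY_CONFIG = SyntheticConfig(
    beta_t=0.0, tokens_per_recording=455, test_recording_speakers=()
)

#: Null scenario: no probability effect and no speaker variance, evaluated
#: in the same well-estimated regime as the discrimination check (long
#: recordings).  With short recordings the sparse-bigram predictors put most
#: of their variance on a handful of singleton-count tokens; the |t| > 2
#: convention (no degrees-of-freedom correction) is then anti-conservative
#: for reasons unrelated to the modeling stage under test.
NULL_CONFIG = SyntheticConfig(
    beta_p=0.0,
    beta_t=0.0,
    speaker_intercept_sd=0.0,
    tokens_per_recording=1820,
    test_recording_speakers=(),
)

#: Equal-magnitude generating effects (the discrimination question is then
#: symmetric in the two generating predictors) and recordings long enough
#: (~20k tokens over 11 speakers) for per-speaker bigram probabilities to be
#: well-estimated; with short recordings the fitted conditional predictors
#: are dominated by count noise and the comparison measures estimation
#: error, not model discrimination.
DISCRIMINATION_CONFIG = SyntheticConfig(
    beta_p=-0.010, beta_t=-0.010, tokens_per_recording=1820, test_recording_speakers=()
)


def _sub_seed(seed: int, rep: int) -> int:
    return (seed * 1_000_003 + rep * 7919 + 17) % (2**31 - 1)


def parameter_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    config: SyntheticConfig = RECOVERY_CONFIG,
    reml: bool = True,
) -> pd.DataFrame:
    """Recover the generative P(S0) slope from fresh corpora.

    Each replicate generates a corpus, fits duration on the generator's own
    standardized log-probability predictor with a speaker random intercept,
    and records the estimate, its SE, the t-value, and whether the
    generative slope lies within estimate ± 2 SE.  REML estimation (the
    single-fit reporting estimator: with few speaker groups ML biases the
    variance components downward and hence the SEs).
    """
    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=_sub_seed(seed, rep))
        corpus, truth = generate_corpus(cfg)
        table = corpus.to_frame()[["speaker_id", "label", "duration_s"]].copy()
        table["z_p_true"] = truth.token_truth["z_p_true"].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_univariate_lmm(table, "z_p_true", reml=reml)
        rows.append(
            {
                "replicate": rep,
                "estimate": fit.estimate,
                "se": fit.se,
                "t": fit.t_value,
                "covered": abs(fit.estimate - cfg.beta_p) <= 2 * fit.se,
                "significant_negative": fit.t_value < -2,
            }
        )
    return pd.DataFrame(rows)


def pipeline_recovery_bias(
    n_replicates: int = 20,
    seed: int = 0,
    config: SyntheticConfig = RECOVERY_CONFIG,
) -> pd.DataFrame:
    """Recovery using the pipeline-estimated Sp-scope P(S0) predictor.

    Empirical per-speaker probabilities carry sampling noise, so the fitted
    slope is attenuated relative to the generative slope (errors in
    variables); this driver quantifies that bias.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=_sub_seed(seed, rep))
        corpus, _ = generate_corpus(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = build_model_table(corpus)
            fit = fit_univariate_lmm(table, "Sp_p_s0")
        rows.append({"replicate": rep, "estimate": fit.estimate, "se": fit.se, "t": fit.t_value})
    return pd.DataFrame(rows)


def _reference_for(corpus: Corpus, seed: int):
    labels = sorted({t.label for t in corpus.tokens})
    counts: dict[str, int] = {}
    for tok in corpus.tokens:
        counts[tok.label] = counts.get(tok.label, 0) + 1
    options = ReferenceOptions(shared_fraction=0.6, vocabulary_size=120, n_utterances=150)
    stream, _ = generate_reference_corpus(labels, options, seed=seed, corpus_counts=counts)
    return stream


def type_one_error(
    n_replicates: int = 100,
    seed: int = 0,
    config: SyntheticConfig = NULL_CONFIG,
) -> pd.DataFrame:
    """Null simulation: no probability effect on duration at all.

    All 12 predictors (pooled, per-speaker and reference-corpus scope) are
    fitted univariately per replicate with REML (significance is single-fit
    reporting; no AICs are compared here); under the null each predictor's
    |t| should stay below 2 in the large majority of replicates.
    """
    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=_sub_seed(seed, rep))
        corpus, _ = generate_corpus(cfg)
        reference = _reference_for(corpus, _sub_seed(seed, rep) + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = build_model_table(corpus, reference=reference)
            fits = [
                fit_univariate_lmm(table, p, reml=True)
                for p in PREDICTOR_COLUMNS
                if p in table.columns
            ]
        tvals = {f.predictor: f.t_value for f in fits}
        rows.append(
            {
                "replicate": rep,
                "max_abs_t": max(abs(t) for t in tvals.values()),
                "all_below_2": all(abs(t) < 2 for t in tvals.values()),
                **{f"t_{k}": v for k, v in tvals.items()},
            }
        )
    return pd.DataFrame(rows)


def aic_discrimination(
    n_replicates: int = 50,
    seed: int = 0,
    config: SyntheticConfig = DISCRIMINATION_CONFIG,
) -> pd.DataFrame:
    """Do the duration-generating predictors win the AIC comparison?

    Durations are generated from P(S0) and P(S0|S-1) only.  Per replicate
    the four per-speaker-scope predictors are fitted on rows complete for
    all four (identical observations, hence comparable AICs) and the
    replicate counts as discriminated when both generating predictors have
    lower AIC than both following-syllable predictors.
    """
    preds = ["Sp_p_s0", "Sp_p_s0_given_prev", "Sp_p_s0_given_next", "Sp_p_next_given_s0"]
    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=_sub_seed(seed, rep))
        corpus, _ = generate_corpus(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = build_model_table(corpus)
            fits, _ = run_model_program(table, predictors=preds, common_rows=True)
        aics = {f.predictor: f.aic for f in fits}
        generating = [aics["Sp_p_s0"], aics["Sp_p_s0_given_prev"]]
        following = [aics["Sp_p_s0_given_next"], aics["Sp_p_next_given_s0"]]
        rows.append(
            {
                "replicate": rep,
                "discriminated": max(generating) < min(following),
                **{f"aic_{k}": v for k, v in aics.items()},
            }
        )
    return pd.DataFrame(rows)


def overlap_recovery(
    targets=(0.0, 0.2, 1.0),
    seed: int = 0,
    config: SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Mean pairwise lexicon overlap of generated corpora vs the target.

    Recordings are long enough (~2,500 tokens) that each speaker's observed
    lexicon covers their generative lexicon; with short recordings the
    observed overlap is attenuated by unused rare types.
    """
    config = config or SyntheticConfig(tokens_per_recording=2500, test_recording_speakers=())
    rows = []
    for target in targets:
        cfg = replace(config, overlap_target=float(target), seed=_sub_seed(seed, int(target * 100)))
        corpus, _ = generate_corpus(cfg)
        df = pairwise_speaker_overlap(corpus)
        mean = float(df.loc[df["subset"] == "all", "value"].mean())
        rows.append({"overlap_target": float(target), "mean_overlap": mean})
    return pd.DataFrame(rows)


def attestation_recovery(
    fractions=(0.0, 0.6, 1.0),
    seed: int = 0,
    config: SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Attested-type rate of generated reference corpora vs the plant fraction."""
    config = config or SyntheticConfig(tokens_per_recording=200, test_recording_speakers=())
    tokenizer = PhoneTokenizer()
    corpus, _ = generate_corpus(replace(config, seed=_sub_seed(seed, 7)))
    labels = sorted({t.label for t in corpus.tokens})
    rows = []
    for frac in fractions:
        stream, plant_log = generate_reference_corpus(
            labels, ReferenceOptions(shared_fraction=float(frac)), seed=_sub_seed(seed, int(frac * 100) + 1)
        )
        att = attest_types(labels, tokenizer, stream)
        rows.append(
            {
                "shared_fraction": float(frac),
                "attested_rate": att.type_rate,
                "planted_rate": sum(plant_log.values()) / len(plant_log),
            }
        )
    return pd.DataFrame(rows)
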