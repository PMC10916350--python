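# syllastats

Statistics of predictability-conditioned phonetic reduction in syllable
sequences.

Speakers of natural languages shorten words and syllables that are frequent
or predictable in context. `syllastats` asks the same question of *any*
corpus of time-aligned syllable annotations — including speech without
lexical semantics, such as glossolalia ("speaking in tongues"), where
syllable sequences look random but may carry an implicitly learned
statistical structure. The package provides the full analysis pipeline:

* **corpus_io** — Praat TextGrid and TSV readers/writers for
  syllable/breathgroup annotations; reference phone streams standing in for
  a large native-language corpus; per-recording summaries.
* **ngram_stats** — syllable n-gram counts within breathgroups, the four
  probability measures P(S0), P(S0|S−1), P(S0|S+1), P(S+1|S0) at pooled /
  per-speaker / reference scope, add-one smoothing, log-z transforms,
  Zipf rank–frequency curves, Spearman correlations.
* **lexicon_compare** — Szymkiewicz–Simpson lexicon overlap between
  speakers, kernel-density overlap of duration distributions, attestation
  of syllables and syllable bigrams in a reference phone stream (word
  boundaries ignored, pauses are hard boundaries), full-word detection.
* **duration_model** — twelve univariate linear mixed models
  `duration ~ predictor + (1 | speaker)` compared by AIC, t-value and
  standardized estimate; syllable-intercept sensitivity check; residual QQ
  and normality-resemblance diagnostics.
* **synthetic_data** — a multi-speaker corpus generator with known ground
  truth (Zipfian lexicons with controlled overlap, first-order Markov
  sequences with repetition structure, log-linear duration effects) plus a
  reference-corpus generator with planted attestation, making every stage
  testable by parameter recovery.
* **validation** — the recovery, type-I, and AIC-discrimination simulation
  drivers built on the generator.

The core quantity is the standardized duration effect: with all predictors
log-transformed and z-scaled, a fitted slope β (in seconds per SD of log
probability) below zero means more probable syllables are shorter; fits are
compared by AIC with |t| > 2 as the significance convention.

## Worked example

```python
from syllastats import (
    SyntheticConfig, generate_corpus, summarize_corpus,
    build_model_table, run_model_program,
)

cfg = SyntheticConfig(seed=1, tokens_per_recording=455, test_recording_speakers=())
corpus, truth = generate_corpus(cfg)          # 11 speakers, 5,005 tokens
print(summarize_corpus(corpus).head(3)[["recording_id", "syllable_tokens",
                                        "syllable_types", "breathgroups"]])

table = build_model_table(corpus)             # 8 glossolalia-scope predictors
fits, report = run_model_program(
    table, predictors=["Sp_p_s0", "All_p_s0"], common_rows=True)
print(report[["predictor", "estimate", "t", "aic", "n_obs"]])
```

```
  recording_id  syllable_tokens  syllable_types  breathgroups
0     S01_main              455              70            27
1     S02_main              455              64            28
2     S03_main              455              62            30
  predictor  estimate          t          aic  n_obs
0   Sp_p_s0 -0.012278 -28.657974 -20853.33283   5005
1  All_p_s0 -0.009851 -22.408669 -20571.60992   5005
```

Both scopes show the negative standardized slope near the generative
−0.010 s/SD; |t| > 2 marks both as significant. The per-speaker measure
fits better (lower AIC) because the corpus was generated from
speaker-specific probability profiles, and its univariate slope slightly
overshoots −0.010 because it also absorbs part of the correlated
transition-probability effect (β_t = −0.004 in the default generator) —
exactly the collinearity that motivates the univariate-comparison design.

A synthetic corpus with companion files (canonical TSV, TextGrids,
reference stream, ground-truth JSON) can also be produced from the shell:

```
syllastats simulate --seed 1 --out-dir scratch/demo
```

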