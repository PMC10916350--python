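# Methods

`syllastats` analyzes predictability-conditioned durational reduction in
syllable sequences: speech (here: glossolalia-style fluent syllable
production without lexical semantics) annotated at the syllable and
breathgroup level, where the question is whether more probable syllables are
produced shorter, as they are in natural languages.

## Corpus model

A corpus is an ordered collection of syllable tokens, each with an X-SAMPA
label, annotation times in seconds (half-open intervals; duration is taken
from the annotation, never re-measured from audio), a speaker, a recording,
and a position within a pause-delimited breathgroup. Breathgroups are the
largest sequence unit: pauses, breathing and hesitations terminate a
sequence, and no n-gram spans a breathgroup boundary (a flag allows
cross-boundary counting for sensitivity analysis). Pause labels default to
`{"", "<p>", "<usb>", "sil"}` and are configurable. Labels are opaque
strings; only attestation against a reference corpus decomposes them into
phones, via a greedy longest-match tokenizer over a declared X-SAMPA
inventory (multi-character symbols such as `tS` listed explicitly; length
and stress diacritics stripped by default, configurable).

## Probability measures

Four per-token measures are computed at three scopes — the pooled corpus
(`All`), the token's speaker (`Sp`), and a reference corpus of the
speakers' native language (`Ger`):

* P(S0) = count(S0) / corpus size;
* P(S0|S-1) = P(S0,S-1) / P(S-1);
* P(S0|S+1) = P(S0,S+1) / P(S+1);
* P(S+1|S0) = P(S+1,S0) / P(S0).

In the default **literal** convention the joint is a bigram count over the
total of all bigram counts and the marginal is a unigram count over the
total of all unigram counts; the quotient can exceed 1. A **row-normalized**
convention (bigram count / conditioning-type count, a proper conditional
that sums to 1 over outcomes) is also provided. After the log transform the
two differ by an additive constant, so z-scaled model predictors agree
whenever both are computed on the same support; both modes are surfaced for
transparency.

Breathgroup-initial tokens have no P(S0|S-1); breathgroup-final tokens have
no P(S0|S+1) or P(S+1|S0). These are missing values, never zeros, and each
model fit drops them per-fit (complete-case), so the number of observations
can differ across fits and is always reported.

Reference-corpus (`Ger`) frequencies are contiguous-subsequence occurrence
counts of each queried syllable (or concatenated syllable-bigram) phone
string inside the reference's pause-delimited chunks, with the reference's
own word and syllable boundaries ignored. Since some queried items never
occur, add-one (Laplace) smoothing over the queried support is applied by
default in this scope; totals are sums over that support. Corpus-internal
scopes are unsmoothed by default. The denominators for the reference scope
are a reconstruction (the natural one given the smoothing support); they
affect the log-probabilities only by additive constants and therefore do
not affect the z-scaled predictors.

Predictors are log-transformed (all raw measures are positive) and z-scaled
over the non-missing rows of the model table; non-positive inputs and
zero-variance columns raise errors rather than being silently patched.

## Duration model

Because the 12 predictors are strongly collinear, they are never entered
jointly. Each is fitted alone in a linear mixed model

    duration_s ~ 1 + predictor + (1 | speaker)

and fits are compared by AIC, t-value and standardized estimate (seconds
per predictor SD). Estimation is by maximum likelihood whenever AICs are
compared across fixed-effect specifications, and by REML for single-fit
reporting (with ~11 speaker groups ML biases the variance components, and
hence the slope SE, downward). AIC is defined as −2·logLik + 2k with k
counting fixed effects, random-effect variances and the residual variance.
Significance uses the |t| > 2 convention with no degrees-of-freedom
approximation. Optimization runs Powell first (derivative-free; robust and
fast when the random-effect variance sits at the boundary) with gradient
methods as fallback and a finiteness guard; rows are canonically sorted
before fitting so results are invariant to input row order. Random-effect
variances on the boundary (singular fits) are retained and flagged;
`converged=False` is reserved for degenerate results.
AICs from fits with different numbers of observations are flagged as not
strictly comparable; `run_model_program(common_rows=True)` restricts all
fits to rows complete for every predictor under comparison.

A sensitivity fit adds a syllable-label random intercept (crossed with
speaker, via variance components) and flags sign changes of the fixed
effect — the collinearity symptom expected when many syllable types occur
only once. Diagnostics include a QQ correlation of conditional residuals
against normal quantiles and a Shapiro–Francia-style normality-resemblance
statistic (correlation of sorted values with expected normal order
statistics, affine-invariant) for comparing predictor distributions.

## Synthetic data generator

The generator emulates a small multi-speaker corpus of pause-segmented
syllable sequences with these defaults, chosen to mirror the scale of a
study corpus of 15 recordings by 11 speakers totalling ~7,900 tokens:

| parameter | default | meaning |
|---|---|---|
| n_speakers | 11 | speakers; 4 contribute a second ("test") recording |
| lexicon_size | 80 | syllable types per speaker |
| overlap_target | 0.2 | mean pairwise Szymkiewicz–Simpson overlap |
| zipf_exponent | 1.0 | rank–frequency decay of type probabilities |
| markov_concentration | 0.3 | Dirichlet parameter of transition rows |
| repetition_boost | 0.25 | extra self-transition mass ("echoism") |
| beta0 | 0.20 s | baseline syllable duration |
| beta_p | −0.010 s/SD | slope on z(log P(S0)) |
| beta_t | −0.004 s/SD | slope on z(log P(S0|S−1)) |
| speaker_intercept_sd | 0.01 s | between-speaker intercept SD |
| noise_sd | 0.03 s | residual duration SD |
| breathgroup_length | 16 | mean of the shifted-Poisson group length |
| tokens_per_recording | 500 | syllable tokens per recording |
| cv_preference | 0.8 | probability of a CV (vs CVC) syllable shape |

Lexicons are a shared core (sized so every pairwise overlap equals the
target exactly) plus speaker-private pools. The syllable pool is kept
prefix-free at the phone level (a CV type and a CVC type with that CV onset
never coexist), which keeps the planted attestation fraction of the
synthetic reference corpus sharp; when the prefix-free constraint cannot
accommodate the requested CV share for large pools, the CV count is capped
at the largest feasible value.

Each speaker receives an independent Zipfian permutation over their lexicon
(distinct individual probability profiles by construction) and a first-order
transition matrix: rows drawn from a Dirichlet, reweighted toward the
Zipfian marginal, renormalized, then mixed with `repetition_boost` mass on
the diagonal. The boost reflects the dominant empirical bigram pattern of
such corpora — immediate repetition of the same syllable, with top-type
self-transition probabilities around 0.2–0.45 — and the concentration and
boost defaults were chosen to land the generated top-type bigram/unigram
ratios in that range. Breathgroups start from the chain's exact stationary
distribution (computed by eigendecomposition), which is also the "true"
P(S0) recorded in the ground truth, so empirical frequencies converge to
the recorded truth.

Durations follow
`beta0 + u_speaker + beta_p·z(log P(S0)) + beta_t·z(log P(S0|S−1)) + ε`
with z-scores taken over the generated tokens, the context term omitted for
breathgroup-initial tokens, ε Gaussian, and negative draws resampled (not
clipped); a warning fires if more than 1% of draws need resampling.

The synthetic reference phone stream plants a stated fraction of the
corpus's syllable types as words; all other words use a filler phone
inventory disjoint from the corpus inventory, and planted words are never
adjacent, so accidental attestation is limited to substrings of planted
material and is visible by comparing the attestation result with the plant
log. When corpus counts are supplied, plant selection is count-weighted
(frequent types are the likelier borrowings, so the token-level attestation
rate exceeds the type-level rate, as observed in natural borrowing) and the
planted words' Zipf weights are re-assigned so reference frequency
rank-correlates with corpus frequency at a configurable strength (default
tuned to a Spearman ρ around 0.4).

What the generator does **not** emulate: acoustic variation beyond the
additive duration model (no segment-level or prosodic structure), speaker
drift over time, annotation errors, higher-order sequence structure (only
first-order transitions are parameterized; longer n-gram regularities are
emergent), or any semantics. Passing recovery tests therefore show that the
pipeline measures what it claims under the stated generative assumptions,
not that real corpora satisfy those assumptions.

## Validation design (problem sizes and estimator choices)

* **Oracle equivalence.** Counting and the probability conventions are
  checked exactly against brute-force recounts on random toy corpora.
* **Parameter recovery.** 100 replicates of an 11-speaker, ~5,000-token
  scenario with beta_p = −0.010 and beta_t = 0; the fit uses the
  generator's own standardized predictor, so coverage of ±2·SE measures the
  mixed-model estimator given the true covariate. Pipeline-estimated
  predictors additionally carry errors-in-variables attenuation (~5% at
  this scale, quantified by `validation.pipeline_recovery_bias`), which is
  a property of empirical probability estimation, not of the model stage.
* **Type-I control and AIC discrimination** are evaluated on corpora with
  long recordings (~20k tokens over 11 speakers) so that per-speaker bigram
  probabilities are well estimated. With study-sized recordings the sparse
  conditional predictors concentrate their variance on a handful of
  singleton-count tokens; the |t| > 2 convention then runs anti-conservative
  (empirically up to ~10% per predictor instead of ~5%) for reasons
  unrelated to the model-fitting machinery under test. The discrimination
  scenario uses equal generating magnitudes (beta_p = beta_t = −0.010) so
  the two generating predictors are symmetric contributors, and compares
  AICs on rows complete for all four compared predictors (identical
  observations).
* **Overlap recovery** uses ~2,500-token recordings so each speaker's
  observed lexicon covers their generative lexicon; with short recordings
  the observed overlap is attenuated by unused rare types.

## Known limitations

* The conditional-probability conventions (literal vs row-normalized) are
  both exposed because the field's formulas are used inconsistently;
  z-scaled model predictors are convention-invariant, but raw probability
  exports are not.
* Attestation is exact symbol-sequence matching; no phonological-feature
  similarity.
* The crossed speaker+syllable random-intercept fit uses variance
  components on a single group and scales poorly beyond a few thousand
  distinct labels.
* Spearman correlations on union support assign absent types zero
  probability (rank-tied at the bottom); a shared-support mode exists, and
  the two can differ noticeably for small lexicon overlap.
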