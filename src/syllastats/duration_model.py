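"""Univariate mixed-effects modeling of syllable duration by predictability.

Because the 12 probability measures ({All, Sp, Ger} x {P(S0), P(S0|S-1),
P(S0|S+1), P(S+1|S0)}, each log-transformed and z-scaled) are strongly
collinear, they are never entered jointly: each is fitted alone in

    duration_s ~ 1 + predictor + (1 | speaker)

and the fits are compared by AIC, t-value and standardized estimate.  Models
are estimated by maximum likelihood (not REML) so that AICs of models with
identical random effects and different fixed effects are comparable.  AIC is
computed as -2 logLik + 2k with k counting fixed effects, random-effect
variances and the residual variance.  Significance uses the |t| > 2
convention without any degrees-of-freedom approximation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .corpus_io import Corpus, ReferencePhoneStream
from .lexicon_compare import PhoneTokenizer, reference_frequency_tables
from .ngram_stats import (
    MEASURE_NAMES,
    count_ngrams,
    probability_measures,
    transform_predictors,
)

logger = logging.getLogger(__name__)

SCOPES = ("All", "Sp", "Ger")

#: Column names of the 12 predictors in a model table.
PREDICTOR_COLUMNS = [f"{scope}_{m}" for scope in SCOPES for m in MEASURE_NAMES]


def build_model_table(
    corpus: Corpus,
    reference: ReferencePhoneStream | None = None,
    tokenizer: PhoneTokenizer | None = None,
    mode: str = "literal",
) -> pd.DataFrame:
    """Per-token model table: duration plus log-z predictors at all scopes.

    ``All`` measures come from the pooled corpus, ``Sp`` from each speaker's
    own tokens, ``Ger`` from reference-corpus lookups (add-one smoothed over
    the queried support).  Without a reference stream only the 8
    glossolalia-internal predictors are produced.  Rows with a missing
    predictor are retained; each fit drops them per-fit (complete-case).
    """
    base = corpus.to_frame()
    key = ["recording_id", "breathgroup_index", "position_in_breathgroup"]
    table = base[key + ["speaker_id", "label", "duration_s"]].copy()
    if (table["duration_s"] <= 0).any():
        raise ValueError("model table requires strictly positive durations")

    uni_all = count_ngrams(corpus, 1)
    bi_all = count_ngrams(corpus, 2)
    frames = {"All": probability_measures(corpus, uni_all, bi_all, mode=mode)}

    sp_parts = []
    for sid in corpus.speakers():
        uni_sp = count_ngrams(corpus, 1, scope="Sp", speaker_id=sid)
        bi_sp = count_ngrams(corpus, 2, scope="Sp", speaker_id=sid)
        sp_parts.append(probability_measures(corpus, uni_sp, bi_sp, speaker_id=sid, mode=mode))
    frames["Sp"] = pd.concat(sp_parts, ignore_index=True)

    if reference is not None:
        tok = tokenizer or PhoneTokenizer()
        uni_ger, bi_ger = reference_frequency_tables(
            {g[0] for g in uni_all.counts},
            set(bi_all.counts),
            tok,
            reference,
        )
        frames["Ger"] = probability_measures(corpus, uni_ger, bi_ger, mode=mode)

    for scope, meas in frames.items():
        meas = meas.set_index(key)
        for m in MEASURE_NAMES:
            col = f"{scope}_{m}"
            aligned = meas[m].reindex(pd.MultiIndex.from_frame(table[key]))
            if aligned.notna().sum() == 0:
                raise ValueError(f"predictor column {col} is entirely missing")
            table[col] = transform_predictors(aligned.to_numpy())
    return table


@dataclass
class DurationModelFit:
    """One univariate mixed-model result."""

    predictor: str
    estimate: float
    se: float
    t_value: float
    aic: float
    log_lik: float
    n_obs: int
    converged: bool
    random_effects: str = "speaker"
    singular: bool = False
    message: str = ""
    result: object = field(default=None, repr=False, compare=False)

    @property
    def significant(self) -> bool:
        return abs(self.t_value) > 2


def _aic(llf: float, k: int) -> float:
    return -2.0 * llf + 2.0 * k


def fit_univariate_lmm(
    table: pd.DataFrame,
    predictor: str,
    random_effects: str = "speaker",
    reml: bool = False,
) -> DurationModelFit:
    """Fit duration ~ 1 + predictor with speaker (+ syllable) random intercepts.

    ML estimation by default so AICs are comparable across fixed-effect
    specifications.  Rows missing the predictor are dropped for this fit
    only.  Non-convergence and singular random-effect variances are flagged,
    never raised.
    """
    if predictor not in table.columns:
        raise KeyError(f"predictor {predictor!r} not in table")
    data = table.dropna(subset=[predictor, "duration_s"]).copy()
    if len(data) < 10:
        raise ValueError(f"predictor {predictor!r} has only {len(data)} complete rows")
    if data["speaker_id"].nunique() < 2:
        raise ValueError("need at least 2 speakers for a speaker random intercept")
    data = data.rename(columns={predictor: "x"})
    # canonical row order makes the fit invariant to input permutation
    data = data.sort_values(["speaker_id", "x", "duration_s"], kind="mergesort").reset_index(
        drop=True
    )

    converged = True
    singular = False
    message = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if random_effects == "speaker":
            model = smf.mixedlm("duration_s ~ x", data, groups=data["speaker_id"])
            n_re_var = 1
        elif random_effects == "speaker+syllable":
            # crossed random intercepts via variance components on one group
            data["_one"] = 1
            model = smf.mixedlm(
                "duration_s ~ x",
                data,
                groups=data["_one"],
                vc_formula={
                    "speaker": "0 + C(speaker_id)",
                    "syllable": "0 + C(label)",
                },
            )
            n_re_var = 2
        else:
            raise ValueError(f"unknown random_effects spec {random_effects!r}")
        # Powell first: derivative-free, robust and fast when the
        # random-effect variance sits at or near the boundary; gradient
        # methods as fallback.
        try:
            result = model.fit(reml=reml, method="powell", maxiter=2000)
            if not math.isfinite(result.llf) or not getattr(result, "converged", True):
                retry = model.fit(reml=reml, maxiter=500)
                if math.isfinite(retry.llf) and retry.llf >= result.llf - 1e-6:
                    result = retry
        except Exception:  # pragma: no cover - fallback optimizer
            result = model.fit(reml=reml, maxiter=500)
        for w in caught:
            if "singular" in str(w.message).lower() or "boundary" in str(w.message).lower():
                singular = True
                if not message:
                    message = str(w.message)

    est = float(result.params["x"])
    se = float(result.bse["x"])
    t = est / se if se > 0 else math.nan
    # a boundary solution (random-effect variance at ~0) is retained as a
    # singular but usable fit; converged=False only for a degenerate result
    if not (
        math.isfinite(result.llf)
        and math.isfinite(est)
        and math.isfinite(se)
        and se > 0
    ):
        converged = False
        message = message or "optimizer did not converge"
    elif not getattr(result, "converged", True):
        singular = True
        message = message or "gradient test failed (boundary solution retained)"
    k = 2 + n_re_var + 1  # intercept + slope, RE variances, residual variance
    llf = float(result.llf)
    aic = _aic(llf, k) if converged else math.nan
    if reml:
        aic = math.nan  # REML likelihoods are not comparable across fixed effects
    return DurationModelFit(
        predictor=predictor,
        estimate=est,
        se=se,
        t_value=t,
        aic=aic,
        log_lik=llf,
        n_obs=len(data),
        converged=converged,
        random_effects=random_effects,
        singular=singular,
        message=message,
        result=result,
    )


def run_model_program(
    table: pd.DataFrame,
    predictors: Sequence[str] | None = None,
    common_rows: bool = False,
) -> tuple[list[DurationModelFit], pd.DataFrame]:
    """Fit one univariate model per predictor and tabulate the comparison.

    ``common_rows=True`` restricts every fit to rows complete for *all*
    requested predictors so that AICs are computed on identical observations;
    otherwise complete cases are taken per-fit and n_obs may differ, in which
    case the report flags the AICs as not strictly comparable.
    """
    if predictors is None:
        predictors = [c for c in PREDICTOR_COLUMNS if c in table.columns]
    data = table.dropna(subset=list(predictors)) if common_rows else table
    fits = [fit_univariate_lmm(data, p) for p in predictors]
    report = pd.DataFrame(
        {
            "predictor": [f.predictor for f in fits],
            "scope": [f.predictor.split("_", 1)[0] for f in fits],
            "estimate": [f.estimate for f in fits],
            "se": [f.se for f in fits],
            "t": [f.t_value for f in fits],
            "aic": [f.aic for f in fits],
            "n_obs": [f.n_obs for f in fits],
            "converged": [f.converged for f in fits],
            "significant": [f.significant for f in fits],
            "sign": [int(np.sign(f.estimate)) for f in fits],
        }
    ).sort_values("aic").reset_index(drop=True)
    report["aic_rank"] = np.arange(1, len(report) + 1)
    report.attrs["aic_comparable"] = bool(report["n_obs"].nunique() == 1)
    if not report.attrs["aic_comparable"]:
        logger.warning("n_obs differs across fits; AICs not strictly comparable")
    return fits, report


def sensitivity_syllable_intercept(
    table: pd.DataFrame, predictor: str
) -> tuple[DurationModelFit, DurationModelFit, dict]:
    """Refit with an added syllable-label random intercept; flag sign changes.

    A sign flip of the fixed-effect estimate when syllable intercepts enter
    is a collinearity symptom, aggravated by a high share of singleton
    syllable types (types occurring once).
    """
    fit_sp = fit_univariate_lmm(table, predictor, random_effects="speaker")
    fit_both = fit_univariate_lmm(table, predictor, random_effects="speaker+syllable")
    counts = table["label"].value_counts()
    diagnostics = {
        "sign_change": bool(np.sign(fit_sp.estimate) != np.sign(fit_both.estimate)),
        "singleton_share": float((counts == 1).sum() / len(counts)),
        "n_types": int(len(counts)),
    }
    return fit_sp, fit_both, diagnostics


def predictor_correlation_matrix(
    table: pd.DataFrame,
    method: str = "pearson",
    include_duration: bool = True,
) -> pd.DataFrame:
    """Pairwise-complete correlations among the predictors (and duration).

    Both product-moment (on the log-z values) and rank variants are valid
    choices; select via ``method`` ("pearson" or "spearman").
    """
    cols = [c for c in PREDICTOR_COLUMNS if c in table.columns]
    if include_duration:
        cols = cols + ["duration_s"]
    return table[cols].corr(method=method)


def residual_qq(fit: DurationModelFit) -> tuple[float, np.ndarray, np.ndarray]:
    """QQ correlation of standardized conditional residuals vs normal quantiles.

    Returns (correlation, theoretical quantiles, sorted residuals).  No
    residuals are excluded.  Small samples (< 10) are computed but flagged.
    """
    if fit.result is None:
        raise ValueError("fit carries no underlying result object")
    resid = np.asarray(fit.result.resid, dtype=float)
    resid = (resid - resid.mean()) / resid.std(ddof=1)
    resid.sort()
    n = resid.size
    if n < 10:
        logger.warning("QQ correlation on only %d residuals is underpowered", n)
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    corr = float(np.corrcoef(theo, resid)[0, 1])
    return corr, theo, resid


def normality_resemblance(values: Sequence[float]) -> float:
    """Correlation of sorted values with expected normal order statistics.

    A Shapiro–Francia-style statistic in [-1, 1]; 1 means the sample is an
    affine image of the normal quantile sequence.  Invariant under affine
    transformation of the input.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 10:
        raise ValueError("need at least 10 non-missing values")
    if arr.std() == 0:
        raise ValueError("constant input: resemblance undefined")
    arr = np.sort(arr)
    theo = stats.norm.ppf((np.arange(1, arr.size + 1) - 0.375) / (arr.size + 0.25))
    return float(np.corrcoef(theo, arr)[0, 1])


def plot_model_comparison(report: pd.DataFrame, path: str) -> None:
    """Three-panel comparison plot (AIC, t, estimate) of the univariate fits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"All": "black", "Sp": "tab:blue", "Ger": "tab:red"}
    fig, axes = plt.subplots(1, 3, figsize=(12, 4), sharey=True)
    rep = report.sort_values("predictor").reset_index(drop=True)
    y = np.arange(len(rep))
    for ax, col, title in zip(axes, ["aic", "t", "estimate"], ["AIC", "t-value", "estimate"]):
        for i, row in rep.iterrows():
            alpha = 1.0 if row["significant"] else 0.35  # pale dot = not significant
            ax.plot(row[col], i, "o", color=colors.get(row["scope"], "gray"), alpha=alpha)
        ax.set_title(title)
        ax.axvline(0, color="0.8", lw=0.5) if col != "aic" else None
    axes[0].set_yticks(y, rep["predictor"])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def export_model_report(report: pd.DataFrame, path: str) -> None:
    report.to_csv(path, sep="\t", index=False)
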