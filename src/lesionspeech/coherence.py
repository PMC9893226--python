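"""Coherence-judgement analysis: trial exclusions, d-prime with boundary
corrections, condition models with deviation coding and per-participant
residual condition effects.

Trial tables are pandas DataFrames with columns
``participant, sentence_id, sentence_type, judged_coherent, correct,
rt_from_offset`` where ``rt_from_offset`` is in ms (negative = response
before sentence offset) and ``sentence_type`` is one of ``high_ambiguity``,
``low_ambiguity``, ``anomalous``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "FAST_CUTOFF_MS",
    "SLOW_CUTOFF_MS",
    "ExclusionReport",
    "DPrimeResult",
    "ModelFit",
    "apply_exclusions",
    "dprime",
    "fit_condition_model",
    "residual_effect",
    "dprime_by_participant",
]

#: responses more than 300 ms before sentence offset are anticipatory
FAST_CUTOFF_MS = -300.0
#: responses more than 4000 ms after sentence offset are not speeded
SLOW_CUTOFF_MS = 4000.0

COHERENT_TYPES = ("high_ambiguity", "low_ambiguity")


@dataclass(frozen=True)
class ExclusionReport:
    analysis: str
    n_input: int
    n_fast: int
    n_slow: int
    n_incorrect_removed: int
    n_anomalous_removed: int
    n_output: int
    excluded_index: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class DPrimeResult:
    hit_rate_adj: float
    fa_rate_adj: float
    dprime: float


@dataclass
class ModelFit:
    """A fitted condition model with per-trial fitted values and residuals.

    Residuals are on the response scale: observed minus fitted probability
    for the binomial family, observed minus fitted log10 RT for the gaussian
    family.
    """

    family: str
    params: pd.Series
    contrast_name: str
    data: pd.DataFrame      # analysis rows, with 'fitted' and 'residual'
    condition_col: str
    result: object = None   # underlying statsmodels results


def _validate(trials: pd.DataFrame) -> pd.DataFrame:
    required = {"participant", "sentence_id", "sentence_type",
                "judged_coherent", "correct", "rt_from_offset"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if trials["rt_from_offset"].isna().any():
        raise ValueError("rt_from_offset must be present for all trials")
    return trials


def apply_exclusions(trials: pd.DataFrame, analysis: str
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Filter trials for the accuracy or RT analysis.

    ``accuracy``: removes anticipatory (fast) trials and all anomalous
    trials; the remaining coherent trials carry the accuracy signal since
    the false-alarm set is shared between ambiguity conditions.

    ``rt``: restricts to coherent trials, then removes incorrect judgements,
    fast trials and slow (> 4000 ms after offset) trials.
    """
    trials = _validate(trials)
    fast = trials["rt_from_offset"] < FAST_CUTOFF_MS
    slow = trials["rt_from_offset"] > SLOW_CUTOFF_MS
    anomalous = trials["sentence_type"] == "anomalous"
    # removal categories are reported disjointly so counts reconcile exactly
    if analysis == "accuracy":
        drop = fast | anomalous
        n_fast = int((fast & ~anomalous).sum())
        n_slow = 0
        n_incorrect = 0
    elif analysis == "rt":
        incorrect = ~trials["correct"].astype(bool)
        drop = anomalous | incorrect | fast | slow
        n_incorrect = int((incorrect & ~anomalous).sum())
        n_fast = int((fast & ~anomalous & ~incorrect).sum())
        n_slow = int((slow & ~anomalous & ~incorrect & ~fast).sum())
    else:
        raise ValueError(f"unknown analysis {analysis!r}; use 'accuracy' or 'rt'")
    kept = trials.loc[~drop].copy()
    report = ExclusionReport(
        analysis=analysis,
        n_input=len(trials),
        n_fast=n_fast,
        n_slow=n_slow,
        n_incorrect_removed=n_incorrect,
        n_anomalous_removed=int(anomalous.sum()),
        n_output=len(kept),
        excluded_index=tuple(trials.index[drop]),
    )
    return kept, report


def _adjust_rate(k: int, n: int) -> float:
    # boundary correction: rates of 1 -> 1 - 1/(2N), rates of 0 -> 1/(2N)
    if n <= 0:
        raise ValueError("total count must be positive")
    rate = k / n
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    if rate <= 0.0:
        return 1.0 / (2 * n)
    return rate


def dprime(n_hits: int, n_coherent: int, n_fa: int, n_anomalous: int) -> DPrimeResult:
    """Signal-detection sensitivity z(hit rate) - z(false-alarm rate).

    Boundary rates are adjusted before the inverse-normal transform: a hit
    rate of 1 becomes 1 - 1/(2 N_coherent) and a false-alarm rate of 0
    becomes 1/(2 N_anomalous).
    """
    if min(n_hits, n_coherent, n_fa, n_anomalous) < 0:
        raise ValueError("counts must be nonnegative")
    hit = _adjust_rate(n_hits, n_coherent)
    fa = _adjust_rate(n_fa, n_anomalous)
    return DPrimeResult(hit_rate_adj=hit, fa_rate_adj=fa,
                        dprime=float(norm.ppf(hit) - norm.ppf(fa)))


def dprime_by_participant(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant d-prime for each ambiguity condition against the shared
    anomalous set, computed after removing anticipatory responses."""
    trials = _validate(trials)
    trials = trials.loc[trials["rt_from_offset"] >= FAST_CUTOFF_MS]
    rows = []
    for pid, grp in trials.groupby("participant", sort=True):
        anom = grp[grp["sentence_type"] == "anomalous"]
        n_fa = int(anom["judged_coherent"].sum())
        for cond in COHERENT_TYPES:
            coh = grp[grp["sentence_type"] == cond]
            res = dprime(int(coh["judged_coherent"].sum()), len(coh),
                         n_fa, len(anom))
            rows.append({"participant": pid, "condition": cond,
                         "dprime": res.dprime,
                         "hit_rate_adj": res.hit_rate_adj,
                         "fa_rate_adj": res.fa_rate_adj})
    return pd.DataFrame(rows)


def _deviation_code(series: pd.Series, positive: str, negative: str) -> pd.Series:
    vals = set(series.unique())
    if not vals <= {positive, negative}:
        raise ValueError(f"unexpected levels {vals - {positive, negative}}")
    if len(vals) < 2:
        raise ValueError("both conditions must be present")
    return series.map({positive: 0.5, negative: -0.5}).astype(float)


def fit_condition_model(trials: pd.DataFrame, family: str,
                        condition_col: str = "sentence_type",
                        positive: str = "high_ambiguity",
                        negative: str = "low_ambiguity",
                        extra_terms: list | None = None) -> ModelFit:
    """Fit the deviation-coded (+1/2 vs -1/2) condition model.

    family
        ``"binomial-logit"`` models ``correct`` (accuracy); the contrast is
        the log-odds difference between conditions. ``"gaussian-log10rt"``
        models log10 response time; the contrast is the RT cost in log10
        units.

    Participant and item intercepts enter as fixed effects (two-way
    fixed-intercept G/LM); a random-effects engine can be substituted
    upstream as the design matrix and residual definitions are unchanged.
    """
    trials = trials.copy()
    if trials["participant"].nunique() < 2:
        raise ValueError("need >= 2 participants")
    trials["_cond"] = _deviation_code(trials[condition_col], positive, negative)

    y, extra = _prepare_outcome(trials, family)
    X = _design_matrix(trials, extra)
    if family == "binomial-logit":
        model = sm.GLM(y, X, family=sm.families.Binomial())
    else:
        model = sm.OLS(y, X)
    result = model.fit()
    fitted = np.asarray(result.predict(X))
    trials["fitted"] = fitted
    trials["residual"] = np.asarray(y, dtype=float) - fitted
    return ModelFit(family=family, params=result.params, contrast_name="_cond",
                    data=trials, condition_col=condition_col, result=result)


def _prepare_outcome(trials: pd.DataFrame, family: str):
    if family == "binomial-logit":
        return trials["correct"].astype(float), []
    if family == "gaussian-log10rt":
        rt = trials["rt_from_offset"].astype(float)
        if (rt <= 0).any():
            raise ValueError(
                "non-positive RTs survived exclusion; cannot take log10")
        trials["_log10rt"] = np.log10(rt)
        return trials["_log10rt"], []
    raise ValueError(f"unknown family {family!r}")


def _design_matrix(trials: pd.DataFrame, extra_cols: list) -> pd.DataFrame:
    parts = [pd.Series(1.0, index=trials.index, name="intercept"),
             trials["_cond"]]
    parts.extend(trials[c] for c in extra_cols)
    parts.append(pd.get_dummies(trials["participant"], prefix="p",
                                drop_first=True, dtype=float))
    # Item intercepts are only identifiable jointly with a between-item
    # condition contrast when they are shrunk (random effects). In this
    # fixed-effect engine they would absorb the contrast entirely, so they
    # are included only if they leave the design full-rank.
    items = pd.get_dummies(trials["sentence_id"], prefix="i",
                           drop_first=True, dtype=float)
    X = pd.concat(parts + [items], axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        X = pd.concat(parts, axis=1)
    return X


def residual_effect(fit: ModelFit, participant, cond_a: str, cond_b: str) -> float:
    """Per-participant residual condition effect: mean residual over
    ``cond_a`` trials minus mean residual over ``cond_b`` trials.

    Positive values mean the participant's effect exceeds the group model's
    prediction.
    """
    rows = fit.data[fit.data["participant"] == participant]
    a = rows[rows[fit.condition_col] == cond_a]["residual"]
    b = rows[rows[fit.condition_col] == cond_b]["residual"]
    if a.empty or b.empty:
        raise ValueError(
            f"participant {participant!r} lacks trials in "
            f"{cond_a if a.empty else cond_b!r}")
    return float(a.mean() - b.mean())
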