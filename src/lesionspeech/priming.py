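"""Word-meaning priming analysis.

Association trial tables are pandas DataFrames with columns
``participant, word_id, source_sentence_id, primed, dominance, consistent``
where ``consistent`` is the 0/1 coding of whether the free-association
response matched the subordinate meaning.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .coherence import ModelFit, residual_effect

__all__ = ["exclude_misjudged", "fit_priming_model", "priming_effect"]


def _validate(trials: pd.DataFrame) -> pd.DataFrame:
    required = {"participant", "word_id", "source_sentence_id", "primed",
                "dominance", "consistent"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    return trials


def exclude_misjudged(assoc_trials: pd.DataFrame,
                      coherence_trials: pd.DataFrame
                      ) -> tuple[pd.DataFrame, int]:
    """Drop primed words from sentences the participant misjudged.

    For each participant, high-ambiguity coherence trials judged incorrectly
    identify the sentences whose two primed target words carry no valid
    priming exposure; those primed association rows (and only those) are
    removed. Unprimed rows are never excluded.
    """
    assoc_trials = _validate(assoc_trials)
    primed = assoc_trials[assoc_trials["primed"].astype(bool)]
    coh_keys = set(zip(coherence_trials["participant"],
                       coherence_trials["sentence_id"]))
    unmapped = [
        (p, s) for p, s in zip(primed["participant"],
                               primed["source_sentence_id"])
        if (p, s) not in coh_keys
    ]
    if unmapped:
        raise ValueError(
            f"primed words without a coherence-task sentence: {unmapped[:5]}")
    high = coherence_trials[
        coherence_trials["sentence_type"] == "high_ambiguity"]
    misjudged = set(zip(high.loc[~high["correct"].astype(bool), "participant"],
                        high.loc[~high["correct"].astype(bool), "sentence_id"]))
    drop = assoc_trials["primed"].astype(bool) & np.array([
        (p, s) in misjudged
        for p, s in zip(assoc_trials["participant"],
                        assoc_trials["source_sentence_id"])
    ])
    kept = assoc_trials.loc[~drop].copy()
    return kept, int(drop.sum())


def fit_priming_model(assoc_trials: pd.DataFrame,
                      center_dominance: bool = True) -> ModelFit:
    """Binomial-logit model of subordinate-meaning consistency.

    Fixed effects: Priming (deviation coded Primed = +1/2, Unprimed = -1/2),
    Meaning Dominance (mean-centred by default so the priming main effect is
    evaluated at average dominance) and their interaction, plus participant
    and word fixed intercepts.
    """
    trials = _validate(assoc_trials).copy()
    primed = trials["primed"].astype(bool)
    if primed.nunique() < 2:
        raise ValueError("both priming conditions must be present")
    y = trials["consistent"].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome is constant; model is unidentifiable")
    trials["_cond"] = np.where(primed, 0.5, -0.5)
    dom = trials["dominance"].astype(float)
    trials["_dominance"] = dom - dom.mean() if center_dominance else dom
    trials["_interaction"] = trials["_cond"] * trials["_dominance"]

    parts = [pd.Series(1.0, index=trials.index, name="intercept"),
             trials["_cond"], trials["_dominance"], trials["_interaction"],
             pd.get_dummies(trials["participant"], prefix="p",
                            drop_first=True, dtype=float)]
    word_dummies = pd.get_dummies(trials["word_id"], prefix="w",
                                  drop_first=True, dtype=float)
    # dominance is a word-level covariate; drop word intercepts if they make
    # the design singular (dominance lies in the span of word indicators)
    X = pd.concat(parts + [word_dummies], axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        X = pd.concat(parts, axis=1)
    # constant dominance degenerates the centred covariate to a zero column
    degenerate = [c for c in ("_dominance", "_interaction")
                  if float(X[c].abs().max()) == 0.0]
    X = X.drop(columns=degenerate)
    result = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    fitted = np.asarray(result.predict(X))
    trials["_condlabel"] = np.where(primed, "primed", "unprimed")
    trials["fitted"] = fitted
    trials["residual"] = np.asarray(y, dtype=float) - fitted
    return ModelFit(family="binomial-logit", params=result.params,
                    contrast_name="_cond", data=trials,
                    condition_col="_condlabel", result=result)


def priming_effect(fit: ModelFit, participant) -> float:
    """Residual priming effect: mean residual (primed) - mean residual (unprimed)."""
    return residual_effect(fit, participant, "primed", "unprimed")
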