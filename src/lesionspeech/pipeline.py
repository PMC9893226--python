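"""End-to-end orchestration of the two listening-challenge analyses and the
cross-challenge dissociation report.

Challenge 1: word report of noise-vocoded sentences -> per-participant
psychometric thresholds (and pre/post adaptation) correlated with lesion
volumes. Challenge 2: coherence judgements and word association ->
per-participant residual ambiguity RT effects and residual priming effects
correlated with lesion volumes. The dissociation report compares dependent
correlations with Meng's z.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import coherence as coh
from . import priming as pri
from . import psychometrics as psy
from . import stats as st
from . import synth

__all__ = [
    "fit_word_report",
    "run_challenge1",
    "run_challenge2",
    "run_dissociation",
    "run_all",
    "correlation_table",
]

NETWORKS = ("md", "lang", "total")
_VOL_COL = {"md": "lesion_vol_md", "lang": "lesion_vol_lang",
            "total": "lesion_vol_total"}


def fit_word_report(word_report: pd.DataFrame) -> pd.DataFrame:
    """Per-participant psychometric fits for each phase.

    Sentence rows are pooled to per-level binomial totals; the lapse rate is
    fixed at 1 minus clear-speech accuracy for that participant and phase.
    """
    rows = []
    for (pid, phase), grp in word_report.groupby(["participant", "phase"],
                                                 sort=True):
        pooled = grp.groupby("channels")[["k_correct", "n_words"]].sum()
        clear = pooled.loc[psy.CLEAR_CHANNELS]
        clear_acc = clear["k_correct"] / clear["n_words"]
        conds = [psy.ChannelCondition(channels=int(ch),
                                      k_correct=int(r["k_correct"]),
                                      n_words=int(r["n_words"]))
                 for ch, r in pooled.iterrows()]
        fit = psy.fit_participant(conds, clear_acc, phase=phase)
        rows.append({"participant": pid, "phase": phase, "alpha": fit.alpha,
                     "beta": fit.beta, "lambda": fit.lambda_,
                     "threshold_channels": psy.threshold_channels(fit),
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def correlation_table(volumes: pd.DataFrame, behaviour: pd.Series,
                      direction: str) -> pd.DataFrame:
    """One-tailed correlations of a per-participant measure with each
    lesion-volume column, on the participants present in both."""
    rows = []
    merged = volumes.join(behaviour.rename("behaviour"), how="inner").dropna()
    if len(merged) < 4:
        raise ValueError(
            f"only {len(merged)} participants with complete data; need >= 4")
    for net in NETWORKS:
        res = st.pearson_one_tailed(merged[_VOL_COL[net]], merged["behaviour"],
                                    direction)
        rows.append({"network": net, "r": res.r, "p_one_tailed": res.p_one_tailed,
                     "n": res.n, "direction": direction})
    return pd.DataFrame(rows)


def _volume_frame(cohort) -> pd.DataFrame:
    df = synth.cohort_frame(cohort)
    return df.set_index("id")[list(_VOL_COL.values())]


def run_challenge1(config: synth.CohortConfig, cohort=None) -> dict:
    """Synthetic Challenge 1: thresholds, adaptation, lesion correlations."""
    if cohort is None:
        cohort = synth.generate_cohort(config)
    word_report = synth.generate_word_report_trials(
        cohort, synth.build_stimulus_sets(), config)
    fits = fit_word_report(word_report)
    wide = fits.pivot(index="participant", columns="phase", values="alpha")
    missing = wide.index[wide.isna().any(axis=1)]
    if len(missing):
        raise ValueError(f"participants missing a phase fit: {list(missing)}")
    per_participant = pd.DataFrame({
        "mean_alpha": wide.mean(axis=1),
        "mean_threshold_channels": (2.0 ** wide).mean(axis=1),
        "adaptation": wide["pre"] - wide["post"],
    })
    volumes = _volume_frame(cohort)
    return {
        "word_report": word_report,
        "fits": fits,
        "per_participant": per_participant,
        # more damage -> higher threshold (worse perception)
        "perception_correlations": correlation_table(
            volumes, per_participant["mean_alpha"], "positive"),
        # more damage -> less adaptation
        "adaptation_correlations": correlation_table(
            volumes, per_participant["adaptation"], "negative"),
        "seed": config.seed,
    }


def run_challenge2(config: synth.CohortConfig, cohort=None,
                   paper_counts_fixture: bool = False) -> dict:
    """Synthetic Challenge 2: d-primes, ambiguity RT effects, priming
    effects, exclusion reports and lesion correlations."""
    if cohort is None:
        cohort = synth.generate_cohort(config)
    trials = synth.generate_coherence_trials(
        cohort, config, paper_counts_fixture=paper_counts_fixture)
    assoc = synth.generate_association_trials(
        cohort, config, paper_counts_fixture=paper_counts_fixture,
        coherence_trials=trials if paper_counts_fixture else None)

    dprimes = coh.dprime_by_participant(trials)
    acc_trials, acc_report = coh.apply_exclusions(trials, "accuracy")
    acc_fit = coh.fit_condition_model(acc_trials, "binomial-logit")
    rt_trials, rt_report = coh.apply_exclusions(trials, "rt")
    rt_fit = coh.fit_condition_model(rt_trials, "gaussian-log10rt")
    pids = sorted({p.id for p in cohort})
    rt_effects = pd.Series(
        {pid: coh.residual_effect(rt_fit, pid, "high_ambiguity",
                                  "low_ambiguity") for pid in pids},
        name="ambiguity_rt_effect")

    assoc_kept, n_excluded = pri.exclude_misjudged(assoc, trials)
    prime_fit = pri.fit_priming_model(assoc_kept)
    prime_effects = pd.Series(
        {pid: pri.priming_effect(prime_fit, pid) for pid in pids},
        name="priming_effect")

    volumes = _volume_frame(cohort)
    return {
        "coherence_trials": trials,
        "association_trials": assoc,
        "dprimes": dprimes,
        "accuracy_exclusions": acc_report,
        "rt_exclusions": rt_report,
        "accuracy_fit": acc_fit,
        "rt_fit": rt_fit,
        "priming_fit": prime_fit,
        "n_assoc_excluded": n_excluded,
        "n_assoc_remaining": len(assoc_kept),
        "rt_effects": rt_effects,
        "priming_effects": prime_effects,
        # more damage -> larger ambiguity slowing
        "comprehension_correlations": correlation_table(
            volumes, rt_effects, "positive"),
        # more damage -> less word-meaning priming
        "priming_correlations": correlation_table(
            volumes, prime_effects, "negative"),
        "seed": config.seed,
    }


def _r_of(table: pd.DataFrame, network: str) -> float:
    return float(table.loc[table["network"] == network, "r"].iloc[0])


def run_dissociation(ch1: dict, ch2: dict, cohort) -> dict:
    """Meng's z comparisons of dependent correlations, within and across
    challenges, on the participants shared by both reports."""
    volumes = _volume_frame(cohort)
    measures = pd.DataFrame({
        "perception": ch1["per_participant"]["mean_alpha"],
        "adaptation": ch1["per_participant"]["adaptation"],
        "comprehension": ch2["rt_effects"],
        "priming": ch2["priming_effects"],
    })
    shared = measures.dropna().index.intersection(volumes.index)
    if len(shared) < 4:
        raise ValueError("cohorts share fewer than 4 participants")
    vols = volumes.loc[shared]
    meas = measures.loc[shared]
    n = len(shared)

    def corr(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    comparisons = {}
    # within task: does MD vs language damage predict the measure differently?
    r12_vol = corr(vols["lesion_vol_md"], vols["lesion_vol_lang"])
    for measure in measures.columns:
        r_md = corr(vols["lesion_vol_md"], meas[measure])
        r_lang = corr(vols["lesion_vol_lang"], meas[measure])
        comparisons[f"{measure}:md_vs_lang"] = st.meng_z(
            r_md, r_lang, r12_vol, n)
    # across task: is one network's damage more predictive of one measure?
    pairs = [("perception", "adaptation"), ("comprehension", "priming"),
             ("perception", "comprehension"), ("perception", "priming"),
             ("adaptation", "priming")]
    for net in ("md", "lang"):
        for m1, m2 in pairs:
            r1 = corr(vols[_VOL_COL[net]], meas[m1])
            r2 = corr(vols[_VOL_COL[net]], meas[m2])
            r12 = corr(meas[m1], meas[m2])
            comparisons[f"{net}:{m1}_vs_{m2}"] = st.meng_z(r1, r2, r12, n)
    return {"n_shared": n, "comparisons": comparisons,
            "shared_participants": list(shared)}


def run_all(config: synth.CohortConfig) -> dict:
    """Full synthetic pipeline: both challenges plus the dissociation report."""
    cohort = synth.generate_cohort(config)
    ch1 = run_challenge1(config, cohort=cohort)
    ch2 = run_challenge2(config, cohort=cohort)
    diss = run_dissociation(ch1, ch2, cohort)
    return {"cohort": cohort, "challenge1": ch1, "challenge2": ch2,
            "dissociation": diss, "seed": config.seed}


def report_json(results: dict) -> str:
    """Serialisable summary of a run_all result (correlations + comparisons)."""
    ch1, ch2, diss = (results["challenge1"], results["challenge2"],
                      results["dissociation"])
    out = {
        "seed": results["seed"],
        "n_participants": len(results["cohort"]),
        "perception_correlations":
            ch1["perception_correlations"].to_dict("records"),
        "adaptation_correlations":
            ch1["adaptation_correlations"].to_dict("records"),
        "comprehension_correlations":
            ch2["comprehension_correlations"].to_dict("records"),
        "priming_correlations":
            ch2["priming_correlations"].to_dict("records"),
        "accuracy_exclusions": asdict(ch2["accuracy_exclusions"]) | {
            "excluded_index": None},
        "rt_exclusions": asdict(ch2["rt_exclusions"]) | {
            "excluded_index": None},
        "n_assoc_excluded": ch2["n_assoc_excluded"],
        "n_assoc_remaining": ch2["n_assoc_remaining"],
        "dissociation": {k: {"z": v.z, "p_two_tailed": v.p_two_tailed,
                             "r1": v.r1, "r2": v.r2, "r12": v.r12, "n": v.n}
                         for k, v in diss["comparisons"].items()},
        "multiple_testing_correction": "none",
    }
    return json.dumps(out, indent=2)
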