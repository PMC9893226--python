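"""Synthetic cohorts, behavioural trial tables, toy audio and toy imaging
volumes carrying the statistical structure the analysis pipeline assumes.

Every generator is deterministic given the config seed: each draws from its
own named substream so tables can be regenerated independently and
byte-identically.

The ``paper_counts_fixture`` flags reproduce, for an 18-participant cohort,
the exact pattern of exclusion-triggering trials the published counts imply
(anticipatory responses, incorrect coherent judgements, over-slow responses),
injected deterministically into otherwise clean data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import psychometrics as psy
from .lesion import VolumeGrid

__all__ = [
    "CohortConfig",
    "Participant",
    "StimulusSet",
    "generate_cohort",
    "build_stimulus_sets",
    "set_assignment",
    "generate_word_report_trials",
    "generate_coherence_trials",
    "generate_association_trials",
    "generate_toy_audio",
    "generate_toy_volumes",
    "sphere_mask",
    "DEGRADATION_LEVELS",
]

#: degradation levels; clear speech is treated as 32-channel vocoded speech
DEGRADATION_LEVELS = ("clear", 16, 8, 4)

_N_HIGH = 20    # high-ambiguity coherent sentences per participant
_N_LOW = 20     # low-ambiguity coherent sentences per participant
_N_ANOM = 40    # anomalous sentences, shared across participants
_N_WORDS = 80   # association words (2 per high-ambiguity sentence)

# substream tags so each generator has an independent, reproducible stream
_STREAMS = {"cohort": 1, "word_report": 2, "coherence": 3, "association": 4,
            "dominance": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed),
                               spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class CohortConfig:
    """Population parameters of a synthetic lesion cohort."""

    n_participants: int = 19
    seed: int = 0
    # lesion volumes (cm^3), log-normal with median exp(mu) per network and
    # a configurable between-network correlation of the log volumes
    lesion_lognorm_mu: float = math.log(8.0)
    lesion_lognorm_sigma: float = 0.75
    lesion_network_corr: float = 0.2
    # couplings between lesion volume and latent behaviour
    coupling_md_threshold: float = 0.03      # log2-channels per cm^3
    coupling_lang_priming: float = 0.03      # log-odds per cm^3
    noise_sd_alpha: float = 0.4
    noise_sd_priming: float = 0.3
    # psychometric generation
    baseline_alpha: float = 2.5              # log2-channels
    training_gain: float = 0.4               # log2-channels, pre -> post
    psychometric_slope: float = 2.0
    # coherence generation
    coherence_error_rate: float = 0.03
    anomalous_error_rate: float = 0.01
    rt_log10_mean: float = 2.95              # log10 ms from sentence offset
    rt_log10_sd: float = 0.12
    rt_participant_sd: float = 0.05
    ambiguity_rt_cost: float = 0.043         # log10 units, high - low
    ambiguity_rt_cost_sd: float = 0.0
    # word association generation
    baseline_subordinate_rate: float = 0.29
    priming_log_odds: float = 0.352
    dominance_slope: float = 1.112
    priming_dominance_interaction: float = -0.300
    dominance_mean: float = 0.31
    dominance_sd: float = 0.25

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        for name, val in asdict(self).items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite config value for {name}")
        for name in ("baseline_subordinate_rate",):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("lesion_lognorm_sigma", "psychometric_slope",
                     "rt_log10_sd", "dominance_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_sd_alpha", "noise_sd_priming",
                     "ambiguity_rt_cost_sd", "rt_participant_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not -1.0 < self.lesion_network_corr < 1.0:
            raise ValueError("lesion_network_corr must lie in (-1, 1)")


@dataclass(frozen=True)
class Participant:
    id: str
    group: str                      # LANG / MD / OTHER
    lesion_vol_lang: float
    lesion_vol_md: float
    lesion_vol_total: float
    latent_alpha_pre: float
    latent_alpha_post: float
    latent_priming: float
    latent_rt_intercept: float = 0.0
    latent_rt_cost: float = 0.0


@dataclass(frozen=True)
class StimulusSet:
    """Five sentence word counts summing to exactly 45 words."""

    set_id: int
    word_counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.word_counts) != 5 or sum(self.word_counts) != 45:
            raise ValueError("a stimulus set is 5 sentences totalling 45 words")
        if any(not 6 <= w <= 13 for w in self.word_counts):
            raise ValueError("sentence word counts must lie in 6..13")

    @property
    def total_words(self) -> int:
        return sum(self.word_counts)


# eight fixed quintuples of word counts, each in 6..13 and summing to 45
_SET_COUNTS = (
    (6, 7, 9, 11, 12),
    (6, 8, 9, 10, 12),
    (7, 8, 9, 10, 11),
    (6, 7, 8, 11, 13),
    (6, 8, 8, 10, 13),
    (7, 7, 9, 11, 11),
    (6, 9, 9, 9, 12),
    (7, 8, 8, 9, 13),
)


def build_stimulus_sets() -> list[StimulusSet]:
    """The eight five-sentence stimulus sets (40 sentences, 45 words each set)."""
    return [StimulusSet(set_id=i + 1, word_counts=c)
            for i, c in enumerate(_SET_COUNTS)]


def set_assignment(participant_index: int) -> dict[int, tuple[str, object]]:
    """Counterbalanced map set_id -> (phase, degradation level).

    A Latin-square rotation: across any 8 consecutive participants every set
    appears at every (phase, level) cell exactly once.
    """
    cells = [(phase, level) for phase in ("pre", "post")
             for level in DEGRADATION_LEVELS]
    return {s + 1: cells[(s + participant_index) % 8] for s in range(8)}


def _assign_group(vol_lang: float, vol_md: float) -> str:
    if max(vol_lang, vol_md) < 2.0:
        return "OTHER"
    return "LANG" if vol_lang >= vol_md else "MD"


def generate_cohort(config: CohortConfig) -> list[Participant]:
    """Draw a cohort with lesion volumes coupled to latent behaviour.

    latent_alpha_pre = baseline_alpha + coupling_md_threshold * vol_md + noise
    latent_alpha_post = latent_alpha_pre - training_gain
    latent_priming = priming_log_odds - coupling_lang_priming * vol_lang + noise
    """
    rng = _rng(config.seed, "cohort")
    participants = []
    rho = config.lesion_network_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)
    for i in range(config.n_participants):
        z = chol @ rng.standard_normal(2)
        vol_lang = math.exp(config.lesion_lognorm_mu
                            + config.lesion_lognorm_sigma * z[0])
        vol_md = math.exp(config.lesion_lognorm_mu
                          + config.lesion_lognorm_sigma * z[1])
        vol_other = math.exp(config.lesion_lognorm_mu - 1.0
                             + 0.5 * rng.standard_normal())
        alpha_pre = (config.baseline_alpha
                     + config.coupling_md_threshold * vol_md
                     + config.noise_sd_alpha * rng.standard_normal())
        priming = (config.priming_log_odds
                   - config.coupling_lang_priming * vol_lang
                   + config.noise_sd_priming * rng.standard_normal())
        rt_icpt = config.rt_participant_sd * rng.standard_normal()
        rt_cost = config.ambiguity_rt_cost_sd * rng.standard_normal()
        participants.append(Participant(
            id=f"p{i:03d}",
            group=_assign_group(vol_lang, vol_md),
            lesion_vol_lang=vol_lang,
            lesion_vol_md=vol_md,
            lesion_vol_total=vol_lang + vol_md + vol_other,
            latent_alpha_pre=alpha_pre,
            latent_alpha_post=alpha_pre - config.training_gain,
            latent_priming=priming,
            latent_rt_intercept=rt_icpt,
            latent_rt_cost=rt_cost,
        ))
    return participants


def cohort_frame(cohort: list[Participant]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in cohort])


def _level_channels(level) -> int:
    if level == "clear":
        return psy.CLEAR_CHANNELS
    if level in (16, 8, 4):
        return int(level)
    raise ValueError(f"unknown degradation level {level!r}")


def generate_word_report_trials(cohort: list[Participant],
                                stimulus_sets: list[StimulusSet],
                                config: CohortConfig) -> pd.DataFrame:
    """Word-report counts per sentence from each participant's latent
    psychometric curve: one stimulus set per (phase, level) cell, words
    correct drawn binomially at p = f(log2 channels)."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    sets = {s.set_id: s for s in stimulus_sets}
    rng = _rng(config.seed, "word_report")
    rows = []
    for i, part in enumerate(cohort):
        assignment = set_assignment(i)
        for set_id, (phase, level) in sorted(assignment.items()):
            channels = _level_channels(level)
            alpha = (part.latent_alpha_pre if phase == "pre"
                     else part.latent_alpha_post)
            p = psy.psychometric(math.log2(channels), alpha,
                                 config.psychometric_slope, 0.0, 0.0)
            for j, n_words in enumerate(sets[set_id].word_counts):
                rows.append({
                    "participant": part.id,
                    "phase": phase,
                    "level": str(level),
                    "channels": channels,
                    "set_id": set_id,
                    "sentence": f"s{set_id}_{j}",
                    "n_words": n_words,
                    "k_correct": int(rng.binomial(n_words, p)),
                })
    return pd.DataFrame(rows)


def _participant_lists(i: int) -> tuple[list[str], list[str]]:
    """Coherent sentence lists: even participants get list A, odd list B."""
    if i % 2 == 0:
        high = [f"hs{k:02d}" for k in range(20)]
        low = [f"ls{k:02d}" for k in range(20)]
    else:
        high = [f"hs{k:02d}" for k in range(20, 40)]
        low = [f"ls{k:02d}" for k in range(20, 40)]
    return high, low


def generate_coherence_trials(cohort: list[Participant], config: CohortConfig,
                              paper_counts_fixture: bool = False) -> pd.DataFrame:
    """80 coherence-judgement trials per participant (20 high-ambiguity, 20
    low-ambiguity, 40 anomalous) with a log10-RT ambiguity cost.

    With ``paper_counts_fixture`` (requires exactly 18 participants) the data
    are generated clean and the published exclusion-triggering pattern is
    injected deterministically: 2 anomalous + 1 low-ambiguity anticipatory
    responses, 23 incorrect coherent judgements (14 high-, 9 low-ambiguity)
    and 3 over-slow (> 4000 ms) responses, pairwise non-overlapping.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if paper_counts_fixture and len(cohort) != 18:
        raise ValueError("paper_counts_fixture requires exactly 18 participants")
    rng = _rng(config.seed, "coherence")
    frames = []
    for i, part in enumerate(cohort):
        high, low = _participant_lists(i)
        anom = [f"as{k:02d}" for k in range(_N_ANOM)]
        sent_ids = high + low + anom
        types = (["high_ambiguity"] * _N_HIGH + ["low_ambiguity"] * _N_LOW
                 + ["anomalous"] * _N_ANOM)
        order = rng.permutation(len(sent_ids))
        df = pd.DataFrame({
            "participant": part.id,
            "sentence_id": np.asarray(sent_ids)[order],
            "sentence_type": np.asarray(types)[order],
        })
        coherent = df["sentence_type"] != "anomalous"
        if paper_counts_fixture:
            correct = np.ones(len(df), dtype=bool)
        else:
            err = np.where(coherent, config.coherence_error_rate,
                           config.anomalous_error_rate)
            correct = rng.random(len(df)) >= err
        df["judged_coherent"] = np.where(coherent, correct, ~correct)
        df["correct"] = correct
        cost = config.ambiguity_rt_cost + part.latent_rt_cost
        logrt = (config.rt_log10_mean + part.latent_rt_intercept
                 + np.where(df["sentence_type"] == "high_ambiguity", cost, 0.0)
                 + config.rt_log10_sd * rng.standard_normal(len(df)))
        if paper_counts_fixture:
            # keep clean RTs strictly inside the admissible window
            logrt = np.clip(logrt, 2.0, 3.55)
        df["rt_from_offset"] = 10.0 ** logrt
        frames.append(df)
    trials = pd.concat(frames, ignore_index=True)
    if paper_counts_fixture:
        _inject_fixture(trials, cohort)
    return trials


def _first_idx(trials: pd.DataFrame, pid: str, stype: str, position: int = 0):
    idx = trials.index[(trials["participant"] == pid)
                       & (trials["sentence_type"] == stype)]
    return idx[position]


def _inject_fixture(trials: pd.DataFrame, cohort: list[Participant]) -> None:
    # deterministic placement: first/last eligible trials per participant,
    # participants taken in id order
    pids = [p.id for p in cohort]
    for pid in pids[:14]:       # 14 incorrect high-ambiguity judgements
        k = _first_idx(trials, pid, "high_ambiguity", 0)
        trials.loc[k, ["judged_coherent", "correct"]] = [False, False]
    for pid in pids[:9]:        # 9 incorrect low-ambiguity judgements
        k = _first_idx(trials, pid, "low_ambiguity", 0)
        trials.loc[k, ["judged_coherent", "correct"]] = [False, False]
    for pid in pids[:2]:        # 2 anticipatory anomalous responses
        k = _first_idx(trials, pid, "anomalous", 0)
        trials.loc[k, "rt_from_offset"] = -400.0
    # 1 anticipatory (correct) low-ambiguity response
    k = _first_idx(trials, pids[2], "low_ambiguity", -1)
    trials.loc[k, "rt_from_offset"] = -350.0
    for pid in pids[:3]:        # 3 over-slow correct high-ambiguity responses
        k = _first_idx(trials, pid, "high_ambiguity", -1)
        trials.loc[k, "rt_from_offset"] = 4500.0


def _dominance_values(config: CohortConfig) -> np.ndarray:
    """Word-level dominance norms: Beta with the configured mean and SD."""
    m, s = config.dominance_mean, config.dominance_sd
    nu = m * (1 - m) / s ** 2 - 1.0
    if nu <= 0:
        raise ValueError("dominance mean/sd imply an invalid Beta distribution")
    rng = _rng(config.seed, "dominance")
    return rng.beta(m * nu, (1 - m) * nu, size=_N_WORDS)


def generate_association_trials(cohort: list[Participant],
                                config: CohortConfig,
                                paper_counts_fixture: bool = False,
                                coherence_trials: pd.DataFrame | None = None
                                ) -> pd.DataFrame:
    """80 word-association trials per participant, half primed.

    Word 2j and 2j+1 are the two ambiguous targets of high-ambiguity sentence
    j; a word is primed when its source sentence was presented to that
    participant in the coherence task (counterbalanced by list).  Consistency
    with the subordinate meaning is Bernoulli with deviation-coded log-odds
    (primed_c = +-1/2, dom_c = dominance - mean)

        logit(baseline) + latent_priming * (primed_c + 1/2)
        + slope * dom_c + interaction * primed_c * dom_c

    so unprimed trials at mean dominance sit exactly at the configured
    baseline rate and a deviation-coded logistic fit recovers the configured
    slope/interaction directly.

    In fixture mode (18 participants, ``coherence_trials`` from the fixture
    generator required) an ``excluded`` column marks the primed words from
    each participant's misjudged high-ambiguity sentences.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if paper_counts_fixture:
        if len(cohort) != 18:
            raise ValueError(
                "paper_counts_fixture requires exactly 18 participants")
        if coherence_trials is None:
            raise ValueError(
                "fixture mode needs the fixture coherence trial table")
    dominance = _dominance_values(config)
    rng = _rng(config.seed, "association")
    base_logit = math.log(config.baseline_subordinate_rate
                          / (1.0 - config.baseline_subordinate_rate))
    rows = []
    for i, part in enumerate(cohort):
        high, _ = _participant_lists(i)
        primed_sentences = set(high)
        for w in range(_N_WORDS):
            sent = f"hs{w // 2:02d}"
            primed = sent in primed_sentences
            dom_c = dominance[w] - config.dominance_mean
            primed_c = 0.5 if primed else -0.5
            eta = (base_logit
                   + part.latent_priming * (primed_c + 0.5)
                   + config.dominance_slope * dom_c
                   + config.priming_dominance_interaction * primed_c * dom_c)
            rows.append({
                "participant": part.id,
                "word_id": f"w{w:02d}",
                "source_sentence_id": sent,
                "primed": primed,
                "dominance": float(dominance[w]),
                "consistent": int(rng.random() < 1.0 / (1.0 + math.exp(-eta))),
            })
    trials = pd.DataFrame(rows)
    if paper_counts_fixture:
        high = coherence_trials[
            coherence_trials["sentence_type"] == "high_ambiguity"]
        misjudged = set(zip(
            high.loc[~high["correct"].astype(bool), "participant"],
            high.loc[~high["correct"].astype(bool), "sentence_id"]))
        trials["excluded"] = trials["primed"] & np.array([
            (p, s) in misjudged
            for p, s in zip(trials["participant"],
                            trials["source_sentence_id"])])
    return trials


def generate_toy_audio(duration_s: float, sample_rate: int = 22050,
                       seed: int = 0) -> np.ndarray:
    """Deterministic broadband test signal: a 100 Hz harmonic complex
    spanning 50-8000 Hz, amplitude-modulated at 4 Hz, plus faint noise."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate < 16000:
        raise ValueError("sample_rate must be >= 16000 Hz (8 kHz band edge)")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    f0 = 100.0
    signal = np.zeros_like(t)
    n_harm = int(8000.0 // f0)
    for n in range(1, n_harm + 1):
        phase = rng.uniform(0, 2 * np.pi)
        signal += np.sin(2 * np.pi * n * f0 * t + phase) / math.sqrt(n)
    am = 1.0 + 0.8 * np.sin(2 * np.pi * 4.0 * t)
    signal = signal * am + 0.01 * rng.standard_normal(t.size)
    return signal / np.max(np.abs(signal))


def sphere_mask(grid_shape, center, radius: float) -> np.ndarray:
    """Binary mask of the voxels whose centres lie within ``radius`` of
    ``center`` (in voxel units)."""
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return (d2 <= radius ** 2).astype(np.uint8)


def generate_toy_volumes(grid_shape=(32, 32, 32), voxel_size_mm: float = 2.0,
                         n_participants: int = 19, seed: int = 0
                         ) -> tuple[VolumeGrid, VolumeGrid, list[VolumeGrid]]:
    """Toy probabilistic network maps and per-participant lesion masks on a
    shared grid: Gaussian-blob probability fields (left-lateralised language,
    bilateral MD) and spherical lesions at seeded locations."""
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 4 for s in grid_shape):
        raise ValueError("grid_shape must be 3-D with each dim >= 4")
    dims = (float(voxel_size_mm),) * 3
    affine = np.diag([*dims, 1.0])
    rng = np.random.default_rng(seed)
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    shape = np.asarray(grid_shape, dtype=float)

    def blob(center_frac, width_frac):
        c = shape * np.asarray(center_frac)
        w = shape * np.asarray(width_frac)
        d2 = sum(((g - ci) / wi) ** 2 for g, ci, wi in zip(grids, c, w))
        return np.clip(np.exp(-d2 / 2.0), 0.0, 1.0)

    prob_lang = blob((0.3, 0.5, 0.5), (0.15, 0.2, 0.2))
    prob_md = np.maximum(blob((0.35, 0.3, 0.65), (0.12, 0.15, 0.15)),
                         blob((0.65, 0.3, 0.65), (0.12, 0.15, 0.15)))
    lang = VolumeGrid(prob_lang, dims, affine, kind="probability")
    md = VolumeGrid(prob_md, dims, affine, kind="probability")
    lesions = []
    for _ in range(n_participants):
        center = rng.uniform(0.2, 0.8, size=3) * shape
        radius = rng.uniform(0.05, 0.2) * float(min(grid_shape))
        lesions.append(VolumeGrid(sphere_mask(grid_shape, center, radius),
                                  dims, affine, kind="binary"))
    return lang, md, lesions
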