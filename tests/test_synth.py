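import math

import numpy as np
import pandas as pd
import pytest

from lesionspeech import synth
from lesionspeech.lesion import lesion_overlap, threshold_map
from lesionspeech.synth import (CohortConfig, build_stimulus_sets,
                                generate_association_trials,
                                generate_coherence_trials, generate_cohort,
                                generate_toy_audio, generate_toy_volumes,
                                generate_word_report_trials, set_assignment,
                                sphere_mask)


class TestConfig:
    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_participants=-1)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(baseline_alpha=float("nan"))

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            CohortConfig(baseline_subordinate_rate=1.2)


class TestGenerateCohort:
    def test_empty_cohort(self):
        assert generate_cohort(CohortConfig(n_participants=0)) == []

    def test_zero_effect_case(self):
        cfg = CohortConfig(n_participants=10, coupling_md_threshold=0.0,
                           noise_sd_alpha=0.0)
        cohort = generate_cohort(cfg)
        assert all(p.latent_alpha_pre == cfg.baseline_alpha for p in cohort)

    def test_training_gain_constant_shift(self):
        cohort = generate_cohort(CohortConfig(n_participants=8, seed=2))
        for p in cohort:
            assert p.latent_alpha_pre - p.latent_alpha_post == \
                pytest.approx(0.4)

    def test_determinism(self):
        cfg = CohortConfig(n_participants=12, seed=3)
        assert generate_cohort(cfg) == generate_cohort(cfg)

    def test_volumes_nonnegative(self):
        for p in generate_cohort(CohortConfig(n_participants=30, seed=4)):
            assert p.lesion_vol_lang >= 0
            assert p.lesion_vol_md >= 0
            assert p.lesion_vol_total >= 0

    def test_closed_form_correlation_oracle(self):
        """Sample r(vol_md, alpha_pre) near the closed-form value
        r = slope * sd(vol) / sd(alpha) implied by the config."""
        cfg = CohortConfig(n_participants=200, seed=5)
        cohort = generate_cohort(cfg)
        vols = np.array([p.lesion_vol_md for p in cohort])
        alphas = np.array([p.latent_alpha_pre for p in cohort])
        # independent oracle from the generative equation, using the sample
        # volume spread (lognormal tails make the population sd unstable)
        slope = cfg.coupling_md_threshold
        r_oracle = slope * vols.std() / math.sqrt(
            (slope * vols.std()) ** 2 + cfg.noise_sd_alpha ** 2)
        r_sample = np.corrcoef(vols, alphas)[0, 1]
        assert r_sample == pytest.approx(r_oracle, abs=0.1)

    def test_network_volume_correlation_configurable(self):
        cfg = CohortConfig(n_participants=2000, seed=6,
                           lesion_network_corr=0.6)
        cohort = generate_cohort(cfg)
        logs = np.array([[math.log(p.lesion_vol_lang),
                          math.log(p.lesion_vol_md)] for p in cohort])
        assert np.corrcoef(logs.T)[0, 1] == pytest.approx(0.6, abs=0.05)


class TestStimulusSets:
    def test_each_set_totals_45(self):
        sets = build_stimulus_sets()
        assert len(sets) == 8
        for s in sets:
            assert s.total_words == 45
            assert len(s.word_counts) == 5
            assert all(6 <= w <= 13 for w in s.word_counts)

    def test_forty_sentences_total(self):
        assert sum(len(s.word_counts) for s in build_stimulus_sets()) == 40

    def test_counterbalancing_latin_square(self):
        """Across 8 participants each set hits each (phase, level) cell once."""
        seen = {s: set() for s in range(1, 9)}
        for i in range(8):
            for set_id, cell in set_assignment(i).items():
                seen[set_id].add(cell)
        for cells in seen.values():
            assert len(cells) == 8


class TestWordReportTrials:
    def test_row_count_19_participants(self):
        cfg = CohortConfig(n_participants=19, seed=7)
        cohort = generate_cohort(cfg)
        trials = generate_word_report_trials(cohort, build_stimulus_sets(), cfg)
        assert len(trials) == 760     # 19 x 2 phases x 4 levels x 5 sentences

    def test_determinism(self):
        cfg = CohortConfig(n_participants=1, seed=8)
        cohort = generate_cohort(cfg)
        sets = build_stimulus_sets()
        t1 = generate_word_report_trials(cohort, sets, cfg)
        t2 = generate_word_report_trials(cohort, sets, cfg)
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_cohort_rejected(self):
        cfg = CohortConfig(n_participants=0)
        with pytest.raises(ValueError):
            generate_word_report_trials([], build_stimulus_sets(), cfg)

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            synth._level_channels(2)

    def test_clear_speech_near_ceiling_for_good_alpha(self):
        cfg = CohortConfig(n_participants=6, seed=9,
                           baseline_alpha=1.0, noise_sd_alpha=0.0,
                           coupling_md_threshold=0.0)
        cohort = generate_cohort(cfg)
        trials = generate_word_report_trials(cohort, build_stimulus_sets(), cfg)
        clear = trials[trials["level"] == "clear"]
        assert clear["k_correct"].sum() / clear["n_words"].sum() > 0.98

    def test_accuracy_monotone_in_channels(self):
        cfg = CohortConfig(n_participants=30, seed=10)
        cohort = generate_cohort(cfg)
        trials = generate_word_report_trials(cohort, build_stimulus_sets(), cfg)
        acc = trials.groupby("channels").apply(
            lambda g: g["k_correct"].sum() / g["n_words"].sum(),
            include_groups=False)
        assert acc.loc[4] < acc.loc[8] < acc.loc[16] < acc.loc[32]


class TestCoherenceTrials:
    def test_1440_rows_for_18(self):
        cfg = CohortConfig(n_participants=18, seed=11)
        trials = generate_coherence_trials(generate_cohort(cfg), cfg)
        assert len(trials) == 1440

    def test_null_rt_cost(self):
        cfg = CohortConfig(n_participants=40, seed=12, ambiguity_rt_cost=0.0)
        trials = generate_coherence_trials(generate_cohort(cfg), cfg)
        logrt = np.log10(trials["rt_from_offset"])
        means = logrt.groupby(trials["sentence_type"]).mean()
        diff = means["high_ambiguity"] - means["low_ambiguity"]
        # MC error: sd 0.12+ over 800 trials per cell
        assert abs(diff) < 3 * 0.15 * math.sqrt(2 / 800)

    def test_fixture_flag_counts(self, fixture_coherence):
        fast = fixture_coherence["rt_from_offset"] < -300
        slow = fixture_coherence["rt_from_offset"] > 4000
        incorrect = ~fixture_coherence["correct"]
        assert fast.sum() == 3
        assert slow.sum() == 3
        assert incorrect.sum() == 23
        high_bad = incorrect & (
            fixture_coherence["sentence_type"] == "high_ambiguity")
        assert high_bad.sum() == 14

    def test_fixture_requires_18(self):
        cfg = CohortConfig(n_participants=17, seed=13)
        with pytest.raises(ValueError):
            generate_coherence_trials(generate_cohort(cfg), cfg,
                                      paper_counts_fixture=True)

    def test_determinism(self):
        cfg = CohortConfig(n_participants=5, seed=14)
        cohort = generate_cohort(cfg)
        pd.testing.assert_frame_equal(
            generate_coherence_trials(cohort, cfg),
            generate_coherence_trials(cohort, cfg))

    def test_correctness_invariant(self):
        cfg = CohortConfig(n_participants=10, seed=15)
        t = generate_coherence_trials(generate_cohort(cfg), cfg)
        coherent = t["sentence_type"] != "anomalous"
        assert (t["correct"] == np.where(coherent, t["judged_coherent"],
                                         ~t["judged_coherent"])).all()


class TestAssociationTrials:
    def test_dominance_moments(self):
        cfg = CohortConfig(n_participants=1, seed=16)
        dom = synth._dominance_values(cfg)
        # 80 draws from Beta targeting mean .31, sd .25
        assert dom.mean() == pytest.approx(0.31, abs=0.09)
        assert dom.std() == pytest.approx(0.25, abs=0.09)
        assert ((dom >= 0) & (dom <= 1)).all()

    def test_fixture_excluded_column(self, fixture_association):
        assert fixture_association["excluded"].sum() == 28

    def test_fixture_needs_coherence_table(self, fixture_cohort,
                                           fixture_config):
        with pytest.raises(ValueError):
            generate_association_trials(fixture_cohort, fixture_config,
                                        paper_counts_fixture=True)

    def test_determinism(self):
        cfg = CohortConfig(n_participants=4, seed=17)
        cohort = generate_cohort(cfg)
        pd.testing.assert_frame_equal(
            generate_association_trials(cohort, cfg),
            generate_association_trials(cohort, cfg))


class TestToyAudio:
    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_toy_audio(0.0, 22050)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            generate_toy_audio(1.0, 8000)

    def test_determinism(self):
        assert np.array_equal(generate_toy_audio(0.5, 22050, seed=1),
                              generate_toy_audio(0.5, 22050, seed=1))

    def test_energy_above_2khz(self):
        """Spectrum-integration oracle: nontrivial power above 2 kHz."""
        sig = generate_toy_audio(1.0, 22050, seed=2)
        spectrum = np.abs(np.fft.rfft(sig)) ** 2
        freqs = np.fft.rfftfreq(sig.size, 1 / 22050)
        frac = spectrum[freqs > 2000].sum() / spectrum.sum()
        assert frac > 0.05


class TestToyVolumes:
    def test_shapes_and_ranges(self):
        lang, md, lesions = generate_toy_volumes((16, 16, 16), 2.0, 3, seed=0)
        for g in (lang, md):
            assert g.kind == "probability"
            assert g.data.min() >= 0 and g.data.max() <= 1
        assert len(lesions) == 3
        for les in lesions:
            assert les.kind == "binary"
            assert les.data.shape == lang.data.shape

    def test_sphere_volume_oracle(self):
        """Voxel count within 5% of (4/3) pi r^3 (enumeration vs continuum)."""
        r = 8.0
        mask = sphere_mask((33, 33, 33), (16, 16, 16), r)
        analytic = 4.0 / 3.0 * math.pi * r ** 3
        assert abs(mask.sum() - analytic) / analytic < 0.05

    def test_zero_lesion_zero_overlap(self):
        lang, _, _ = generate_toy_volumes((12, 12, 12), 2.0, 1, seed=1)
        net = threshold_map(lang)
        empty = synth.VolumeGrid(np.zeros((12, 12, 12), dtype=np.uint8),
                                 net.voxel_dims, net.affine, kind="binary")
        assert lesion_overlap(empty, net).overlap_volume == 0.0

    def test_identity_overlap(self):
        lang, _, _ = generate_toy_volumes((12, 12, 12), 2.0, 1, seed=2)
        net = threshold_map(lang)
        res = lesion_overlap(net, net)
        assert res.overlap_volume == pytest.approx(res.network_volume)
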