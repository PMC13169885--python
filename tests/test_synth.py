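"""Generator tests: reproducibility, truth consistency, parameter recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from voicemark import synth
from voicemark.distributions import (ConfigurationError, Dist, normal, point,
                                     uniform)
from voicemark.synth import (GenerationError, GroupProfile, default_profiles,
                             generate_cohort, synthesize_transcript,
                             synthesize_utterance, wav_bytes)

from conftest import scaled_profiles


def bp_profile(**changes):
    prof = default_profiles()["BP"]
    return dataclasses.replace(prof, **changes)


class TestDistributions:
    def test_point_mass_samples_exactly(self):
        rng = np.random.default_rng(0)
        assert point(0.3).sample(rng) == 0.3
        assert np.all(point(0.3).sample(rng, size=10) == 0.3)

    def test_truncated_normal_respects_bounds_and_mean(self):
        rng = np.random.default_rng(0)
        d = normal(10.0, 2.0, 6.0, 14.0)
        x = d.sample(rng, size=4000)
        assert x.min() >= 6.0 and x.max() <= 14.0
        # symmetric truncation keeps the mean at the nominal value
        assert abs(x.mean() - 10.0) < 3 * 2.0 / np.sqrt(4000)

    @pytest.mark.parametrize("bad", [
        dict(kind="point"),
        dict(kind="normal", mean=1.0),
        dict(kind="normal", mean=1.0, sd=-0.5),
        dict(kind="uniform", low=2.0, high=1.0),
        dict(kind="exotic", value=1.0),
    ])
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            Dist(**bad)


class TestProfileValidation:
    def test_zero_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            bp_profile(n_subjects=0)

    def test_pause_fraction_support_bounded(self):
        with pytest.raises(ConfigurationError):
            bp_profile(pause_fraction=point(0.96))

    def test_probability_mass_bounded(self):
        with pytest.raises(ConfigurationError):
            bp_profile(negation_prob=1.5)


class TestUtterance:
    def test_zero_pause_fraction_has_no_silences(self):
        rng = np.random.default_rng(1)
        prof = bp_profile(pause_fraction=point(0.0),
                          speech_duration_s=point(10.0))
        wave, truth = synthesize_utterance(prof, rng)
        assert truth["n_silences"] == 0
        assert truth["pause_total_s"] == 0.0

    def test_pause_budget_matches_target_within_one_pause_length(self):
        rng = np.random.default_rng(2)
        prof = bp_profile(pause_fraction=point(0.25),
                          speech_duration_s=point(60.0),
                          pause_length_ms=uniform(250, 450))
        _wave, truth = synthesize_utterance(prof, rng)
        target = 0.25 * truth["duration_s"]
        assert abs(truth["pause_total_s"] - target) <= 0.45
        # truth log is self-consistent: intervals sum to the recorded total
        interval_sum = sum(e - s for s, e in truth["silences"])
        assert interval_sum == pytest.approx(truth["pause_total_s"], abs=1e-9)

    def test_point_mass_amplitude_sets_peak_exactly(self):
        rng = np.random.default_rng(3)
        prof = bp_profile(voiced_amplitude=point(0.5),
                          pause_fraction=point(0.0),
                          speech_duration_s=point(5.0))
        wave, _truth = synthesize_utterance(prof, rng)
        assert np.max(np.abs(wave)) == pytest.approx(0.5, abs=1e-9)

    def test_infeasible_pause_fraction_raises(self):
        rng = np.random.default_rng(4)
        prof = bp_profile(pause_fraction=point(0.93),
                          speech_duration_s=point(10.0))
        with pytest.raises(GenerationError):
            synthesize_utterance(prof, rng)


class TestTranscript:
    def test_all_neutral_mix_has_no_positive_or_negation(self, res):
        rng = np.random.default_rng(5)
        prof = bp_profile(lexical_mix={"neutral": 1.0}, keyword_probs={},
                          negation_prob=0.0,
                          words_per_subject=point(200))
        tokens, truth = synthesize_transcript(prof, rng, res)
        assert truth["ann_positive"] == 0
        assert truth["negation_count"] == 0
        assert truth["word_count"] == len(tokens) == 200

    def test_negation_count_within_binomial_interval(self, res):
        rng = np.random.default_rng(6)
        prof = bp_profile(words_per_subject=point(100), negation_prob=0.1)
        totals = 0
        n_subjects = 200
        for _ in range(n_subjects):
            _toks, truth = synthesize_transcript(prof, rng, res)
            totals += truth["negation_count"]
        n_trials = 100 * n_subjects
        lo = sps.binom.ppf(0.005, n_trials, 0.1)
        hi = sps.binom.ppf(0.995, n_trials, 0.1)
        assert lo <= totals <= hi

    def test_keyword_probability_recovered(self, res):
        rng = np.random.default_rng(7)
        prof = bp_profile(keyword_probs={"work": 0.05},
                          words_per_subject=point(10_000),
                          negation_prob=0.0)
        tokens, _truth = synthesize_transcript(prof, rng, res)
        freq = sum(1 for s, _t in tokens if s == "work") / len(tokens)
        assert freq == pytest.approx(0.05, abs=0.01)

    def test_empty_vocabulary_pool_rejected(self, res):
        rng = np.random.default_rng(8)
        prof = bp_profile(lexical_mix={"no_such_class": 1.0},
                          keyword_probs={})
        with pytest.raises(ConfigurationError):
            synthesize_transcript(prof, rng, res)


class TestCohort:
    def test_reproducible_byte_identical(self):
        profiles = scaled_profiles(n_bp=2, n_mdd=2, duration=10.0, words=50)
        a = generate_cohort(profiles, seed=11)
        b = generate_cohort(profiles, seed=11)
        for sa, sb in zip(a.subjects, b.subjects):
            assert wav_bytes(sa.waveform, sa.sample_rate) == \
                wav_bytes(sb.waveform, sb.sample_rate)
            assert sa.transcript == sb.transcript
            assert sa.demographics == sb.demographics

    def test_truth_consistency(self, small_cohort):
        for s in small_cohort.subjects:
            assert 0.0 <= s.truth["pause_total_s"] <= s.truth["duration_s"]
            assert s.truth["word_count"] == len(s.transcript.split())

    def test_point_mass_pause_fraction_recovered(self):
        profiles = {
            "BP": dataclasses.replace(
                scaled_profiles(n_bp=50, duration=20.0, words=30)["BP"],
                pause_fraction=point(0.30)),
        }
        bundle = generate_cohort(profiles, seed=12)
        ratios = [s.truth["pause_total_s"] / s.truth["duration_s"]
                  for s in bundle.subjects]
        # hop-grid quantisation bounds the per-subject error below 1e-4
        assert np.mean(ratios) == pytest.approx(0.30, abs=5e-5)

    def test_group_labels_and_sizes(self, small_cohort):
        labels = [s.label for s in small_cohort.subjects]
        assert labels.count("BP") == 6
        assert labels.count("MDD") == 6

    def test_write_cohort_roundtrip(self, tmp_path):
        profiles = scaled_profiles(n_bp=2, n_mdd=2, duration=10.0, words=40)
        bundle = generate_cohort(profiles, seed=13)
        manifest = synth.write_cohort(bundle, tmp_path)
        assert len(manifest) == 4
        assert (tmp_path / "truth.csv").exists()
        from voicemark.pipeline import load_cohort_dir
        loaded = load_cohort_dir(tmp_path)
        assert [s["subject_id"] for s in loaded] == \
            [s.subject_id for s in bundle.subjects]
        # PCM16 round trip preserves samples to quantisation accuracy
        assert np.allclose(loaded[0]["waveform"],
                           bundle.subjects[0].waveform, atol=1.0 / 32000)
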