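"""Shared fixtures: small synthetic cohorts so every stage is tested on
generated data with known ground truth."""

from __future__ import annotations

import dataclasses

import pytest

import voicemark as vm
from voicemark import synth
from voicemark.distributions import normal, point
from voicemark.resources import default_resources


@pytest.fixture(scope="session")
def res():
    return default_resources()


def scaled_profiles(n_bp=6, n_mdd=6, duration=20.0, words=150):
    """Default group profiles scaled down for fast tests."""
    profiles = synth.default_profiles()
    out = {}
    for label, n in (("BP", n_bp), ("MDD", n_mdd)):
        out[label] = dataclasses.replace(
            profiles[label],
            n_subjects=n,
            speech_duration_s=normal(duration, duration / 12,
                                     0.7 * duration, 1.3 * duration),
            words_per_subject=point(words),
        )
    return out


@pytest.fixture(scope="session")
def small_cohort():
    return synth.generate_cohort(scaled_profiles(), seed=7)


@pytest.fixture(scope="session")
def small_fm(small_cohort):
    fm, tfidf = vm.extract_features(small_cohort)
    return fm


@pytest.fixture(scope="session")
def small_tfidf(small_cohort):
    _fm, tfidf = vm.extract_features(small_cohort)
    return tfidf
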