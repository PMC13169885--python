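"""Synthetic cohort generator: audio, transcripts and demographics with
known ground truth.

The generator emulates the study design this package analyses: two
diagnostic groups (bipolar disorder, BP, n=41; major depressive disorder,
MDD, n=150), each subject contributing a ~60 s monologue recording and its
transcript.  Because the clinical recordings are private, every downstream
stage is exercised on cohorts produced here, and the generator writes a
per-subject ground-truth record (true pause intervals, true token category
counts, ...) so that extraction can be tested against known answers.

Audio model
-----------
A subject's waveform alternates voiced segments and true silences.  Voiced
segments are band-limited harmonic bursts (fundamental drawn from 120-220 Hz
plus two overtones, normalised so the segment's peak equals the drawn
per-segment amplitude) — pause and amplitude features depend only on the
envelope, so no attempt is made at phonetic realism.  Silences sit at a
-80 dBFS noise floor, far below the 35 dB relative detection threshold, so
detector behaviour is unambiguous.  The pause budget is allocated in whole
samples as ``round(pause_fraction * duration_samples)``; the realised
pause/duration ratio therefore matches a point-mass ``pause_fraction`` to
better than one part in 10**6 at 60 s / 16 kHz.

Transcript model
----------------
Tokens are whitespace-delimited pseudo-words written as ``surface/tag``
(the slash tagger in :mod:`voicemark.text` recovers the tag exactly).  Each
token draws a lexical class (polarity/emotion/stop-word/pronoun/keyword/
plain) from ``lexical_mix`` + ``keyword_probs`` and, independently, a raw
POS tag from ``pos_tag_probs``.  Negation words are inserted in front of
content tokens with probability ``negation_prob``.  Chinese segmentation is
not emulated; the tagger interface in :mod:`voicemark.text` is pluggable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .distributions import ConfigurationError, Dist, normal, point, uniform
from .resources import EMOTIONS, Resources, default_resources


class GenerationError(RuntimeError):
    """Raised when a profile is internally valid but cannot be realised."""


# ---------------------------------------------------------------------------
# demographics


@dataclass(frozen=True)
class Categorical:
    levels: Tuple[str, ...]
    probs: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.probs):
            raise ConfigurationError("levels/probs length mismatch")
        if any(p < 0 or p > 1 for p in self.probs):
            raise ConfigurationError("categorical probabilities must lie in [0, 1]")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ConfigurationError("categorical probabilities must sum to 1")

    def sample(self, rng: np.random.Generator) -> str:
        return self.levels[rng.choice(len(self.levels), p=np.asarray(self.probs))]


#: demographic schema: field -> ordered levels (None = numeric field).
#: Level order is the integer encoding used in the feature matrix.
DEMOGRAPHIC_SCHEMA: Dict[str, Optional[Tuple[str, ...]]] = {
    "sex": ("female", "male"),
    "age": None,
    "education": ("elementary", "junior_high", "senior_high", "college_or_higher"),
    "occupation": ("no", "yes"),
    "marriage": ("unmarried", "married", "divorced"),
    "suicide_history": ("no", "yes"),
    "hospitalization": ("never", "within_past_year", "more_than_one_year_ago"),
    "residential": ("with_family", "alone"),
    "alcohol": ("lt3_per_week", "ge3_per_week"),
    "physical_illnesses": None,
}


# ---------------------------------------------------------------------------
# group profile


@dataclass(frozen=True)
class GroupProfile:
    """Everything the generator needs to emit one diagnostic group."""

    n_subjects: int
    speech_duration_s: Dist
    pause_fraction: Dist
    pause_length_ms: Dist
    voiced_amplitude: Dist
    words_per_subject: Dist
    keyword_probs: Mapping[str, float]
    lexical_mix: Mapping[str, float]
    pos_tag_probs: Mapping[str, float]
    negation_prob: float
    demographics: Mapping[str, object]
    voiced_segment_s: Dist = field(default_factory=lambda: uniform(0.8, 2.2))
    f0_range_hz: Tuple[float, float] = (120.0, 220.0)
    noise_floor_db: float = -80.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        lo, hi = self.pause_fraction.bounds()
        if lo < 0 or hi > 0.95:
            raise ConfigurationError("pause_fraction support must lie in [0, 0.95]")
        alo, ahi = self.voiced_amplitude.bounds()
        if alo < 0 or ahi > 1:
            raise ConfigurationError("voiced_amplitude must lie in [0, 1]")
        if not 0 <= self.negation_prob <= 1:
            raise ConfigurationError("negation_prob must lie in [0, 1]")
        for name, probs in (("keyword_probs", self.keyword_probs),
                            ("lexical_mix", self.lexical_mix),
                            ("pos_tag_probs", self.pos_tag_probs)):
            for key, p in probs.items():
                if not 0 <= p <= 1:
                    raise ConfigurationError(f"{name}[{key!r}] outside [0, 1]")
        total = sum(self.lexical_mix.values()) + sum(self.keyword_probs.values())
        if total > 1.0 + 1e-9:
            raise ConfigurationError(
                "lexical_mix + keyword_probs mass exceeds 1 "
                f"(got {total:.4f}); the remainder is the plain-word class")
        if sum(self.pos_tag_probs.values()) > 1.0 + 1e-9:
            raise ConfigurationError("pos_tag_probs mass exceeds 1")
        for fname, spec in self.demographics.items():
            if fname not in DEMOGRAPHIC_SCHEMA:
                raise ConfigurationError(f"unknown demographic field {fname!r}")
            if DEMOGRAPHIC_SCHEMA[fname] is not None and isinstance(spec, Categorical):
                if spec.levels != DEMOGRAPHIC_SCHEMA[fname]:
                    raise ConfigurationError(
                        f"demographic {fname!r}: levels must equal schema order")


# lexical classes with surface pools drawn from the bundled lexica
_SENTIMENT_CLASSES = ("positive", "negative", "neutral", "non_opinionated",
                      "not_a_word")
_PRONOUN_CLASSES = ("pronoun_first", "pronoun_second", "pronoun_third")

_PLAIN_POOL = tuple(f"topic{i:02d}" for i in range(60))

_DEFAULT_KEYWORDS_SHARED = {
    "work": 0.012, "sleep": 0.012, "doctor": 0.008, "body": 0.008,
    "stress": 0.008, "family": 0.008, "money": 0.006, "night": 0.006,
    "mood": 0.006, "medicine": 0.006, "school": 0.004, "friend": 0.004,
    "weather": 0.004, "exercise": 0.004, "appetite": 0.004,
}
# group-weighted keywords give the classifier a linguistic signal to find
_BP_KEYWORDS = {"spirit": 0.010, "energy": 0.008, "travel": 0.006,
                "busy": 0.006, "active": 0.005,
                "emotion": 0.002, "normal": 0.002, "quiet": 0.001,
                "slow": 0.001, "tranquil": 0.001}
_MDD_KEYWORDS = {"spirit": 0.002, "energy": 0.002, "travel": 0.001,
                 "busy": 0.001, "active": 0.001,
                 "emotion": 0.010, "normal": 0.008, "quiet": 0.006,
                 "slow": 0.006, "tranquil": 0.005}


def _default_lexical_mix(group: str) -> Dict[str, float]:
    bp = group == "BP"
    mix = {
        "positive": 0.110 if bp else 0.105,
        "negative": 0.064 if bp else 0.070,
        "neutral": 0.012 if bp else 0.013,
        "non_opinionated": 0.004 if bp else 0.008,
        "not_a_word": 0.001,
        "stopword": 0.20,
        "pronoun_first": 0.001 if bp else 0.003,
        "pronoun_second": 0.031 if bp else 0.044,
        "pronoun_third": 0.005 if bp else 0.011,
    }
    emotion_p = {
        "Anger": (0.013, 0.016), "Anticipation": (0.031, 0.033),
        "Disgust": (0.011, 0.011), "Fear": (0.022, 0.021),
        "Joy": (0.028, 0.028), "Sadness": (0.021, 0.022),
        "Surprise": (0.019, 0.020), "Trust": (0.035, 0.037),
    }
    for emo, (p_bp, p_mdd) in emotion_p.items():
        mix[f"emotion_{emo}"] = p_bp if bp else p_mdd
    return mix


_DEFAULT_POS_TAG_PROBS = {
    "a": 0.032, "c": 0.003, "d": 0.220, "n": 0.125, "v": 0.060,
    "q": 0.028, "p": 0.032, "r": 0.032, "t": 0.044, "m": 0.010, "u": 0.050,
}


def _bp_demographics() -> Dict[str, object]:
    return {
        "sex": Categorical(("female", "male"), (29 / 41, 12 / 41)),
        "age": normal(39.9, 11.2, 18, 90),
        "education": Categorical(
            DEMOGRAPHIC_SCHEMA["education"], (0.0, 5 / 41, 15 / 41, 21 / 41)),
        "occupation": Categorical(("no", "yes"), (17 / 41, 24 / 41)),
        "marriage": Categorical(
            DEMOGRAPHIC_SCHEMA["marriage"], (22 / 41, 14 / 41, 5 / 41)),
        "suicide_history": Categorical(("no", "yes"), (24 / 41, 17 / 41)),
        "hospitalization": Categorical(
            DEMOGRAPHIC_SCHEMA["hospitalization"], (20 / 41, 2 / 41, 19 / 41)),
        "residential": Categorical(("with_family", "alone"), (35 / 41, 6 / 41)),
        "alcohol": Categorical(
            ("lt3_per_week", "ge3_per_week"), (38 / 41, 3 / 41)),
        "physical_illnesses": ("poisson", 0.68),
    }


def _mdd_demographics() -> Dict[str, object]:
    return {
        "sex": Categorical(("female", "male"), (112 / 150, 38 / 150)),
        "age": normal(42.48, 12.9, 18, 90),
        "education": Categorical(
            DEMOGRAPHIC_SCHEMA["education"],
            (9 / 150, 13 / 150, 50 / 150, 78 / 150)),
        "occupation": Categorical(("no", "yes"), (77 / 150, 73 / 150)),
        "marriage": Categorical(
            DEMOGRAPHIC_SCHEMA["marriage"], (73 / 150, 65 / 150, 12 / 150)),
        "suicide_history": Categorical(("no", "yes"), (98 / 150, 52 / 150)),
        "hospitalization": Categorical(
            DEMOGRAPHIC_SCHEMA["hospitalization"],
            (112 / 150, 17 / 150, 21 / 150)),
        "residential": Categorical(("with_family", "alone"), (119 / 150, 31 / 150)),
        "alcohol": Categorical(
            ("lt3_per_week", "ge3_per_week"), (144 / 150, 6 / 150)),
        "physical_illnesses": ("poisson", 0.42),
    }


def default_profiles() -> Dict[str, GroupProfile]:
    """The default study-shaped cohort: 41 BP + 150 MDD subjects.

    Group centres follow the observed direction of the clinical tables:
    BP pauses less (fraction ~0.19 vs ~0.30), speaks more words (~201 vs
    ~146) at lower and less variable amplitude than MDD.  Spreads are
    calibration choices documented in the methods note.
    """
    return {
        "BP": GroupProfile(
            n_subjects=41,
            speech_duration_s=normal(60.0, 5.0, 45.0, 75.0),
            pause_fraction=normal(0.19, 0.05, 0.04, 0.34),
            pause_length_ms=uniform(250.0, 450.0),
            voiced_amplitude=normal(0.16, 0.05, 0.02, 0.30),
            words_per_subject=normal(201.0, 35.0, 80.0, 322.0),
            keyword_probs={**_DEFAULT_KEYWORDS_SHARED, **_BP_KEYWORDS},
            lexical_mix=_default_lexical_mix("BP"),
            pos_tag_probs=dict(_DEFAULT_POS_TAG_PROBS),
            negation_prob=0.0147,
            demographics=_bp_demographics(),
        ),
        "MDD": GroupProfile(
            n_subjects=150,
            speech_duration_s=normal(60.0, 5.0, 45.0, 75.0),
            pause_fraction=normal(0.30, 0.08, 0.06, 0.54),
            pause_length_ms=uniform(250.0, 450.0),
            voiced_amplitude=normal(0.40, 0.17, 0.06, 0.74),
            words_per_subject=normal(146.0, 30.0, 60.0, 232.0),
            keyword_probs={**_DEFAULT_KEYWORDS_SHARED, **_MDD_KEYWORDS},
            lexical_mix=_default_lexical_mix("MDD"),
            pos_tag_probs=dict(_DEFAULT_POS_TAG_PROBS),
            negation_prob=0.0185,
            demographics=_mdd_demographics(),
        ),
    }


# ---------------------------------------------------------------------------
# waveform synthesis


def synthesize_utterance(profile: GroupProfile, rng: np.random.Generator,
                         sample_rate: int = 16000
                         ) -> Tuple[np.ndarray, Dict[str, object]]:
    """Build one alternating voiced/silence waveform and its truth log.

    Returns ``(samples, truth)`` where truth records the total duration,
    the exact pause budget in samples, and every inserted silence interval
    in seconds.
    """
    if sample_rate < 8000:
        raise ConfigurationError("sample_rate must be >= 8 kHz")
    dur_s = profile.speech_duration_s.sample(rng)
    frac = profile.pause_fraction.sample(rng)
    # every segment boundary sits on the 5 ms envelope hop grid, so a
    # framed RMS detector measures inserted silences exactly; the grid
    # quantisation perturbs the realised pause fraction by < 1e-4 at 60 s
    hop = max(1, int(round(0.005 * sample_rate)))
    n_total = int(round(dur_s * sample_rate / hop)) * hop
    n_pause = int(round(frac * n_total / hop)) * hop
    n_voiced = n_total - n_pause

    # silence lengths accumulate to the pause budget; the last one is
    # truncated so the budget is met exactly
    sil_lengths: List[int] = []
    acc = 0
    while acc < n_pause:
        length = int(round(profile.pause_length_ms.sample(rng) / 1000.0
                           * sample_rate / hop)) * hop
        length = max(length, hop)
        if acc + length > n_pause:
            length = n_pause - acc
        sil_lengths.append(length)
        acc += length
    k = len(sil_lengths)

    min_voiced = int(0.05 * sample_rate)
    if n_voiced < (k + 1) * min_voiced:
        raise GenerationError(
            f"infeasible pause_fraction {frac:.3f}: voiced budget "
            f"{n_voiced / sample_rate:.2f}s cannot host {k + 1} segments")

    # proportional split of the voiced budget into k+1 hop-aligned chunks
    weights = profile.voiced_segment_s.sample(rng, size=k + 1)
    weights = np.maximum(np.asarray(weights, dtype=float), 1e-3)
    voiced_hops = n_voiced // hop
    chunks = np.floor(weights / weights.sum() * voiced_hops).astype(int)
    chunks = np.maximum(chunks, 1)
    chunks[-1] += voiced_hops - int(chunks.sum())  # re-balance after clamping
    if chunks[-1] < 1:
        raise GenerationError("voiced budget too small to split into segments")
    chunks *= hop

    floor_amp = 10.0 ** (profile.noise_floor_db / 20.0)
    fade = int(0.005 * sample_rate)
    pieces: List[np.ndarray] = []
    silences: List[Tuple[float, float]] = []
    pos = 0
    for i, n_chunk in enumerate(chunks):
        amp = profile.voiced_amplitude.sample(rng)
        f0 = rng.uniform(*profile.f0_range_hz)
        t = np.arange(n_chunk) / sample_rate
        burst = (0.6 * np.sin(2 * np.pi * f0 * t)
                 + 0.3 * np.sin(4 * np.pi * f0 * t)
                 + 0.1 * np.sin(6 * np.pi * f0 * t))
        peak = np.max(np.abs(burst))
        if peak > 0:
            burst *= amp / peak  # segment peak equals the drawn amplitude
        if n_chunk > 2 * fade > 0:
            ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(fade) / fade)
            burst[:fade] *= ramp
            burst[-fade:] *= ramp[::-1]
        pieces.append(burst)
        pos += n_chunk
        if i < k:
            n_sil = sil_lengths[i]
            pieces.append(floor_amp * rng.uniform(-1.0, 1.0, size=n_sil))
            silences.append((pos / sample_rate, (pos + n_sil) / sample_rate))
            pos += n_sil

    wave = np.concatenate(pieces) if pieces else np.zeros(0)
    truth = {
        "duration_s": n_total / sample_rate,
        "pause_total_s": n_pause / sample_rate,
        "n_silences": k,
        "silences": silences,
        "pause_fraction_drawn": frac,
    }
    return wave, truth


# ---------------------------------------------------------------------------
# transcript synthesis


def _surface_pools(res: Resources) -> Dict[str, Tuple[str, ...]]:
    by_ann: Dict[str, List[str]] = {c: [] for c in _SENTIMENT_CLASSES}
    ann_key = {"Positive": "positive", "Negative": "negative",
               "Neutral": "neutral", "Non-opinionated": "non_opinionated",
               "Not-a-word": "not_a_word"}
    for word, (_o, ann) in res.polarity.entries.items():
        by_ann[ann_key[ann]].append(word)
    pools: Dict[str, Tuple[str, ...]] = {
        c: tuple(sorted(ws)) for c, ws in by_ann.items()}
    for emo in EMOTIONS:
        pools[f"emotion_{emo}"] = tuple(sorted(
            w for w, emos in res.emotion.entries.items() if emo in emos))
    pools["stopword"] = tuple(sorted(res.stopwords))
    pools["pronoun_first"] = tuple(sorted(res.pronouns["First-Person Pronouns"]))
    pools["pronoun_second"] = tuple(sorted(res.pronouns["Second-Person Pronouns"]))
    pools["pronoun_third"] = tuple(sorted(res.pronouns["Third-Person Pronouns"]))
    pools["plain"] = _PLAIN_POOL
    return pools


def synthesize_transcript(profile: GroupProfile, rng: np.random.Generator,
                          resources: Optional[Resources] = None
                          ) -> Tuple[List[Tuple[str, str]], Dict[str, object]]:
    """Draw one token sequence (``(surface, tag)`` pairs) plus truth counts."""
    res = resources if resources is not None else default_resources()
    pools = _surface_pools(res)
    for cls in profile.lexical_mix:
        if cls not in pools:
            raise ConfigurationError(f"unknown lexical class {cls!r}")
        if not pools[cls]:
            raise ConfigurationError(f"empty vocabulary pool for class {cls!r}")

    n_words = max(1, int(round(profile.words_per_subject.sample(rng))))
    kw_items = sorted(profile.keyword_probs.items())
    classes = [c for c, _ in sorted(profile.lexical_mix.items())]
    class_p = [profile.lexical_mix[c] for c in classes]
    kw_names = [w for w, _ in kw_items]
    kw_p = [p for _, p in kw_items]
    outcomes = classes + ["kw:" + w for w in kw_names] + ["plain"]
    probs = np.array(class_p + kw_p
                     + [1.0 - sum(class_p) - sum(kw_p)], dtype=float)
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()

    tag_names = sorted(profile.pos_tag_probs)
    tag_p = np.array([profile.pos_tag_probs[t] for t in tag_names], dtype=float)
    tag_names.append("x")
    tag_p = np.append(tag_p, max(0.0, 1.0 - tag_p.sum()))
    tag_p /= tag_p.sum()

    neg_pool = tuple(sorted(res.negations))

    tokens: List[Tuple[str, str]] = []
    truth_counts = {
        "annotation": {c: 0 for c in _SENTIMENT_CLASSES},
        "emotion": {e: 0 for e in EMOTIONS},
        "tag": {t: 0 for t in tag_names},
        "pronoun_person": {c: 0 for c in _PRONOUN_CLASSES},
        "stopwords": 0,
        "negations": 0,
    }
    draw_cls = rng.choice(len(outcomes), size=n_words, p=probs)
    draw_tag = rng.choice(len(tag_names), size=n_words, p=tag_p)
    draw_neg = rng.random(n_words) < profile.negation_prob
    for i in range(n_words):
        outcome = outcomes[draw_cls[i]]
        if outcome.startswith("kw:"):
            surface, cls = outcome[3:], "plain"
        else:
            cls = outcome
            pool = pools[cls]
            surface = pool[rng.integers(len(pool))]
        tag = tag_names[draw_tag[i]]
        if draw_neg[i]:
            negword = neg_pool[rng.integers(len(neg_pool))]
            tokens.append((negword, "neg"))
            truth_counts["negations"] += 1
        tokens.append((surface, tag))
        truth_counts["tag"][tag] += 1
        if cls in _SENTIMENT_CLASSES:
            truth_counts["annotation"][cls] += 1
        elif cls.startswith("emotion_"):
            truth_counts["emotion"][cls[len("emotion_"):]] += 1
        elif cls == "stopword":
            truth_counts["stopwords"] += 1
        elif cls in _PRONOUN_CLASSES:
            truth_counts["pronoun_person"][cls] += 1

    truth = {
        "word_count": len(tokens),
        "content_words": n_words,
        **{f"ann_{c}": n for c, n in truth_counts["annotation"].items()},
        **{f"emo_{e}": n for e, n in truth_counts["emotion"].items()},
        **{f"tag_{t}": n for t, n in truth_counts["tag"].items()},
        **{f"{c}": n for c, n in truth_counts["pronoun_person"].items()},
        "stopword_count": truth_counts["stopwords"],
        "negation_count": truth_counts["negations"],
    }
    return tokens, truth


def render_transcript(tokens: Sequence[Tuple[str, str]]) -> str:
    """Serialise tokens to the slash-annotated plain-text transcript form."""
    return " ".join(f"{surface}/{tag}" for surface, tag in tokens)


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SubjectRecord:
    subject_id: str
    label: str
    demographics: Dict[str, object]
    waveform: np.ndarray
    sample_rate: int
    transcript: str
    truth: Dict[str, object]


@dataclass
class CohortBundle:
    subjects: List[SubjectRecord]
    seed: int
    sample_rate: int

    @property
    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "label": s.label}
            row.update({k: v for k, v in s.truth.items() if k != "silences"})
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject_id")


def _sample_demographics(spec: Mapping[str, object],
                         rng: np.random.Generator) -> Dict[str, object]:
    out: Dict[str, object] = {}
    for fname in DEMOGRAPHIC_SCHEMA:
        entry = spec[fname]
        if isinstance(entry, Categorical):
            out[fname] = entry.sample(rng)
        elif isinstance(entry, Dist):
            out[fname] = round(float(entry.sample(rng)), 1)
        elif isinstance(entry, tuple) and entry[0] == "poisson":
            out[fname] = int(rng.poisson(entry[1]))
        else:
            raise ConfigurationError(f"bad demographic spec for {fname!r}")
    return out


def generate_cohort(profiles: Optional[Mapping[str, GroupProfile]] = None,
                    seed: int = 0, sample_rate: int = 16000,
                    resources: Optional[Resources] = None) -> CohortBundle:
    """Generate a full cohort; deterministic for fixed (profiles, seed)."""
    if profiles is None:
        profiles = default_profiles()
    res = resources if resources is not None else default_resources()
    rng = np.random.default_rng(seed)
    subjects: List[SubjectRecord] = []
    for label in sorted(profiles):
        prof = profiles[label]
        for i in range(prof.n_subjects):
            wave, audio_truth = synthesize_utterance(prof, rng, sample_rate)
            tokens, text_truth = synthesize_transcript(prof, rng, res)
            demo = _sample_demographics(prof.demographics, rng)
            truth = {**audio_truth, **text_truth}
            subjects.append(SubjectRecord(
                subject_id=f"{label}{i + 1:03d}",
                label=label,
                demographics=demo,
                waveform=wave,
                sample_rate=sample_rate,
                transcript=render_transcript(tokens),
                truth=truth,
            ))
    return CohortBundle(subjects=subjects, seed=seed, sample_rate=sample_rate)


# ---------------------------------------------------------------------------
# disk I/O


def waveform_to_pcm16(samples: np.ndarray) -> np.ndarray:
    return np.round(np.clip(samples, -1.0, 1.0) * 32767.0).astype(np.int16)


def write_wav(path: str | Path, samples: np.ndarray, sample_rate: int) -> None:
    wavfile.write(str(path), sample_rate, waveform_to_pcm16(samples))


def wav_bytes(samples: np.ndarray, sample_rate: int) -> bytes:
    buf = io.BytesIO()
    wavfile.write(buf, sample_rate, waveform_to_pcm16(samples))
    return buf.getvalue()


def write_cohort(bundle: CohortBundle, outdir: str | Path) -> pd.DataFrame:
    """Write WAVs, transcripts, manifest and ground-truth CSVs; returns
    the manifest."""
    outdir = Path(outdir)
    (outdir / "wav").mkdir(parents=True, exist_ok=True)
    (outdir / "transcripts").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in bundle.subjects:
        wav_path = outdir / "wav" / f"{s.subject_id}.wav"
        txt_path = outdir / "transcripts" / f"{s.subject_id}.txt"
        write_wav(wav_path, s.waveform, s.sample_rate)
        txt_path.write_text(s.transcript, encoding="utf-8")
        row = {"subject_id": s.subject_id, "label": s.label,
               **s.demographics,
               "wav_path": str(wav_path.relative_to(outdir)),
               "transcript_path": str(txt_path.relative_to(outdir))}
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    bundle.truth_frame.to_csv(outdir / "truth.csv")
    return manifest
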