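"""Negation-aware lexicon sentiment scoring.

Each word ``w`` contributes ``Score(w) = Negation x Orientation(w)`` where
``Orientation`` is the signed polarity from the lexicon (0 when absent) and
``Negation`` is -1 when a negation-dictionary word appears in the scope
window immediately before ``w`` (scope width configurable, default one
token; repeated negations inside one window flip once, not per word).
The aggregate polarity score is the mean per-word score over all tokens,
bounded in [-1, 1] because per-word orientations are.

Annotation frequencies count lexicon hits per annotation class (Positive /
Neutral / Negative / Non-opinionated / Not-a-word) normalised by total word
count.  Emotion frequencies count emotion-lexicon hits per emotion with the
same negation weighting: a negated emotion word contributes -1 to that
emotion's signed count, and the reported frequency is the signed count
floored at zero (an absolute-count mode ignoring negation is available).
"""

from __future__ import annotations

from typing import Dict, FrozenSet, Sequence

from .errors import UndefinedFeatureError
from .resources import (ANNOTATION_CLASSES, EMOTIONS, EmotionLexicon,
                        PolarityLexicon)

DEFAULT_NEGATION_SCOPE = 1


def _negated(tokens: Sequence[str], i: int, negations: FrozenSet[str],
             scope: int) -> bool:
    lo = max(0, i - scope)
    return any(tok in negations for tok in tokens[lo:i])


def score_word(word: str, preceding: Sequence[str], lex: PolarityLexicon,
               negations: FrozenSet[str],
               scope: int = DEFAULT_NEGATION_SCOPE) -> float:
    """Signed polarity of one word given its preceding context window."""
    orientation = lex.orientation(word)
    if orientation == 0.0:
        return 0.0
    window = list(preceding)[-scope:] if scope else []
    negation = -1.0 if any(t in negations for t in window) else 1.0
    return negation * orientation


def copeopi_score(tokens: Sequence[str], lex: PolarityLexicon,
                  negations: FrozenSet[str],
                  scope: int = DEFAULT_NEGATION_SCOPE) -> float:
    """Mean per-word negation-weighted polarity over all tokens, in [-1, 1]."""
    if len(tokens) == 0:
        raise UndefinedFeatureError("sentiment score undefined for empty text")
    total = 0.0
    for i, word in enumerate(tokens):
        orientation = lex.orientation(word)
        if orientation == 0.0:
            continue
        sign = -1.0 if _negated(tokens, i, negations, scope) else 1.0
        total += sign * orientation
    return total / len(tokens)


def annotation_frequencies(tokens: Sequence[str], lex: PolarityLexicon
                           ) -> Dict[str, float]:
    """Per-annotation-class lexicon-hit counts over total word count."""
    if len(tokens) == 0:
        raise UndefinedFeatureError("annotation frequencies undefined for empty text")
    counts = {c: 0 for c in ANNOTATION_CLASSES}
    for word in tokens:
        ann = lex.annotation(word)
        if ann is not None:
            counts[ann] += 1
    n = len(tokens)
    return {c: counts[c] / n for c in ANNOTATION_CLASSES}


def emotion_frequencies(tokens: Sequence[str], emo: EmotionLexicon,
                        negations: FrozenSet[str],
                        scope: int = DEFAULT_NEGATION_SCOPE,
                        signed: bool = True) -> Dict[str, float]:
    """Per-emotion frequencies with negation weighting.

    ``signed`` (default) applies the weighted-multiplication rule: each
    emotion hit contributes +1, or -1 when negated, and the signed count is
    floored at 0 before normalising.  ``signed=False`` counts absolute hits.
    """
    if len(tokens) == 0:
        raise UndefinedFeatureError("emotion frequencies undefined for empty text")
    counts = {e: 0.0 for e in EMOTIONS}
    for i, word in enumerate(tokens):
        emotions = emo.emotions_of(word)
        if not emotions:
            continue
        weight = 1.0
        if signed and _negated(tokens, i, negations, scope):
            weight = -1.0
        for e in emotions:
            counts[e] += weight
    n = len(tokens)
    return {e: max(0.0, counts[e]) / n for e in EMOTIONS}


SENTIMENT_FEATURES = (
    ("copeopi_score",)
    + tuple(f"ann_{c.lower().replace('-', '_')}" for c in ANNOTATION_CLASSES)
    + tuple(f"emo_{e.lower()}" for e in EMOTIONS)
)


def extract_sentiment_features(tokens: Sequence[str], lex: PolarityLexicon,
                               emo: EmotionLexicon,
                               negations: FrozenSet[str],
                               scope: int = DEFAULT_NEGATION_SCOPE
                               ) -> Dict[str, float]:
    """The 14 sentiment features: aggregate polarity, 5 annotation and 8
    emotion frequencies, keyed by feature-matrix column name."""
    out: Dict[str, float] = {
        "copeopi_score": copeopi_score(tokens, lex, negations, scope)}
    ann = annotation_frequencies(tokens, lex)
    for c in ANNOTATION_CLASSES:
        out[f"ann_{c.lower().replace('-', '_')}"] = ann[c]
    emof = emotion_frequencies(tokens, emo, negations, scope)
    for e in EMOTIONS:
        out[f"emo_{e.lower()}"] = emof[e]
    return out
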