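"""Lexical resources: polarity lexicon, emotion lexicon, negation dictionary,
stop-word list, POS tag mapping and pronoun lists.

The repository bundles small synthetic lexica (see ``voicemark/data``) in the
same file formats as the external resources they emulate: a polarity lexicon
in the ANTUSD style (word, signed orientation, annotation class) and an
emotion lexicon in the NRC style (one word-emotion pair per line).  Licensing
prevents bundling the real dictionaries; users who have them can point the
loaders at their own files.

Formats (all UTF-8):

* polarity lexicon TSV: ``word<TAB>orientation<TAB>annotation``
* emotion lexicon TSV:  ``word<TAB>emotion``
* negation dictionary / stop-word list: one word per line
* tag mapping TSV: ``raw_tag<TAB>category``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Dict, FrozenSet, Mapping

ANNOTATION_CLASSES = (
    "Positive", "Neutral", "Negative", "Non-opinionated", "Not-a-word",
)

EMOTIONS = (
    "Anger", "Anticipation", "Disgust", "Fear", "Joy",
    "Sadness", "Surprise", "Trust",
)

#: the thirteen canonical POS-derived feature names
POS_CATEGORIES = (
    "Adjectives", "Conjunctions", "Adverbs", "Nouns", "Verbs",
    "Measure Words", "Prepositions", "Pronouns", "Time", "Negations",
    "First-Person Pronouns", "Second-Person Pronouns", "Third-Person Pronouns",
)

#: extra tag-mapped categories kept behind the extended-features flag
EXTRA_POS_CATEGORIES = ("Numerals", "Particles")

DEFAULT_PRONOUNS = {
    "First-Person Pronouns": frozenset({"i", "me", "we", "us", "my", "our"}),
    "Second-Person Pronouns": frozenset({"you", "your", "yours"}),
    "Third-Person Pronouns": frozenset({"he", "she", "they", "him", "her", "them"}),
}


class LexiconError(ValueError):
    """Raised when a lexicon file violates its format or invariants."""


@dataclass(frozen=True)
class PolarityLexicon:
    """word -> (orientation in [-1, 1], annotation class)."""

    entries: Mapping[str, tuple[float, str]]

    def __post_init__(self) -> None:
        for word, (orient, ann) in self.entries.items():
            if ann not in ANNOTATION_CLASSES:
                raise LexiconError(f"{word!r}: unknown annotation {ann!r}")
            if abs(orient) > 1.0:
                raise LexiconError(f"{word!r}: |orientation| > 1")
            if ann == "Positive" and orient <= 0:
                raise LexiconError(f"{word!r}: Positive requires orientation > 0")
            if ann == "Negative" and orient >= 0:
                raise LexiconError(f"{word!r}: Negative requires orientation < 0")

    def orientation(self, word: str) -> float:
        entry = self.entries.get(word)
        return entry[0] if entry is not None else 0.0

    def annotation(self, word: str) -> str | None:
        entry = self.entries.get(word)
        return entry[1] if entry is not None else None

    def __contains__(self, word: str) -> bool:
        return word in self.entries


@dataclass(frozen=True)
class EmotionLexicon:
    """word -> frozenset of emotion names (NRC-style membership)."""

    entries: Mapping[str, FrozenSet[str]]

    def emotions_of(self, word: str) -> FrozenSet[str]:
        return self.entries.get(word, frozenset())

    def __contains__(self, word: str) -> bool:
        return word in self.entries


@dataclass(frozen=True)
class Resources:
    """The full lexical resource bundle consumed by text/sentiment stages."""

    polarity: PolarityLexicon
    emotion: EmotionLexicon
    negations: FrozenSet[str]
    stopwords: FrozenSet[str]
    tag_map: Mapping[str, str]
    pronouns: Mapping[str, FrozenSet[str]] = field(
        default_factory=lambda: dict(DEFAULT_PRONOUNS))


def _data_path(name: str) -> Path:
    return Path(str(_ilres.files("voicemark").joinpath("data", name)))


def load_polarity_lexicon(path: str | Path) -> PolarityLexicon:
    entries: Dict[str, tuple[float, str]] = {}
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise LexiconError(f"{path}:{lineno}: expected 3 tab-separated fields")
        word, orient, ann = parts
        entries[word] = (float(orient), ann)
    return PolarityLexicon(entries)


def load_emotion_lexicon(path: str | Path) -> EmotionLexicon:
    entries: Dict[str, set] = {}
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconError(f"{path}:{lineno}: expected 2 tab-separated fields")
        word, emo = parts
        if emo not in EMOTIONS:
            raise LexiconError(f"{path}:{lineno}: unknown emotion {emo!r}")
        entries.setdefault(word, set()).add(emo)
    return EmotionLexicon({w: frozenset(s) for w, s in entries.items()})


def load_wordlist(path: str | Path) -> FrozenSet[str]:
    return frozenset(
        w.strip() for w in Path(path).read_text("utf-8").splitlines() if w.strip())


def load_tag_map(path: str | Path) -> Dict[str, str]:
    mapping: Dict[str, str] = {}
    for line in Path(path).read_text("utf-8").splitlines():
        if not line.strip():
            continue
        raw, category = line.split("\t")
        mapping[raw] = category
    return mapping


def default_resources() -> Resources:
    """The bundled synthetic resource set (used by tests and the generator)."""
    return Resources(
        polarity=load_polarity_lexicon(_data_path("synthetic_polarity.tsv")),
        emotion=load_emotion_lexicon(_data_path("synthetic_emotion.tsv")),
        negations=load_wordlist(_data_path("negations.txt")),
        stopwords=load_wordlist(_data_path("stopwords.txt")),
        tag_map=load_tag_map(_data_path("tag_map.tsv")),
    )
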