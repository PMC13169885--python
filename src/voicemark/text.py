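"""Linguistic feature extraction: POS frequencies, stop words, TF-IDF
keywords and speaking rate.

The tagger is pluggable: any callable mapping text to a ``(surface, tag)``
sequence works.  The repository ships :func:`slash_tagger`, which reads the
``surface/tag`` annotation produced by the synthetic-transcript generator
(so POS truth is recovered exactly), and a thin adapter to the jieba
Chinese segmenter for users who have it installed.

TF-IDF uses ``TF = raw count / document length`` and the smoothed
``IDF = ln((1+N)/(1+df)) + 1`` (switchable to the unsmoothed ``ln(N/df)``);
keyword selection ranks terms by corpus-summed TF-IDF mass (ties broken
lexicographically) and keeps the top ``k`` (default 75, configurable within
50-500).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .errors import UndefinedFeatureError
from .resources import (EXTRA_POS_CATEGORIES, POS_CATEGORIES, Resources,
                        default_resources)

Tagger = Callable[[str], Sequence[Tuple[str, str]]]


def slash_tagger(text: str) -> List[Tuple[str, str]]:
    """Whitespace tokenizer reading ``surface/tag`` annotations.

    Tokens without a slash get the unknown tag ``"x"``.
    """
    out: List[Tuple[str, str]] = []
    for tok in text.split():
        if "/" in tok:
            surface, tag = tok.rsplit("/", 1)
        else:
            surface, tag = tok, "x"
        out.append((surface, tag))
    return out


def jieba_tagger(text: str) -> List[Tuple[str, str]]:
    """Adapter to the jieba POS tagger (requires jieba to be installed)."""
    try:
        import jieba.posseg as posseg
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "jieba is not installed; install it or use slash_tagger") from exc
    return [(w, t) for w, t in posseg.cut(text)]


@dataclass(frozen=True)
class TaggedTranscript:
    tokens: Tuple[Tuple[str, str], ...]

    @property
    def word_count(self) -> int:
        return len(self.tokens)

    @property
    def surfaces(self) -> List[str]:
        return [s for s, _ in self.tokens]


def tag(text: str, tagger: Tagger = slash_tagger) -> TaggedTranscript:
    """Tokenize + tag; empty text yields an empty transcript (word_count 0,
    flagged downstream by the zero-count guards)."""
    return TaggedTranscript(tuple(tagger(text)))


def pos_frequencies(t: TaggedTranscript, resources: Resources,
                    extended: bool = False) -> Dict[str, float]:
    """The 13 POS-derived frequencies (optionally + Numerals/Particles).

    Tag-mapped categories count by the configured tag mapping; Negations
    count by negation-dictionary membership of the surface form; the three
    person-pronoun splits count by the configured pronoun lists.  Each
    frequency is category count / word count.
    """
    n = t.word_count
    if n == 0:
        raise UndefinedFeatureError("POS frequencies undefined for empty text")
    categories = POS_CATEGORIES + (EXTRA_POS_CATEGORIES if extended else ())
    counts = {c: 0 for c in categories}
    for surface, raw_tag in t.tokens:
        mapped = resources.tag_map.get(raw_tag)
        if mapped in counts:
            counts[mapped] += 1
        if surface in resources.negations:
            counts["Negations"] += 1
        for person, words in resources.pronouns.items():
            if surface in words:
                counts[person] += 1
    return {c: counts[c] / n for c in categories}


def stopwords(t: TaggedTranscript, stoplist: frozenset
              ) -> Tuple[int, List[str]]:
    """Stop-word count and the stop-word-filtered surface sequence; the
    transcript itself is left unmodified."""
    count = 0
    filtered: List[str] = []
    for surface, _tag in t.tokens:
        if surface in stoplist:
            count += 1
        else:
            filtered.append(surface)
    return count, filtered


# ---------------------------------------------------------------------------
# TF-IDF

DEFAULT_K = 75
DEFAULT_K_BOUNDS = (50, 500)


@dataclass(frozen=True)
class TfidfModel:
    vocabulary: Tuple[str, ...]
    idf: np.ndarray
    df: np.ndarray
    n_docs: int
    smooth: bool

    @property
    def k(self) -> int:
        return len(self.vocabulary)

    def term_index(self) -> Dict[str, int]:
        return {t: i for i, t in enumerate(self.vocabulary)}


def _idf(n_docs: int, df: np.ndarray, smooth: bool) -> np.ndarray:
    if smooth:
        return np.log((1.0 + n_docs) / (1.0 + df)) + 1.0
    return np.log(n_docs / df)


def fit_tfidf(corpus: Sequence[Sequence[str]], k: int = DEFAULT_K,
              smooth: bool = True,
              k_bounds: Tuple[int, int] = DEFAULT_K_BOUNDS) -> TfidfModel:
    """Fit the keyword model on stop-word-filtered token sequences.

    The vocabulary is the top-``k`` terms by corpus-summed TF-IDF mass;
    deterministic for a fixed corpus (ties broken lexicographically).
    """
    lo, hi = k_bounds
    if not lo <= k <= hi:
        raise ValueError(f"k must lie in [{lo}, {hi}], got {k}")
    if len(corpus) < 2:
        raise ValueError("TF-IDF requires a corpus of at least 2 documents")
    n_docs = len(corpus)
    df_counts: Dict[str, int] = {}
    mass: Dict[str, float] = {}
    doc_term_freqs: List[Dict[str, float]] = []
    for doc in corpus:
        length = len(doc)
        tf: Dict[str, float] = {}
        for term in doc:
            tf[term] = tf.get(term, 0.0) + 1.0
        if length:
            tf = {t: c / length for t, c in tf.items()}
        doc_term_freqs.append(tf)
        for term in tf:
            df_counts[term] = df_counts.get(term, 0) + 1
    terms = sorted(df_counts)
    df = np.array([df_counts[t] for t in terms], dtype=float)
    idf = _idf(n_docs, df, smooth)
    idf_of = dict(zip(terms, idf))
    for tf in doc_term_freqs:
        for term, v in tf.items():
            mass[term] = mass.get(term, 0.0) + v * idf_of[term]
    ranked = sorted(terms, key=lambda t: (-mass[t], t))
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds the {len(ranked)} distinct corpus terms; "
            "keeping all terms")
        k = len(ranked)
    vocab = tuple(ranked[:k])
    vidx = [terms.index(t) for t in vocab]
    return TfidfModel(vocabulary=vocab, idf=idf[vidx], df=df[vidx],
                      n_docs=n_docs, smooth=smooth)


def tfidf_features(m: TfidfModel, doc: Sequence[str], word_count: int
                   ) -> Tuple[np.ndarray, float, float]:
    """(per-keyword TF-IDF vector, top-word sum, top-word sum per word).

    ``doc`` is the stop-word-filtered sequence (TF denominators use its
    length); ``word_count`` is the subject's total word count, the
    denominator of the per-word metric.
    """
    if word_count <= 0:
        raise UndefinedFeatureError("TF-IDF features undefined for empty text")
    vec = np.zeros(m.k)
    if len(doc) > 0:
        index = m.term_index()
        for term in doc:
            i = index.get(term)
            if i is not None:
                vec[i] += 1.0
        vec = vec / len(doc) * m.idf
    total = float(vec.sum())
    return vec, total, total / word_count


def speaking_rate(word_count: int, total_duration_s: float) -> float:
    """Words per second over the original (pause-intact) duration."""
    if total_duration_s <= 0:
        raise UndefinedFeatureError("speaking rate undefined for zero duration")
    return word_count / total_duration_s


# ---------------------------------------------------------------------------
# feature block


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_").replace("-", "_")


@dataclass(frozen=True)
class TextFeatureSet:
    total_word_count: int
    speaking_rate: float
    pos_freq: Mapping[str, float]
    stop_word_count: int
    tfidf_vector: np.ndarray
    tfidf_top_word_sum: float
    tfidf_top_word_sum_per_word: float
    vocabulary: Tuple[str, ...]

    def as_dict(self, extended: bool = False) -> Dict[str, float]:
        out = {f"pos_{_slug(c)}": v for c, v in self.pos_freq.items()}
        out.update({f"tfidf_{t}": float(v)
                    for t, v in zip(self.vocabulary, self.tfidf_vector)})
        if extended:
            out["total_word_count"] = float(self.total_word_count)
            out["speaking_rate"] = self.speaking_rate
            out["stop_word_count"] = float(self.stop_word_count)
            out["tfidf_top_word_sum"] = self.tfidf_top_word_sum
            out["tfidf_top_word_sum_per_word"] = self.tfidf_top_word_sum_per_word
        return out


def extract_text_features(transcript: str, total_duration_s: float,
                          tfidf_model: TfidfModel,
                          resources: Optional[Resources] = None,
                          tagger: Tagger = slash_tagger,
                          extended_pos: bool = False) -> TextFeatureSet:
    """Full linguistic feature block for one subject."""
    res = resources if resources is not None else default_resources()
    t = tag(transcript, tagger)
    if t.word_count == 0:
        raise UndefinedFeatureError("empty transcript")
    freqs = pos_frequencies(t, res, extended=extended_pos)
    stop_count, filtered = stopwords(t, res.stopwords)
    vec, top_sum, per_word = tfidf_features(tfidf_model, filtered,
                                            t.word_count)
    return TextFeatureSet(
        total_word_count=t.word_count,
        speaking_rate=speaking_rate(t.word_count, total_duration_s),
        pos_freq=freqs,
        stop_word_count=stop_count,
        tfidf_vector=vec,
        tfidf_top_word_sum=top_sum,
        tfidf_top_word_sum_per_word=per_word,
        vocabulary=tfidf_model.vocabulary,
    )
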