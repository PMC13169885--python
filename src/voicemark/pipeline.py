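"""End-to-end orchestration: simulate -> extract -> compare -> train.

`run_pipeline` wires the stages together for the command-line interface and
the reproduction script: it generates (or loads) a cohort, extracts the
three feature blocks per subject, assembles the feature matrix, builds the
group-comparison tables and runs the classification experiment, writing
every artifact (plus the resolved configuration and a hyperparameter
lockfile) into one run directory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import audio as audio_mod
from . import sentiment as sent_mod
from . import stats as stats_mod
from . import text as text_mod
from .model import (AssemblyError, ClassificationExperiment, ExperimentResult,
                    FeatureMatrix, assemble)
from .resources import Resources, default_resources
from .synth import (CohortBundle, DEMOGRAPHIC_SCHEMA, default_profiles,
                    generate_cohort, write_cohort)


@dataclass
class RunConfig:
    """Resolved pipeline configuration; defaults follow the study protocol
    (35 dB / 200-500 ms pause gate, 75 keywords, 4:1 split, 10-fold CV,
    alpha 0.05)."""

    out_dir: str = "voicemark_run"
    cohort_dir: Optional[str] = None   # None -> simulate a default cohort
    seed: int = 0
    sample_rate: int = 16000
    threshold_db: float = 35.0
    min_ms: float = 200.0
    max_ms: float = 500.0
    noise_profile_s: float = 0.0
    k_keywords: int = 75
    extended_features: bool = False
    test_size: float = 0.2
    cv_folds: int = 10
    k_neighbors: int = 5
    smote_mode: str = "per_fold"
    alpha: float = 0.05
    pooled_fdr: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False),
            encoding="utf-8")


# ---------------------------------------------------------------------------
# feature extraction


def _subject_features(subjects: List[Mapping], cfg: RunConfig,
                      res: Resources) -> Tuple[List[Dict], text_mod.TfidfModel]:
    """Extract the three feature blocks for every subject.

    ``subjects`` holds dicts with subject_id, label, demographics,
    waveform+sample_rate, transcript.
    """
    tagged = []
    corpus = []
    for s in subjects:
        t = text_mod.tag(s["transcript"])
        if t.word_count == 0:
            raise AssemblyError(f"subject {s['subject_id']}: empty transcript")
        _count, filtered = text_mod.stopwords(t, res.stopwords)
        tagged.append(t)
        corpus.append(filtered)
    tfidf = text_mod.fit_tfidf(corpus, k=cfg.k_keywords)

    out = []
    for s, t in zip(subjects, tagged):
        w = audio_mod.Waveform(s["waveform"], s["sample_rate"])
        afs = audio_mod.extract_audio_features(
            w, t.word_count, threshold_db=cfg.threshold_db,
            min_ms=cfg.min_ms, max_ms=cfg.max_ms,
            noise_profile_s=cfg.noise_profile_s)
        tfs = text_mod.extract_text_features(
            s["transcript"], w.duration_s, tfidf, res)
        sfs = sent_mod.extract_sentiment_features(
            t.surfaces, res.polarity, res.emotion, res.negations)
        out.append({"subject_id": s["subject_id"], "label": s["label"],
                    "demographics": s["demographics"],
                    "audio": afs, "text": tfs, "sentiment": sfs})
    return out, tfidf


def bundle_subjects(bundle: CohortBundle) -> List[Dict]:
    return [{"subject_id": s.subject_id, "label": s.label,
             "demographics": s.demographics, "waveform": s.waveform,
             "sample_rate": s.sample_rate, "transcript": s.transcript}
            for s in bundle.subjects]


def extract_features(bundle: CohortBundle, cfg: Optional[RunConfig] = None,
                     resources: Optional[Resources] = None
                     ) -> Tuple[FeatureMatrix, text_mod.TfidfModel]:
    """Full extraction on an in-memory cohort; returns the assembled
    feature matrix and the fitted keyword model."""
    cfg = cfg or RunConfig()
    res = resources or default_resources()
    feats, tfidf = _subject_features(bundle_subjects(bundle), cfg, res)
    return assemble(feats, extended=cfg.extended_features), tfidf


def load_cohort_dir(path: str | Path) -> List[Dict]:
    """Load a simulated cohort back from its run directory (manifest.csv,
    WAVs and transcripts)."""
    path = Path(path)
    manifest = pd.read_csv(path / "manifest.csv")
    subjects: List[Dict] = []
    for _, row in manifest.iterrows():
        wav_path = path / row["wav_path"]
        txt_path = path / row["transcript_path"]
        if not wav_path.exists():
            raise FileNotFoundError(
                f"subject {row['subject_id']}: missing WAV {wav_path}")
        if not txt_path.exists():
            raise FileNotFoundError(
                f"subject {row['subject_id']}: missing transcript {txt_path}")
        w = audio_mod.read_wav(wav_path)
        demo = {f: row[f] for f in DEMOGRAPHIC_SCHEMA}
        subjects.append({"subject_id": row["subject_id"],
                         "label": row["label"], "demographics": demo,
                         "waveform": w.samples, "sample_rate": w.sample_rate,
                         "transcript": txt_path.read_text("utf-8")})
    return subjects


def feature_matrix_from_frame(df: pd.DataFrame) -> FeatureMatrix:
    """Rebuild a FeatureMatrix (families, categorical flags) from a saved
    features CSV, using the documented column-name prefixes."""
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    families: Dict[str, str] = {}
    for col in df.columns:
        if col == "label":
            continue
        if col.startswith("demo_"):
            families[col] = "Demographic"
        elif col.startswith("pos_") or col in (
                "total_word_count", "speaking_rate", "stop_word_count",
                "tfidf_top_word_sum", "tfidf_top_word_sum_per_word"):
            families[col] = "Linguistic"
        elif col.startswith("tfidf_"):
            families[col] = "TF-IDF"
        elif col.startswith(("ann_", "emo_")) or col == "copeopi_score":
            families[col] = "Sentiment"
        else:
            families[col] = "Acoustic"
    categorical = frozenset(
        f"demo_{f}" for f, levels in DEMOGRAPHIC_SCHEMA.items()
        if levels is not None and f"demo_{f}" in df.columns)
    return FeatureMatrix(df=df, families=families, categorical=categorical)


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(cfg: RunConfig) -> Dict[str, Path]:
    """Execute simulate? -> extract -> compare -> train; returns artifact
    paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = default_resources()

    if cfg.cohort_dir is None:
        bundle = generate_cohort(default_profiles(), seed=cfg.seed,
                                 sample_rate=cfg.sample_rate)
        cohort_dir = out / "cohort"
        write_cohort(bundle, cohort_dir)
        subjects = bundle_subjects(bundle)
    else:
        cohort_dir = Path(cfg.cohort_dir)
        subjects = load_cohort_dir(cohort_dir)

    feats, _tfidf = _subject_features(subjects, cfg, res)
    fm = assemble(feats, extended=cfg.extended_features)
    features_path = out / "features.csv"
    fm.df.to_csv(features_path)

    table = stats_mod.build_tables(fm, alpha=cfg.alpha, pooled=cfg.pooled_fdr)
    table_path = out / "comparison.csv"
    table.to_csv(table_path, index=False)
    (out / "comparison.md").write_text(
        stats_mod.render_markdown(table), encoding="utf-8")

    exp = ClassificationExperiment(
        fm, test_size=cfg.test_size, cv_folds=cfg.cv_folds,
        k_neighbors=cfg.k_neighbors, smote_mode=cfg.smote_mode)
    result = exp.fit(seed=cfg.seed)
    report_path = out / "model_report.csv"
    result.report.to_csv(report_path, index=False)
    (out / "run_lockfile.json").write_text(
        json.dumps(result.lockfile, indent=2), encoding="utf-8")
    imp = result.permutation_importance("RF")
    imp_path = out / "importance.csv"
    imp.to_csv(imp_path, index=False)

    cfg.to_yaml(out / "resolved_config.yaml")
    return {"cohort": cohort_dir, "features": features_path,
            "comparison": table_path, "model_report": report_path,
            "importance": imp_path}


def audio_features_frame(wav_paths: List[Path], word_counts: List[Optional[int]],
                         cfg: RunConfig) -> pd.DataFrame:
    """Acoustic feature table for a list of WAV files; word-count-dependent
    features are NaN when no word count is available."""
    rows = []
    for path, wc in zip(wav_paths, word_counts):
        w = audio_mod.read_wav(path)
        if wc is not None and wc > 0:
            afs = audio_mod.extract_audio_features(
                w, wc, threshold_db=cfg.threshold_db, min_ms=cfg.min_ms,
                max_ms=cfg.max_ms, noise_profile_s=cfg.noise_profile_s)
            row = afs.as_dict()
            row["pause_total_s"] = afs.pause_total_s
        else:
            wproc = audio_mod.reduce_noise(w, cfg.noise_profile_s)
            pauses = audio_mod.detect_pauses(
                wproc, cfg.threshold_db, cfg.min_ms, cfg.max_ms)
            total = audio_mod.cumulative_pause(pauses)
            peak, mx, mn, avg = audio_mod.amplitude_stats(wproc)
            row = {"pause_per_duration": total / w.duration_s,
                   "pause_per_word": np.nan, "peak_amplitude": peak,
                   "max_peak_amplitude": mx, "min_peak_amplitude": mn,
                   "average_peak_amplitude": avg, "pause_total_s": total}
        row["file"] = path.name
        row["total_duration_s"] = w.duration_s
        rows.append(row)
    return pd.DataFrame(rows)
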