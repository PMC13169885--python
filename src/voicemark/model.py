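"""Classification harness: feature-matrix assembly, stratified 4:1 split,
SMOTE oversampling, eight classifier families, evaluation metrics and
permutation feature importance.

The harness follows a statsmodels-like shape: a
:class:`ClassificationExperiment` is built from a :class:`FeatureMatrix`,
its :meth:`~ClassificationExperiment.fit` runs the whole protocol for one
seed and returns an :class:`ExperimentResult` carrying the per-classifier
train/test metric grid, the fitted models, the exact hyperparameters used
(a "lockfile", since library defaults drift across versions) and a
``summary()`` table.

Protocol: stratified 4:1 train/test split; SMOTE balances the two classes
on training data only (per cross-validation fold by default, which is
leakage-safe; a once-on-the-whole-training-set mode is available); train
metrics are the arithmetic mean over 10 stratified CV folds, each fold
evaluated on its untouched validation part; test metrics come from a final
model fitted on the balanced full training set and applied to the untouched
holdout.  Bipolar disorder (BP) is the positive class for sensitivity /
specificity / precision, and AUC is the primary metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permimp
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .audio import AUDIO_FEATURES
from .resources import POS_CATEGORIES
from .sentiment import SENTIMENT_FEATURES
from .synth import DEMOGRAPHIC_SCHEMA

POSITIVE_LABEL = "BP"
NEGATIVE_LABEL = "MDD"

EXTENDED_TEXT_FEATURES = ("total_word_count", "speaking_rate",
                          "stop_word_count", "tfidf_top_word_sum",
                          "tfidf_top_word_sum_per_word")


class AssemblyError(ValueError):
    """A subject is missing a feature block."""


class SplitError(ValueError):
    """The label distribution cannot support a stratified split."""


# ---------------------------------------------------------------------------
# feature matrix


def _slug(name: str) -> str:
    return name.lower().replace(" ", "_").replace("-", "_")


@dataclass(frozen=True)
class FeatureMatrix:
    """Subjects x features with labels and column provenance.

    ``df`` is indexed by subject id and holds a ``label`` column plus the
    feature columns; ``families`` maps each feature column to its family
    (Demographic / Linguistic / TF-IDF / Sentiment / Acoustic);
    ``categorical`` names the integer-coded categorical columns.
    """

    df: pd.DataFrame
    families: Mapping[str, str]
    categorical: frozenset

    @property
    def feature_columns(self) -> List[str]:
        return [c for c in self.df.columns if c != "label"]

    @property
    def X(self) -> np.ndarray:
        return self.df[self.feature_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return (self.df["label"] == POSITIVE_LABEL).to_numpy(dtype=int)

    def family_counts(self) -> Dict[str, int]:
        counts: Dict[str, int] = {}
        for col in self.feature_columns:
            fam = self.families[col]
            counts[fam] = counts.get(fam, 0) + 1
        return counts


def encode_demographics(demo: Mapping[str, object]) -> Dict[str, float]:
    """Integer-code one subject's demographics per the schema level order.

    Binary and unordered categoricals become their level index; ordered
    categoricals (education, hospitalization history) are ordinal by
    construction of the level order; numeric fields pass through.
    """
    out: Dict[str, float] = {}
    for fname, levels in DEMOGRAPHIC_SCHEMA.items():
        value = demo[fname]
        if levels is None:
            out[f"demo_{fname}"] = float(value)
        else:
            try:
                out[f"demo_{fname}"] = float(levels.index(value))
            except ValueError as exc:
                raise AssemblyError(
                    f"demographic {fname!r}: unknown level {value!r}") from exc
    return out


def assemble(subjects: Sequence[Mapping[str, object]],
             extended: bool = False) -> FeatureMatrix:
    """Build the feature matrix from per-subject feature blocks.

    Each element needs keys ``subject_id``, ``label``, ``demographics``
    (raw values), ``text`` (a TextFeatureSet), ``sentiment`` (feature dict)
    and ``audio`` (an AudioFeatureSet).  The default layout has 118
    columns: 10 demographic + 13 POS + 75 TF-IDF + 14 sentiment + 6
    acoustic; ``extended`` appends word count, speaking rate, stop-word
    count and the two TF-IDF top-word-sum metrics.
    """
    rows = []
    families: Dict[str, str] = {}
    for subj in subjects:
        sid = subj.get("subject_id", "<unknown>")
        missing = [k for k in ("label", "demographics", "text", "sentiment",
                               "audio") if subj.get(k) is None]
        if missing:
            raise AssemblyError(
                f"subject {sid}: missing feature block(s) {missing}")
        row: Dict[str, float] = {}
        row.update(encode_demographics(subj["demographics"]))
        text_feats = subj["text"].as_dict(extended=extended)
        pos_cols = [f"pos_{_slug(c)}" for c in POS_CATEGORIES]
        for col in pos_cols:
            row[col] = text_feats[col]
        tfidf_cols = [f"tfidf_{t}" for t in subj["text"].vocabulary]
        for col in tfidf_cols:
            row[col] = text_feats[col]
        sent = subj["sentiment"]
        for col in SENTIMENT_FEATURES:
            row[col] = sent[col]
        audio_feats = subj["audio"].as_dict()
        for col in AUDIO_FEATURES:
            row[col] = audio_feats[col]
        if extended:
            for col in EXTENDED_TEXT_FEATURES:
                row[col] = text_feats[col]
        rows.append({"subject_id": sid, "label": subj["label"], **row})

        if not families:
            families.update({f"demo_{f}": "Demographic"
                             for f in DEMOGRAPHIC_SCHEMA})
            families.update({c: "Linguistic" for c in pos_cols})
            families.update({c: "TF-IDF" for c in tfidf_cols})
            families.update({c: "Sentiment" for c in SENTIMENT_FEATURES})
            families.update({c: "Acoustic" for c in AUDIO_FEATURES})
            if extended:
                families.update({c: "Linguistic"
                                 for c in EXTENDED_TEXT_FEATURES})
    df = pd.DataFrame(rows).set_index("subject_id")
    ordered = ["label"] + list(families)
    df = df[ordered]
    categorical = frozenset(
        f"demo_{f}" for f, levels in DEMOGRAPHIC_SCHEMA.items()
        if levels is not None)
    return FeatureMatrix(df=df, families=families, categorical=categorical)


# ---------------------------------------------------------------------------
# split and SMOTE


def split(fm: FeatureMatrix, test_size: float = 0.2, seed: int = 0
          ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split of the feature frame (default 4:1)."""
    if not 0 < test_size < 1:
        raise SplitError("test_size must lie in (0, 1)")
    counts = fm.df["label"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise SplitError("both classes need at least 2 members")
    train, test = train_test_split(
        fm.df, test_size=test_size, stratify=fm.df["label"],
        random_state=seed)
    return train, test


def smote(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
          seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling: new minority rows are convex
    combinations of a minority sample and one of its k nearest minority
    neighbours.  Returns a class-balanced (X, y); already-balanced input is
    returned unchanged."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts[0] == counts[1]:
        return X, y
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_new = int(n_maj - n_min)
    Xmin = X[y == minority]
    k = k_neighbors
    if n_min <= k:
        k = n_min - 1
        warnings.warn(f"minority class has {n_min} members; "
                      f"reducing SMOTE k_neighbors to {k}")
    if k < 1:
        raise SplitError("SMOTE needs at least 2 minority samples")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)
    rng = np.random.default_rng(seed)
    base = rng.integers(n_min, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)  # skip self at position 0
    gaps = rng.random(n_new)
    neigh = idx[base, pick]
    X_new = Xmin[base] + gaps[:, None] * (Xmin[neigh] - Xmin[base])
    return (np.vstack([X, X_new]),
            np.concatenate([y, np.full(n_new, minority)]))


# ---------------------------------------------------------------------------
# classifiers and metrics


def default_classifiers(seed: int = 0) -> Dict[str, Callable[[], object]]:
    """The eight classifier families at library defaults (logistic
    regression gets a raised iteration cap so the default solver converges
    on unscaled features; every parameter used lands in the lockfile)."""
    return {
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        "KNN": lambda: KNeighborsClassifier(),
        "LightGBM": lambda: _lightgbm(seed),
        "LR": lambda: LogisticRegression(max_iter=2000, random_state=seed),
        "SVM": lambda: SVC(random_state=seed),
        "NB": lambda: GaussianNB(),
        "RF": lambda: RandomForestClassifier(random_state=seed),
        "XGBoost": lambda: _xgboost(seed),
    }


def _lightgbm(seed: int):
    from lightgbm import LGBMClassifier
    return LGBMClassifier(random_state=seed, verbose=-1)


def _xgboost(seed: int):
    from xgboost import XGBClassifier
    return XGBClassifier(random_state=seed, eval_metric="logloss")


def _scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    y_score: np.ndarray) -> Dict[str, float]:
    """AUC, sensitivity, specificity, precision, accuracy, F1 with the
    positive class coded 1 (BP)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = float(np.sum((y_true == 1) & (y_pred == 1)))
    tn = float(np.sum((y_true == 0) & (y_pred == 0)))
    fp = float(np.sum((y_true == 0) & (y_pred == 1)))
    fn = float(np.sum((y_true == 1) & (y_pred == 0)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / len(y_true)
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    auc = (roc_auc_score(y_true, y_score)
           if len(np.unique(y_true)) == 2 else np.nan)
    return {"auc": float(auc), "sensitivity": sens, "specificity": spec,
            "precision": prec, "accuracy": acc, "f1": f1}


# ---------------------------------------------------------------------------
# the experiment object


@dataclass
class ExperimentResult:
    """Per-classifier train/test metric grid plus fitted final models."""

    report: pd.DataFrame
    models: Dict[str, object]
    lockfile: Dict[str, Dict[str, object]]
    train_index: pd.Index
    test_index: pd.Index
    X_test: np.ndarray
    y_test: np.ndarray
    feature_names: List[str]
    seed: int

    def summary(self) -> str:
        lines = ["Classification experiment "
                 f"(seed={self.seed}, n_test={len(self.y_test)}, "
                 f"positive class={POSITIVE_LABEL})",
                 "",
                 f"{'method':<10}{'set':<7}{'AUC':>7}{'sens':>7}{'spec':>7}"
                 f"{'prec':>7}{'acc':>7}{'F1':>7}"]
        for _, r in self.report.iterrows():
            lines.append(
                f"{r['method']:<10}{r['dataset']:<7}{r['auc']:>7.3f}"
                f"{r['sensitivity']:>7.3f}{r['specificity']:>7.3f}"
                f"{r['precision']:>7.3f}{r['accuracy']:>7.3f}{r['f1']:>7.3f}")
        return "\n".join(lines)

    def permutation_importance(self, method: str = "RF",
                               n_repeats: int = 10,
                               seed: Optional[int] = None) -> pd.DataFrame:
        """Mean test-AUC drop per feature over ``n_repeats`` permutations,
        ranked descending (ties broken by feature name)."""
        clf = self.models[method]
        rs = self.seed if seed is None else seed
        imp = _sk_permimp(clf, self.X_test, self.y_test,
                          scoring="roc_auc", n_repeats=n_repeats,
                          random_state=rs)
        out = pd.DataFrame({
            "feature": self.feature_names,
            "importance_mean": imp.importances_mean,
            "importance_sd": imp.importances_std,
        })
        return (out.sort_values(["importance_mean", "feature"],
                                ascending=[False, True])
                .reset_index(drop=True))


class ClassificationExperiment:
    """The full evaluation protocol over one feature matrix.

    Parameters
    ----------
    fm : FeatureMatrix
    test_size : float, default 0.2 (the 4:1 split)
    cv_folds : int, default 10
    k_neighbors : int, SMOTE neighbourhood size (default 5)
    smote_mode : "per_fold" (leakage-safe default) or "once"
    classifiers : optional mapping name -> zero-arg factory, defaults to
        the eight standard families
    """

    def __init__(self, fm: FeatureMatrix, test_size: float = 0.2,
                 cv_folds: int = 10, k_neighbors: int = 5,
                 smote_mode: str = "per_fold",
                 classifiers: Optional[Mapping[str, Callable]] = None):
        if smote_mode not in ("per_fold", "once"):
            raise ValueError("smote_mode must be 'per_fold' or 'once'")
        self.fm = fm
        self.test_size = test_size
        self.cv_folds = cv_folds
        self.k_neighbors = k_neighbors
        self.smote_mode = smote_mode
        self._classifiers = classifiers

    def fit(self, seed: int = 0) -> ExperimentResult:
        fm = self.fm
        train_df, test_df = split(fm, self.test_size, seed)
        feat_cols = fm.feature_columns
        X_train = train_df[feat_cols].to_numpy(dtype=float)
        y_train = (train_df["label"] == POSITIVE_LABEL).to_numpy(dtype=int)
        X_test = test_df[feat_cols].to_numpy(dtype=float)
        y_test = (test_df["label"] == POSITIVE_LABEL).to_numpy(dtype=int)

        factories = (self._classifiers if self._classifiers is not None
                     else default_classifiers(seed))
        skf = StratifiedKFold(n_splits=self.cv_folds, shuffle=True,
                              random_state=seed)

        if self.smote_mode == "once":
            X_cv, y_cv = smote(X_train, y_train, self.k_neighbors, seed)
        else:
            X_cv, y_cv = X_train, y_train

        rows = []
        models: Dict[str, object] = {}
        lockfile: Dict[str, Dict[str, object]] = {}
        for name, factory in factories.items():
            fold_metrics = []
            for fold, (tr, va) in enumerate(skf.split(X_cv, y_cv)):
                X_tr, y_tr = X_cv[tr], y_cv[tr]
                if self.smote_mode == "per_fold":
                    X_tr, y_tr = smote(X_tr, y_tr, self.k_neighbors,
                                       seed + fold)
                clf = factory()
                clf.fit(X_tr, y_tr)
                m = compute_metrics(y_cv[va], clf.predict(X_cv[va]),
                                    _scores(clf, X_cv[va]))
                fold_metrics.append(m)
            train_row = {k: float(np.mean([m[k] for m in fold_metrics]))
                         for k in fold_metrics[0]}

            X_bal, y_bal = smote(X_train, y_train, self.k_neighbors, seed)
            clf = factory()
            clf.fit(X_bal, y_bal)
            models[name] = clf
            lockfile[name] = _jsonable(clf.get_params())
            test_row = compute_metrics(y_test, clf.predict(X_test),
                                       _scores(clf, X_test))
            rows.append({"method": name, "dataset": "train", **train_row})
            rows.append({"method": name, "dataset": "test", **test_row})

        report = pd.DataFrame(rows)
        return ExperimentResult(
            report=report, models=models, lockfile=lockfile,
            train_index=train_df.index, test_index=test_df.index,
            X_test=X_test, y_test=y_test, feature_names=list(feat_cols),
            seed=seed)


def _jsonable(params: Mapping[str, object]) -> Dict[str, object]:
    out = {}
    for key, value in params.items():
        if isinstance(value, (str, int, float, bool)) or value is None:
            out[key] = value
        else:
            out[key] = repr(value)
    return out
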