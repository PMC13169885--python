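"""Classification harness tests: assembly, split, SMOTE, metrics,
leakage safety and permutation importance."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier

from voicemark.model import (AssemblyError, ClassificationExperiment,
                             FeatureMatrix, SplitError, assemble,
                             compute_metrics, default_classifiers,
                             encode_demographics, smote, split)


def toy_matrix(n_bp=41, n_mdd=150, n_features=3, seed=0, informative=False):
    """A labelled feature frame with optional group separation."""
    rng = np.random.default_rng(seed)
    labels = ["BP"] * n_bp + ["MDD"] * n_mdd
    X = rng.standard_normal((n_bp + n_mdd, n_features))
    cols = [f"audio_f{i}" for i in range(n_features)]
    df = pd.DataFrame(X, columns=cols)
    if informative:
        df["pause_per_duration"] = np.where(
            np.array(labels) == "BP", 0.19, 0.30) + 0.01 * rng.standard_normal(
            len(labels))
        cols = cols + ["pause_per_duration"]
    df["label"] = labels
    df.index = [f"S{i:03d}" for i in range(len(df))]
    df.index.name = "subject_id"
    families = {c: "Acoustic" for c in cols}
    return FeatureMatrix(df=df[["label"] + cols], families=families,
                         categorical=frozenset())


class TestAssemble:
    def test_default_layout_118_columns(self, small_fm):
        assert len(small_fm.feature_columns) == 118
        assert small_fm.family_counts() == {
            "Demographic": 10, "Linguistic": 13, "TF-IDF": 75,
            "Sentiment": 14, "Acoustic": 6}

    def test_missing_block_names_subject(self, small_fm):
        with pytest.raises(AssemblyError, match="S42"):
            assemble([{"subject_id": "S42", "label": "BP",
                       "demographics": {}, "text": None,
                       "sentiment": {}, "audio": None}])

    def test_demographic_encoding_is_ordinal_by_level_order(self):
        row = encode_demographics({
            "sex": "male", "age": 40.0, "education": "senior_high",
            "occupation": "yes", "marriage": "divorced",
            "suicide_history": "no", "hospitalization": "within_past_year",
            "residential": "alone", "alcohol": "lt3_per_week",
            "physical_illnesses": 2})
        assert row["demo_sex"] == 1.0
        assert row["demo_education"] == 2.0
        assert row["demo_marriage"] == 2.0
        assert row["demo_hospitalization"] == 1.0
        assert row["demo_age"] == 40.0

    def test_unknown_level_rejected(self):
        with pytest.raises(AssemblyError):
            encode_demographics({"sex": "other", "age": 1.0,
                                 "education": "elementary",
                                 "occupation": "no", "marriage": "married",
                                 "suicide_history": "no",
                                 "hospitalization": "never",
                                 "residential": "alone",
                                 "alcohol": "lt3_per_week",
                                 "physical_illnesses": 0})


class TestSplit:
    def test_study_shape_gives_8_bp_in_test(self):
        fm = toy_matrix()
        train, test = split(fm, 0.2, seed=1)
        assert (test["label"] == "BP").sum() == 8
        assert len(train) + len(test) == 191

    def test_reproducible_and_disjoint(self):
        fm = toy_matrix()
        tr1, te1 = split(fm, 0.2, seed=5)
        tr2, te2 = split(fm, 0.2, seed=5)
        assert list(te1.index) == list(te2.index)
        assert set(tr1.index).isdisjoint(te1.index)
        assert set(tr1.index) | set(te1.index) == set(fm.df.index)

    def test_tiny_class_rejected(self):
        fm = toy_matrix(n_bp=1, n_mdd=10)
        with pytest.raises(SplitError):
            split(fm, 0.2, seed=0)


class TestSmote:
    def test_balances_33_120(self):
        rng = np.random.default_rng(70)
        X = rng.standard_normal((153, 4))
        y = np.array([1] * 33 + [0] * 120)
        Xb, yb = smote(X, y, seed=0)
        assert (yb == 1).sum() == (yb == 0).sum() == 120
        assert len(Xb) == 240

    def test_already_balanced_unchanged(self):
        rng = np.random.default_rng(71)
        X = rng.standard_normal((20, 3))
        y = np.array([0] * 10 + [1] * 10)
        Xb, yb = smote(X, y, seed=0)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_synthetic_rows_inside_minority_box(self):
        rng = np.random.default_rng(72)
        X = rng.standard_normal((60, 5))
        y = np.array([1] * 10 + [0] * 50)
        Xb, yb = smote(X, y, seed=3)
        Xmin = X[y == 1]
        new = Xb[len(X):]
        assert np.all(new >= Xmin.min(axis=0) - 1e-12)
        assert np.all(new <= Xmin.max(axis=0) + 1e-12)

    def test_k_reduced_with_warning_for_small_minority(self):
        rng = np.random.default_rng(73)
        X = rng.standard_normal((13, 2))
        y = np.array([1] * 3 + [0] * 10)
        with pytest.warns(UserWarning, match="reducing SMOTE"):
            Xb, yb = smote(X, y, k_neighbors=5, seed=0)
        assert (yb == 1).sum() == 10


class TestMetrics:
    def test_f1_consistent_with_confusion_matrix(self):
        rng = np.random.default_rng(74)
        y = rng.integers(0, 2, 200)
        pred = rng.integers(0, 2, 200)
        score = rng.random(200)
        m = compute_metrics(y, pred, score)
        denom = m["precision"] + m["sensitivity"]
        f1 = 2 * m["precision"] * m["sensitivity"] / denom if denom else 0.0
        assert abs(m["f1"] - f1) < 1e-9

    def test_always_positive_classifier_degeneracy_pattern(self):
        # 8 positive (BP) of 39 test subjects, everything predicted positive
        y = np.array([1] * 8 + [0] * 31)
        pred = np.ones_like(y)
        score = np.full(len(y), 0.5)
        m = compute_metrics(y, pred, score)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0
        assert m["precision"] == pytest.approx(8 / 39)
        assert m["accuracy"] == pytest.approx(8 / 39)


class TestExperiment:
    LR_ONLY = {"LR": lambda: LogisticRegression(max_iter=2000)}
    RF_ONLY = {"RF": lambda: RandomForestClassifier(
        n_estimators=60, random_state=0)}

    def test_test_rows_untouched_by_fitting(self):
        fm = toy_matrix(informative=True, seed=8)
        exp = ClassificationExperiment(fm, cv_folds=3,
                                       classifiers=self.LR_ONLY)
        result = exp.fit(seed=2)
        expected = fm.df.loc[result.test_index,
                             fm.feature_columns].to_numpy(float)
        assert np.array_equal(result.X_test, expected)
        assert set(result.train_index).isdisjoint(result.test_index)

    def test_report_grid_shape_and_metric_bounds(self):
        fm = toy_matrix(informative=True, seed=9)
        exp = ClassificationExperiment(fm, cv_folds=3,
                                       classifiers=self.LR_ONLY)
        result = exp.fit(seed=0)
        assert set(result.report["dataset"]) == {"train", "test"}
        metric_cols = ["auc", "sensitivity", "specificity", "precision",
                       "accuracy", "f1"]
        vals = result.report[metric_cols].to_numpy()
        assert np.all((vals >= 0) & (vals <= 1))
        assert "LR" in result.lockfile
        assert "summary" not in result.summary().lower().split()[0]

    def test_strong_separation_yields_high_test_auc(self):
        fm = toy_matrix(informative=True, seed=10)
        exp = ClassificationExperiment(fm, cv_folds=3,
                                       classifiers=self.RF_ONLY)
        result = exp.fit(seed=1)
        test_auc = result.report.query("dataset == 'test'")["auc"].iloc[0]
        assert test_auc >= 0.9

    def test_label_shuffle_gives_chance_level_auc(self):
        rng = np.random.default_rng(75)
        aucs = []
        for seed in range(10):
            fm = toy_matrix(informative=True, seed=11)
            df = fm.df.copy()
            df["label"] = rng.permutation(df["label"].to_numpy())
            fm_shuffled = FeatureMatrix(df=df, families=fm.families,
                                        categorical=fm.categorical)
            exp = ClassificationExperiment(fm_shuffled, cv_folds=3,
                                           classifiers=self.LR_ONLY)
            aucs.append(exp.fit(seed=seed).report
                        .query("dataset == 'test'")["auc"].iloc[0])
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_default_classifier_set_has_eight_families(self):
        assert set(default_classifiers()) == {
            "DT", "KNN", "LightGBM", "LR", "SVM", "NB", "RF", "XGBoost"}


class TestPermutationImportance:
    def test_informative_feature_ranks_first_and_constant_near_zero(self):
        fm = toy_matrix(informative=True, seed=12, n_features=4)
        df = fm.df.copy()
        df["flatline"] = 1.0
        families = dict(fm.families, flatline="Acoustic")
        fm2 = FeatureMatrix(df=df, families=families, categorical=frozenset())
        exp = ClassificationExperiment(
            fm2, cv_folds=3, classifiers=TestExperiment.RF_ONLY)
        result = exp.fit(seed=3)
        imp = result.permutation_importance("RF", n_repeats=10, seed=3)
        assert imp.iloc[0]["feature"] == "pause_per_duration"
        flat = imp.set_index("feature").loc["flatline", "importance_mean"]
        assert abs(flat) < 1e-9
        imp2 = result.permutation_importance("RF", n_repeats=10, seed=3)
        pd.testing.assert_frame_equal(imp, imp2)
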