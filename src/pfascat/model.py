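"""Operationalizing terminal categories as a supervised classifier.

New substances can be assigned to an existing terminal category without
re-running the landscape categorization: a random forest is trained on
Morgan fingerprint bits, chain length and the (ordinal-encoded) primary
category. Terminal categories below a minimum size are pooled into a
``miscellaneous`` class so stratified splitting is feasible. Evaluation is
balanced accuracy (macro-averaged recall) on a stratified 80/20 split with
5-fold stratified cross-validation and a randomized hyperparameter search;
a majority-class dummy is scored first as the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, recall_score
from sklearn.model_selection import (RandomizedSearchCV, StratifiedKFold,
                                     cross_val_score, train_test_split)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OrdinalEncoder, StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "ModelReport",
    "CategoryClassifier",
    "aggregate_small_categories",
    "build_features",
    "train_and_evaluate",
    "MISC_LABEL",
    "MIN_CATEGORY_SIZE",
]

MISC_LABEL = "miscellaneous"
MIN_CATEGORY_SIZE = 10

#: search space mirroring the reported best configuration
DEFAULT_SEARCH_SPACE = {
    "classifier__n_estimators": [100, 200, 300, 400],
    "classifier__min_samples_split": [2, 4],
    "classifier__min_samples_leaf": [1, 2],
    "classifier__max_features": ["sqrt"],
    "classifier__class_weight": ["balanced_subsample"],
}


@dataclass
class ModelReport:
    n_classes: int
    baseline_balanced_accuracy: float
    cv_balanced_accuracy_mean: float
    cv_balanced_accuracy_sd: float
    test_balanced_accuracy: float
    per_class_recall: dict[str, float]
    hyperparameters: dict
    seed: int

    def summary(self) -> str:
        lines = [
            f"classes:                 {self.n_classes}",
            f"baseline BA (test):      {self.baseline_balanced_accuracy:.3f}",
            ("CV balanced accuracy:    "
             f"{self.cv_balanced_accuracy_mean:.3f} "
             f"(sd {self.cv_balanced_accuracy_sd:.3f})"),
            f"test balanced accuracy:  {self.test_balanced_accuracy:.3f}",
            f"seed:                    {self.seed}",
        ]
        return "\n".join(lines)


def aggregate_small_categories(labels: Sequence[str],
                               min_size: int = MIN_CATEGORY_SIZE,
                               ) -> list[str]:
    """Pool terminal categories with fewer than ``min_size`` members."""
    counts = pd.Series(list(labels)).value_counts()
    small = set(counts[counts < min_size].index)
    out = [MISC_LABEL if lab in small else lab for lab in labels]
    if len(set(out)) == 1 and out and out[0] == MISC_LABEL:
        logger.warning("all categories below min_size; single class remains")
    return out


def build_features(fingerprint_bits: np.ndarray,
                   chain_lengths: Sequence[int],
                   primary_categories: Sequence[str]) -> pd.DataFrame:
    """Assemble the raw (unfitted) feature frame.

    Encoding and standardization are performed inside the model pipeline so
    they are fitted on training data only and reused on test/predict data.
    """
    n, n_bits = fingerprint_bits.shape
    df = pd.DataFrame(fingerprint_bits.astype(float),
                      columns=[f"fp_{i}" for i in range(n_bits)])
    df.insert(0, "chain_length", np.asarray(chain_lengths, dtype=float))
    df.insert(0, "primary_category", list(primary_categories))
    return df


def _make_pipeline(seed: int, n_estimators: int = 200,
                   standardize_bits: bool = True) -> Pipeline:
    # standardizing binary bits ahead of a forest is unusual but is the
    # documented behaviour; raw bits are available via standardize_bits=False
    pre = ColumnTransformer(
        transformers=[
            ("primary", OrdinalEncoder(handle_unknown="use_encoded_value",
                                       unknown_value=-1),
             ["primary_category"]),
        ],
        remainder=StandardScaler() if standardize_bits else "passthrough",
    )
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                class_weight="balanced_subsample",
                                n_jobs=1)
    return Pipeline([("preprocess", pre), ("classifier", rf)])


class CategoryClassifier:
    """Fitted category-assignment model with its evaluation report."""

    def __init__(self, pipeline: Pipeline, report: ModelReport,
                 feature_columns: list[str], classes: list[str]):
        self.pipeline = pipeline
        self.report = report
        self.feature_columns = feature_columns
        self.classes = classes

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict(features[self.feature_columns])

    def predict_proba(self, features: pd.DataFrame) -> pd.DataFrame:
        proba = self.pipeline.predict_proba(features[self.feature_columns])
        return pd.DataFrame(proba, columns=self.pipeline.classes_,
                            index=features.index)


def train_and_evaluate(features: pd.DataFrame, labels: Sequence[str],
                       seed: int = 0,
                       n_search_iter: int = 5,
                       cv_folds: int = 5,
                       search_space: Optional[dict] = None,
                       standardize_bits: bool = True,
                       ) -> CategoryClassifier:
    """Train the category model and evaluate it end to end.

    Raises a ValueError naming the offending class when stratification is
    impossible (any class with a single member) — aggregate such classes
    first. The same seed drives the split, the search and the forest, so
    identical inputs and seed give identical reports.
    """
    y = np.asarray(list(labels))
    counts = pd.Series(y).value_counts()
    tiny = counts[counts < 2]
    if len(tiny):
        raise ValueError(
            "stratification impossible: classes with a single member "
            f"{sorted(tiny.index)}; lower the aggregation threshold "
            "(aggregate_small_categories) before training")
    if counts.size < 2:
        raise ValueError("need at least 2 classes after aggregation")

    X_train, X_test, y_train, y_test = train_test_split(
        features, y, test_size=0.2, stratify=y, random_state=seed)

    # baseline: majority-class dummy
    dummy = DummyClassifier(strategy="most_frequent").fit(X_train, y_train)
    baseline = balanced_accuracy_score(y_test, dummy.predict(X_test))

    folds = min(cv_folds, int(pd.Series(y_train).value_counts().min()))
    folds = max(folds, 2)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    pipe = _make_pipeline(seed, standardize_bits=standardize_bits)
    space = DEFAULT_SEARCH_SPACE if search_space is None else search_space
    n_iter = min(n_search_iter,
                 int(np.prod([len(v) for v in space.values()])))
    search = RandomizedSearchCV(pipe, space, n_iter=n_iter, cv=cv,
                                scoring="balanced_accuracy",
                                random_state=seed, n_jobs=1)
    search.fit(X_train, y_train)
    best = search.best_estimator_

    cv_scores = cross_val_score(best, X_train, y_train, cv=cv,
                                scoring="balanced_accuracy", n_jobs=1)
    y_pred = best.predict(X_test)
    test_ba = balanced_accuracy_score(y_test, y_pred)
    class_order = sorted(set(y_test))
    recalls = recall_score(y_test, y_pred, labels=class_order, average=None,
                           zero_division=0)
    per_class = {c: float(r) for c, r in zip(class_order, recalls)}

    report = ModelReport(
        n_classes=int(counts.size),
        baseline_balanced_accuracy=float(baseline),
        cv_balanced_accuracy_mean=float(cv_scores.mean()),
        cv_balanced_accuracy_sd=float(cv_scores.std()),
        test_balanced_accuracy=float(test_ba),
        per_class_recall=per_class,
        hyperparameters={k: (v.item() if hasattr(v, "item") else v)
                         for k, v in search.best_params_.items()},
        seed=seed,
    )
    # refit on all data for deployment
    best.fit(features, y)
    return CategoryClassifier(best, report, list(features.columns),
                              sorted(counts.index))
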