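"""Frozen multiclass phenotype classifier for external-cohort transfer.

A multinomial logistic regression is trained on the scaled derivation
features with a stratified 80/20 split and benchmarked against random
forest, support-vector and Gaussian naive-Bayes comparators; the fitted
model is then applied, unchanged, to external cohorts scaled with the
frozen derivation scaler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC


@dataclass
class TransferClassifier:
    """Fitted transfer model plus its held-out test metrics."""

    estimator: LogisticRegression
    feature_names: list[str]
    classes: list
    accuracy: float
    per_class: pd.DataFrame
    baseline_accuracy: dict[str, float] = field(default_factory=dict)
    split_seed: int = 0

    def predict(self, scaled: pd.DataFrame) -> pd.Series:
        labels, _ = apply_transfer(self, scaled)
        return labels

    def summary(self) -> str:
        lines = [
            "Phenotype transfer classifier (multinomial logistic regression)",
            "=" * 64,
            f"test accuracy: {self.accuracy:.3f}",
            "per-class precision/recall:",
            self.per_class.to_string(float_format=lambda v: f"{v:.3f}"),
            "baseline comparators (test accuracy): "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.baseline_accuracy.items()),
        ]
        return "\n".join(lines)


def train_transfer(scaled: pd.DataFrame, labels: pd.Series,
                   split_fraction: float = 0.8, seed: int = 0,
                   with_baselines: bool = True) -> TransferClassifier:
    """Stratified split, fit the logistic model, report held-out metrics."""
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1) — a test set is required")
    y = labels.loc[scaled.index]
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to train the transfer model")
    if counts.min() < 2:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has < 2 members; stratified split impossible"
        )
    x_tr, x_te, y_tr, y_te = train_test_split(
        scaled, y, train_size=split_fraction, stratify=y, random_state=seed
    )
    est = LogisticRegression(max_iter=2000, random_state=seed)
    est.fit(x_tr.to_numpy(), y_tr)
    pred = est.predict(x_te.to_numpy())
    acc = float(accuracy_score(y_te, pred))
    prec, rec, f1, supp = precision_recall_fscore_support(
        y_te, pred, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": supp}, index=classes
    )
    baselines = {}
    if with_baselines:
        for name, mk in {
            "random_forest": lambda: RandomForestClassifier(
                n_estimators=100, random_state=seed, n_jobs=1),
            "svm": lambda: SVC(random_state=seed),
            "gaussian_nb": lambda: GaussianNB(),
        }.items():
            m = mk()
            m.fit(x_tr.to_numpy(), y_tr)
            baselines[name] = float(accuracy_score(y_te, m.predict(x_te.to_numpy())))
    return TransferClassifier(
        estimator=est, feature_names=list(scaled.columns),
        classes=list(classes), accuracy=acc, per_class=per_class,
        baseline_accuracy=baselines, split_seed=seed,
    )


def apply_transfer(model: TransferClassifier, external_scaled: pd.DataFrame
                   ) -> tuple[pd.Series, pd.DataFrame]:
    """Frozen application to an external scaled matrix.

    Returns (labels, class probabilities); raises a schema error on
    feature-set mismatch.
    """
    missing = [f for f in model.feature_names if f not in external_scaled.columns]
    extra = [f for f in external_scaled.columns if f not in model.feature_names]
    if missing or extra:
        raise ValueError(
            f"feature-set mismatch: missing={missing[:5]}, extra={extra[:5]}"
        )
    x = external_scaled[model.feature_names]
    if len(x) == 0:
        return (pd.Series([], dtype=object, name="phenotype"),
                pd.DataFrame(columns=model.classes))
    proba = model.estimator.predict_proba(x.to_numpy())
    proba_df = pd.DataFrame(proba, index=x.index, columns=model.estimator.classes_)
    labels = pd.Series(
        proba_df.idxmax(axis=1), index=x.index, name="phenotype"
    )
    return labels, proba_df


def prevalence_table(labels: pd.Series) -> pd.Series:
    """Class-prevalence fractions in a predicted cohort."""
    return labels.value_counts(normalize=True).sort_index()
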