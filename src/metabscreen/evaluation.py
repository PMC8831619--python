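"""Confusion matrices, screening metrics, OVR evaluation, and PLS-DA.

Metrics follow the standard screening definitions:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)

An undefined ratio (empty positive or negative group) is reported as
``None``, never as 0.

One-vs-rest evaluation follows the layered screen's convention: for a
target cancer class the positives are that class's samples and the
control group is every other cancer — with the normal controls folded in
when ``include_normals`` is set, mirroring how a deployed screen would
see a mixture of healthy and other-cancer samples.

PLS-DA regresses one-hot class indicators on the standardized matrix via
partial least squares.  R² is the cumulative fraction of indicator
variance explained in-sample; Q² is its cross-validated counterpart
(1 − PRESS/TSS over seeded stratified folds).  Permuting the labels
drives Q² to ≈0 or below, a standard sanity check of the CV construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .alignment import FeatureMatrix
from .io import CANCER_CLASSES, ValidationError


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsResult:
    """Sensitivity/specificity/accuracy as fractions; None when undefined."""

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None


def confusion(
    true_labels: Sequence | pd.Series,
    predicted_labels: Sequence | pd.Series,
    positive_label,
) -> ConfusionMatrix:
    """Cross-tabulate binary truth against binary predictions."""
    t = np.asarray(pd.Series(true_labels).to_numpy())
    p = np.asarray(pd.Series(predicted_labels).to_numpy())
    if len(t) != len(p):
        raise ValidationError(f"length mismatch: {len(t)} truths vs {len(p)} predictions")
    tp = t == positive_label
    pp = p == positive_label
    return ConfusionMatrix(
        TP=int((tp & pp).sum()),
        TN=int((~tp & ~pp).sum()),
        FP=int((~tp & pp).sum()),
        FN=int((tp & ~pp).sum()),
    )


def metrics(cm: ConfusionMatrix) -> MetricsResult:
    """The three screening formulas, exactly."""
    sens = cm.TP / (cm.TP + cm.FN) if cm.TP + cm.FN > 0 else None
    spec = cm.TN / (cm.TN + cm.FP) if cm.TN + cm.FP > 0 else None
    acc = (cm.TP + cm.TN) / cm.total if cm.total > 0 else None
    return MetricsResult(sensitivity=sens, specificity=spec, accuracy=acc)


def ovr_evaluate(
    predictions: pd.DataFrame,
    truth: Mapping[str, str] | pd.Series,
    target_class: str,
    include_normals: bool = True,
    threshold: float | None = None,
) -> tuple[ConfusionMatrix, MetricsResult]:
    """One-vs-rest metrics for one cancer class.

    ``predictions`` is the layered prediction frame (indexed by sample
    id).  A sample counts predicted-positive for the target class either
    by ``final_label`` equality (default) or, when ``threshold`` is
    given, by its ``score_<class>`` exceeding it.  Positives are the
    target class's samples; controls are the other cancers, plus the
    normal controls when ``include_normals``.
    """
    if target_class not in CANCER_CLASSES:
        raise ValidationError(
            f"unknown target_class {target_class!r}; allowed: {', '.join(CANCER_CLASSES)}"
        )
    truth = pd.Series(truth).loc[predictions.index]
    keep = truth.notna()
    if not include_normals:
        keep &= truth != "normal"
    truth = truth[keep]
    preds = predictions.loc[truth.index]
    if threshold is None:
        called = preds["final_label"] == target_class
    else:
        called = preds[f"score_{target_class}"] > threshold
    t = np.where(truth == target_class, "pos", "neg")
    p = np.where(called, "pos", "neg")
    cm = confusion(t, p, positive_label="pos")
    return cm, metrics(cm)


@dataclass
class PLSDAResult:
    """Latent scores and fit/CV variance explained, per component count."""

    n_components: int
    sample_scores: pd.DataFrame  # samples x components
    x_weights: np.ndarray  # features x components
    R2: np.ndarray  # cumulative, length n_components
    Q2: np.ndarray  # cross-validated counterpart, length n_components

    def plot(self, labels: pd.Series, ax=None):
        """Scatter the first two latent components, colored by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = pd.Series(labels).loc[self.sample_scores.index]
        for lbl in sorted(labels.unique()):
            sel = labels == lbl
            ax.scatter(
                self.sample_scores.loc[sel.to_numpy(), "LV1"],
                self.sample_scores.loc[sel.to_numpy(), "LV2"],
                s=12, label=str(lbl),
            )
        ax.set_xlabel("LV1")
        ax.set_ylabel("LV2")
        ax.legend(fontsize=8)
        ax.set_title(f"PLS-DA  R2={self.R2[-1]:.2f}  Q2={self.Q2[-1]:.2f}")
        return ax


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValidationError("matrix has zero-variance features; cannot standardize")
    return (X - mu) / sd


def _one_hot(labels: pd.Series) -> np.ndarray:
    classes = sorted(labels.unique())
    return np.column_stack([(labels == c).to_numpy(float) for c in classes])


def plsda(
    matrix: FeatureMatrix,
    labels: Mapping[str, str] | pd.Series,
    n_components: int = 2,
    cv_folds: int = 7,
    seed: int = 0,
) -> PLSDAResult:
    """Partial least squares discriminant analysis of a completed matrix.

    The matrix is mean-centered and unit-scaled per feature; class
    membership is one-hot encoded.  R²(k) and Q²(k) are reported for
    every component count k up to ``n_components``; Q² uses seeded
    stratified k-fold cross-validation (default 7 folds).
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    labels = pd.Series(labels).loc[list(matrix.sample_ids)]
    counts = labels.value_counts()
    if (counts < cv_folds).any():
        raise ValidationError(
            f"every class needs >= cv_folds={cv_folds} members for Q2"
        )
    X = _standardize(matrix.values.to_numpy(dtype=float).T)
    Y = _one_hot(labels)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum()

    r2 = np.empty(n_components)
    pls_full = None
    for k in range(1, n_components + 1):
        pls = PLSRegression(n_components=k, scale=False)
        pls.fit(X, Y)
        resid = Y - pls.predict(X)
        r2[k - 1] = 1.0 - (resid**2).sum() / tss
        pls_full = pls

    q2 = np.empty(n_components)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, labels.to_numpy()))
    for k in range(1, n_components + 1):
        press = 0.0
        for tr, te in folds:
            pls = PLSRegression(n_components=k, scale=False)
            pls.fit(X[tr], Y[tr])
            press += ((Y[te] - pls.predict(X[te])) ** 2).sum()
        q2[k - 1] = 1.0 - press / tss

    scores = pd.DataFrame(
        pls_full.x_scores_,
        index=matrix.sample_ids,
        columns=[f"LV{i + 1}" for i in range(n_components)],
    )
    return PLSDAResult(
        n_components=n_components,
        sample_scores=scores,
        x_weights=pls_full.x_weights_,
        R2=r2,
        Q2=q2,
    )
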