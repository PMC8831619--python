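"""Weight-based feature ranking and add-one-at-a-time selection.

A fitted linear gate assigns each feature a coefficient; sorting by
absolute coefficient ranks features by their leverage on the score.  The
forward-selection procedure then asks how small a panel suffices: refit
the gate on the top-1, top-2, … ranked features and stop at the first
prefix whose held-out sensitivity and specificity both meet the targets.
Selection metrics are always computed on an explicit evaluation split
supplied by the caller — never on the training data used for the refits —
so the reported panel size is not inflated by leakage.  A cheaper
no-refit variant (restricting the full model's coefficients to the
prefix) is available via ``refit=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import FeatureMatrix
from .io import ValidationError
from .models import (
    MulticlassModel,
    TrainedBinaryModel,
    classify_binary,
    score_binary_matrix,
    train_binary,
    youden_threshold,
)
from .evaluation import confusion, metrics


def rank_features(model: TrainedBinaryModel, names: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Features ordered by descending |coefficient|.

    Ties break lexicographically on feature_id, so the ordering is
    deterministic.  Returns columns feature_id, name, coefficient,
    abs_coefficient.
    """
    if len(model.coefficients) < 1:
        raise ValidationError("model has no coefficients")
    df = pd.DataFrame(
        {
            "feature_id": list(model.feature_ids),
            "coefficient": model.coefficients,
        }
    )
    df["abs_coefficient"] = df["coefficient"].abs()
    df["name"] = df["feature_id"].map(names) if names else df["feature_id"]
    df = df.sort_values(
        ["abs_coefficient", "feature_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df[["feature_id", "name", "coefficient", "abs_coefficient"]]


@dataclass
class SelectionResult:
    """Outcome of add-one-feature-at-a-time selection."""

    selected_features: list[str]  # contiguous prefix of the ranking
    achieved_sensitivity: float
    achieved_specificity: float
    target_sensitivity: float
    target_specificity: float
    met: bool


def _eval_prefix(
    feature_ids: Sequence[str],
    train_matrix: FeatureMatrix,
    train_labels: pd.Series,
    eval_matrix: FeatureMatrix,
    eval_labels: pd.Series,
    positive_label: str,
    refit: bool,
    full_model: TrainedBinaryModel | None,
    **fit_kwargs,
) -> tuple[float, float]:
    sub_train = train_matrix.subset_features(feature_ids)
    if refit:
        m = train_binary(sub_train, train_labels, positive_label=positive_label, **fit_kwargs)
    else:
        pos = [full_model.feature_ids.index(f) for f in feature_ids]
        coefs = full_model.coefficients[pos]
        m = TrainedBinaryModel(
            intercept=full_model.intercept,
            coefficients=coefs,
            threshold=0.0,
            class_weighting=full_model.class_weighting,
            feature_ids=tuple(feature_ids),
        )
        train_scores = score_binary_matrix(m, sub_train)
        m.threshold = youden_threshold(
            train_scores.to_numpy(), (train_labels == positive_label).to_numpy()
        )
    scores = score_binary_matrix(m, eval_matrix.subset_features(feature_ids))
    pred = np.where(scores.to_numpy() > m.threshold, positive_label, "rest")
    t = np.where(eval_labels.to_numpy() == positive_label, positive_label, "rest")
    mr = metrics(confusion(t, pred, positive_label=positive_label))
    return mr.sensitivity or 0.0, mr.specificity or 0.0


def forward_select(
    ranking: pd.DataFrame,
    train_matrix: FeatureMatrix,
    train_labels: Mapping[str, str] | pd.Series,
    eval_matrix: FeatureMatrix,
    eval_labels: Mapping[str, str] | pd.Series,
    target_sens: float,
    target_spec: float,
    max_features: int | None = None,
    positive_label: str = "cancer",
    refit: bool = True,
    full_model: TrainedBinaryModel | None = None,
    **fit_kwargs,
) -> SelectionResult:
    """Grow the panel one ranked feature at a time until targets are met.

    For m = 1, 2, …: fit (or restrict) the gate to the top-m features,
    compute sensitivity/specificity on the evaluation split, and stop at
    the first m meeting both targets.  If ``max_features`` is exhausted
    without success, ``met`` is False and the best prefix by Youden's J
    is reported.
    """
    if len(ranking) == 0:
        raise ValidationError("ranking is empty")
    if not (0 <= min(target_sens, target_spec)):
        raise ValidationError("targets must be >= 0")
    if not refit and full_model is None:
        raise ValidationError("no-refit selection needs the full model")
    max_features = len(ranking) if max_features is None else min(max_features, len(ranking))
    train_labels = pd.Series(train_labels).loc[list(train_matrix.sample_ids)]
    eval_labels = pd.Series(eval_labels).loc[list(eval_matrix.sample_ids)]

    best = None  # (J, m, sens, spec)
    for m in range(1, max_features + 1):
        feats = ranking["feature_id"].iloc[:m].tolist()
        sens, spec = _eval_prefix(
            feats, train_matrix, train_labels, eval_matrix, eval_labels,
            positive_label, refit, full_model, **fit_kwargs,
        )
        if sens >= target_sens and spec >= target_spec:
            return SelectionResult(feats, sens, spec, target_sens, target_spec, met=True)
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-12:
            best = (j, m, sens, spec)
    _, m, sens, spec = best
    return SelectionResult(
        ranking["feature_id"].iloc[:m].tolist(), sens, spec, target_sens, target_spec, met=False
    )


def top_k_report(ranking: pd.DataFrame, k: int, annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """First k ranked features joined with matrix annotations.

    With annotations supplied (indexed by feature_id, with mz_mean and
    rt_mean), the report mirrors the published signature tables: name,
    mean m/z, mean RT, coefficient.
    """
    if k > len(ranking):
        raise ValidationError(f"k={k} exceeds ranking length {len(ranking)}")
    out = ranking.iloc[:k].copy()
    if annotations is not None:
        out = out.merge(
            annotations[["mz_mean", "rt_mean"]],
            left_on="feature_id",
            right_index=True,
            how="left",
        )
    return out.reset_index(drop=True)
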