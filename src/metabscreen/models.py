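"""The two-layer classification scheme.

Stage 1 is a binary gate: a regularized logistic model separating the
pooled cancer group from normal controls, with per-class weights
inversely proportional to class frequency to absorb the ~4.5:1 cohort
imbalance.  Its *score* for a sample is the linear predictor

    y_score = x0 + x1·I1 + x2·I2 + … + xp·Ip

(the intercept plus the coefficient-weighted normalized intensities, not
the sigmoid-mapped probability), and a sample is called cancer when the
score strictly exceeds a threshold.  The default threshold maximizes
Youden's J (sensitivity + specificity − 1) on the training scores; any
fixed value can be supplied instead.

Stage 2 is one-vs-rest: four binary components, one per cancer class
(endometrial, breast, cervical, ovarian), each fitted exactly like the
gate on the cancer training samples only, sharing the feature order and
producing four linear scores per sample.  The layered prediction first
applies the gate; only samples called cancer are forwarded to stage 2,
where the final label is the argmax of the four class scores (ties
broken by the fixed class order above).  A gate false negative can
therefore never receive a cancer class — the structural property the
layered design trades recall for.

The :class:`LayeredScreen` / :class:`LayeredScreenResults` pair wraps the
functional layer in a model-object surface: build the model from a
completed matrix and labels, ``fit()`` it, inspect ``summary()``, then
``predict()`` held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .alignment import FeatureMatrix
from .io import CANCER_CLASSES, LABELS, ValidationError

_SOLVER_TOL = 1e-8
_MAX_ITER = 10000


@dataclass
class SplitAssignment:
    """Stratified train/test partition of the cohort."""

    assignment: dict[str, str]  # sample_id -> "train" | "test"
    seed: int

    def ids(self, split: str) -> list[str]:
        return [sid for sid, s in self.assignment.items() if s == split]


def split_train_test(
    manifest: pd.DataFrame, frac_train: float = 0.5, seed: int = 0
) -> SplitAssignment:
    """Random partition stratified by label.

    Each label's samples are split as close to ``frac_train`` as integer
    rounding allows; deterministic under the seed.  A label with fewer
    than 2 samples cannot be stratified and is rejected.
    """
    if not 0 < frac_train < 1:
        raise ValidationError("frac_train must be in (0, 1)")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for lbl in LABELS:
        ids = manifest.loc[manifest["label"] == lbl, "sample_id"].tolist()
        if not ids:
            continue
        if len(ids) < 2:
            raise ValidationError(f"label {lbl!r} has fewer than 2 samples; cannot stratify")
        perm = rng.permutation(len(ids))
        n_train = int(round(frac_train * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        for i, j in enumerate(perm):
            assignment[ids[j]] = "train" if i < n_train else "test"
    return SplitAssignment(assignment=assignment, seed=seed)


@dataclass
class TrainedBinaryModel:
    """Intercept + per-feature coefficients realizing the linear score."""

    intercept: float
    coefficients: np.ndarray
    threshold: float
    class_weighting: str  # "balanced" or "none"
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_ids):
            raise ValidationError("coefficient length must equal feature count")
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")


@dataclass
class MulticlassModel:
    """Four one-vs-rest binary components sharing one feature order."""

    components: dict[str, TrainedBinaryModel]
    feature_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.components) != set(CANCER_CLASSES):
            raise ValidationError(
                f"components must be exactly {set(CANCER_CLASSES)}"
            )
        for m in self.components.values():
            if m.feature_ids != self.feature_ids:
                raise ValidationError("all components must share the feature order")


@dataclass
class LayeredPrediction:
    """Outcome of the two-stage scheme for one sample."""

    sample_id: str
    stage1_score: float
    stage1_label: str  # "cancer" | "normal"
    stage2_scores: dict[str, float] | None
    final_label: str

    def __post_init__(self) -> None:
        if (self.stage2_scores is None) != (self.final_label == "normal"):
            raise ValidationError("stage2_scores must be absent iff final_label is normal")
        if self.stage1_label == "normal" and self.final_label != "normal":
            raise ValidationError("a gate-negative sample can never carry a cancer class")


def _as_sample_matrix(matrix: FeatureMatrix) -> np.ndarray:
    vals = matrix.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("matrix must be completed (no missing cells) before modeling")
    if not np.isfinite(vals).all():
        raise ValidationError("matrix contains non-finite values")
    return vals.T  # samples x features


def youden_threshold(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity − 1 on given scores.

    Candidates are midpoints between consecutive distinct sorted scores.
    When several candidates tie for the maximum (e.g. perfectly separated
    scores leave a gap where every cut is optimal), the center of the
    maximizing range is returned — max-margin placement, deterministic.
    """
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return float(uniq[0])
    cands = (uniq[:-1] + uniq[1:]) / 2
    n_pos = int(is_positive.sum())
    n_neg = len(scores) - n_pos
    js = np.empty(len(cands))
    for i, t in enumerate(cands):
        pred = scores > t
        sens = (pred & is_positive).sum() / n_pos if n_pos else 0.0
        spec = (~pred & ~is_positive).sum() / n_neg if n_neg else 0.0
        js[i] = sens + spec - 1
    winners = cands[js >= js.max() - 1e-12]
    return float((winners.min() + winners.max()) / 2)


def train_binary(
    train_matrix: FeatureMatrix,
    labels: Mapping[str, str] | pd.Series,
    positive_label: str = "cancer",
    weighting: str = "balanced",
    regularization_strength: float = 1.0,
    threshold: float | None = None,
) -> TrainedBinaryModel:
    """Fit the regularized logistic gate on a completed training matrix.

    ``labels`` maps sample id to a binary label where ``positive_label``
    marks the positive class.  ``weighting='balanced'`` gives each class
    a weight inversely proportional to its frequency.  L2 regularization
    strength is the penalty weight λ (sklearn's C = 1/λ).

    When ``threshold`` is None, the stored decision threshold is the
    Youden-optimal cut on *out-of-fold* training scores (5-fold
    stratified CV, deterministic): in-sample scores of a
    high-dimensional fit are optimistically separated, so a threshold
    placed on them sits in an overfit margin and miscalls held-out
    controls.  When either class has fewer than 5 members the in-sample
    scores are used instead.
    """
    if weighting not in ("balanced", "none"):
        raise ValidationError("weighting must be 'balanced' or 'none'")
    if regularization_strength <= 0:
        raise ValidationError("regularization_strength must be positive")
    X = _as_sample_matrix(train_matrix)
    lab = pd.Series(labels)
    lab = lab.loc[list(train_matrix.sample_ids)]
    y = (lab == positive_label).to_numpy()
    if y.all() or not y.any():
        raise ValidationError("training labels must contain both classes")
    def _make_clf() -> LogisticRegression:
        return LogisticRegression(
            C=1.0 / regularization_strength,
            class_weight="balanced" if weighting == "balanced" else None,
            solver="lbfgs",
            tol=_SOLVER_TOL,
            max_iter=_MAX_ITER,
        )

    clf = _make_clf()
    clf.fit(X, y.astype(int))
    intercept = float(clf.intercept_[0])
    coef = clf.coef_[0].astype(float)
    if threshold is not None:
        thr = float(threshold)
    else:
        n_min = min(int(y.sum()), int((~y).sum()))
        if n_min >= 5:
            from sklearn.model_selection import StratifiedKFold

            oof = np.empty(len(y))
            skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
            for tr_i, te_i in skf.split(X, y):
                sub = _make_clf()
                sub.fit(X[tr_i], y[tr_i].astype(int))
                oof[te_i] = sub.intercept_[0] + X[te_i] @ sub.coef_[0]
            thr = youden_threshold(oof, y)
        else:
            thr = youden_threshold(intercept + X @ coef, y)
    return TrainedBinaryModel(
        intercept=intercept,
        coefficients=coef,
        threshold=thr,
        class_weighting=weighting,
        feature_ids=tuple(train_matrix.feature_ids),
    )


def score_binary(model: TrainedBinaryModel, sample: pd.Series | np.ndarray) -> float:
    """The linear score x0 + Σ xi·Ii (not the sigmoid probability)."""
    x = sample.to_numpy(dtype=float) if isinstance(sample, pd.Series) else np.asarray(sample, float)
    if len(x) != len(model.coefficients):
        raise ValidationError(
            f"sample has {len(x)} features, model expects {len(model.coefficients)}"
        )
    return float(model.intercept + x @ model.coefficients)


def score_binary_matrix(model: TrainedBinaryModel, matrix: FeatureMatrix) -> pd.Series:
    """Linear scores for every sample column of a completed matrix."""
    if tuple(matrix.feature_ids) != model.feature_ids:
        raise ValidationError("matrix feature order does not match the model")
    X = _as_sample_matrix(matrix)
    return pd.Series(model.intercept + X @ model.coefficients, index=matrix.sample_ids)


def classify_binary(score: float, threshold: float) -> str:
    """Cancer iff score strictly exceeds the threshold."""
    return "cancer" if score > threshold else "normal"


def train_ovr(
    train_matrix: FeatureMatrix,
    labels: Mapping[str, str] | pd.Series,
    weighting: str = "balanced",
    regularization_strength: float = 1.0,
) -> MulticlassModel:
    """One-vs-rest model over the four cancer classes.

    Each component is an independent binary fit of its class against the
    other three, identical to :func:`train_binary` under the one-vs-rest
    relabeling; the four components share the matrix's feature order.
    """
    lab = pd.Series(labels).loc[list(train_matrix.sample_ids)]
    missing = [c for c in CANCER_CLASSES if (lab == c).sum() == 0]
    if missing:
        raise ValidationError(f"missing cancer class(es) in training labels: {missing}")
    components = {}
    for cls in CANCER_CLASSES:
        relabeled = lab.map(lambda v: cls if v == cls else "rest")
        components[cls] = train_binary(
            train_matrix,
            relabeled,
            positive_label=cls,
            weighting=weighting,
            regularization_strength=regularization_strength,
        )
    return MulticlassModel(components=components, feature_ids=tuple(train_matrix.feature_ids))


def score_ovr(model: MulticlassModel, sample: pd.Series | np.ndarray) -> dict[str, float]:
    """The four linear class scores for one sample."""
    return {cls: score_binary(model.components[cls], sample) for cls in CANCER_CLASSES}


def predict_layered(
    m1: TrainedBinaryModel,
    m2: MulticlassModel,
    sample: pd.Series | np.ndarray,
    sample_id: str = "",
    threshold: float | None = None,
) -> LayeredPrediction:
    """Gate with the binary model, then argmax the OVR scores if positive.

    ``threshold`` overrides the gate's stored threshold.  Ties in the
    argmax are broken by the fixed class order (endometrial, breast,
    cervical, ovarian).
    """
    thr = m1.threshold if threshold is None else threshold
    s1 = score_binary(m1, sample)
    if classify_binary(s1, thr) == "normal":
        return LayeredPrediction(sample_id, s1, "normal", None, "normal")
    s2 = score_ovr(m2, sample)
    # np.argmax returns the first maximum, i.e. ties break by fixed class order
    best = CANCER_CLASSES[int(np.argmax([s2[c] for c in CANCER_CLASSES]))]
    return LayeredPrediction(sample_id, s1, "cancer", s2, best)


def predict_layered_matrix(
    m1: TrainedBinaryModel,
    m2: MulticlassModel,
    matrix: FeatureMatrix,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Layered predictions for every column; one row per sample.

    Columns: stage1_score, stage1_label, score_<class>…, final_label.
    Stage-2 scores are reported for every sample (for plotting and OVR
    evaluation) but the final label of gate-negative samples is normal.
    """
    if tuple(matrix.feature_ids) != m1.feature_ids:
        raise ValidationError("matrix feature order does not match model 1")
    thr = m1.threshold if threshold is None else threshold
    s1 = score_binary_matrix(m1, matrix)
    rows = []
    for sid in matrix.sample_ids:
        col = matrix.values[sid]
        s2 = score_ovr(m2, col)
        gate = classify_binary(float(s1[sid]), thr)
        if gate == "normal":
            final = "normal"
        else:
            final = CANCER_CLASSES[int(np.argmax([s2[c] for c in CANCER_CLASSES]))]
        rows.append(
            {
                "sample_id": sid,
                "stage1_score": float(s1[sid]),
                "stage1_label": gate,
                **{f"score_{c}": s2[c] for c in CANCER_CLASSES},
                "final_label": final,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# --- model-object surface ----------------------------------------------------


class LayeredScreen:
    """Two-stage cancer screen as a fit/predict model object.

    Parameters
    ----------
    matrix
        Completed (log-normalized, imputed) feature × sample matrix of
        the *training* samples.
    labels
        Mapping sample id → class label from the five-class set.
    weighting, regularization_strength
        Passed to both stages' logistic fits.
    """

    def __init__(
        self,
        matrix: FeatureMatrix,
        labels: Mapping[str, str] | pd.Series,
        weighting: str = "balanced",
        regularization_strength: float = 1.0,
    ) -> None:
        self.matrix = matrix
        self.labels = pd.Series(labels).loc[list(matrix.sample_ids)]
        unknown = ~self.labels.isin(LABELS)
        if unknown.any():
            raise ValidationError(f"unknown label {self.labels[unknown].iloc[0]!r}")
        self.weighting = weighting
        self.regularization_strength = regularization_strength

    @classmethod
    def from_dataframe(
        cls, values: pd.DataFrame, labels: Mapping[str, str] | pd.Series, **kwargs
    ) -> "LayeredScreen":
        """Build from a plain features × samples DataFrame (no annotations)."""
        ann = pd.DataFrame(
            {
                "metabolite_id": values.index,
                "name": values.index,
                "mz_mean": np.nan,
                "rt_mean": np.nan,
            },
            index=values.index,
        )
        return cls(FeatureMatrix(annotations=ann, values=values), labels, **kwargs)

    def fit(self, threshold: float | None = None) -> "LayeredScreenResults":
        binary_labels = self.labels.map(lambda v: "normal" if v == "normal" else "cancer")
        m1 = train_binary(
            self.matrix,
            binary_labels,
            weighting=self.weighting,
            regularization_strength=self.regularization_strength,
            threshold=threshold,
        )
        cancer_ids = [sid for sid in self.matrix.sample_ids if self.labels[sid] != "normal"]
        m2 = train_ovr(
            self.matrix.subset_samples(cancer_ids),
            self.labels.loc[cancer_ids],
            weighting=self.weighting,
            regularization_strength=self.regularization_strength,
        )
        return LayeredScreenResults(self, m1, m2)


class LayeredScreenResults:
    """Fitted two-stage screen: coefficients, thresholds, diagnostics."""

    def __init__(self, model: LayeredScreen, m1: TrainedBinaryModel, m2: MulticlassModel):
        self.model = model
        self.binary_model = m1
        self.ovr_model = m2

    @property
    def threshold(self) -> float:
        return self.binary_model.threshold

    def predict(self, matrix: FeatureMatrix, threshold: float | None = None) -> pd.DataFrame:
        return predict_layered_matrix(self.binary_model, self.ovr_model, matrix, threshold)

    def training_predictions(self) -> pd.DataFrame:
        return self.predict(self.model.matrix)

    def summary(self, top: int = 10) -> str:
        """Readable report: fit setup, training metrics, top gate features."""
        from .evaluation import confusion, metrics

        preds = self.training_predictions()
        truth = self.model.labels.map(lambda v: "normal" if v == "normal" else "cancer")
        cm = confusion(truth, preds["stage1_label"], positive_label="cancer")
        mr = metrics(cm)
        coef = pd.Series(self.binary_model.coefficients, index=self.binary_model.feature_ids)
        top_feats = coef.reindex(coef.abs().sort_values(ascending=False).index)[:top]
        lines = [
            "Layered cancer screen (stage 1: cancer vs normal; stage 2: one-vs-rest)",
            f"  features: {len(coef)}   training samples: {self.model.matrix.shape[1]}",
            f"  weighting: {self.model.weighting}   "
            f"L2 strength: {self.model.regularization_strength}",
            f"  gate threshold: {self.binary_model.threshold:.4f}",
            "  training confusion (gate): "
            f"TP={cm.TP} FN={cm.FN} TN={cm.TN} FP={cm.FP}",
            f"  training sensitivity={mr.sensitivity:.3f} "
            f"specificity={mr.specificity:.3f} accuracy={mr.accuracy:.3f}",
            f"  top {top} gate features by |coefficient|:",
        ]
        for fid, c in top_feats.items():
            lines.append(f"    {fid:<16} {c:+.4f}")
        return "\n".join(lines)
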