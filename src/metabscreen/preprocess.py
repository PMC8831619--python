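"""Matrix conditioning: log transform, quantile normalization, KNN gap filling.

The conditioning chain runs log → quantile-normalize → impute, all in the
feature × sample matrix produced by alignment.

Quantile normalization here is *train-referenced*: the reference
distribution (per-rank mean of the training samples' sorted observed
values on a common fractional-rank grid) is fitted once on the training
split and stored, and any later sample — including a single held-out
sample arriving alone — is projected onto it by the fractional ranks of
its own observed values.  This keeps test-time normalization free of any
test-set information and makes one-sample-at-a-time scoring well defined.
On a complete matrix the construction reduces exactly to textbook
sort–mean–reassign quantile normalization.

Gap filling is k-nearest-neighbour: a missing cell is filled with the
unweighted mean of that feature among the k nearest *training* samples,
where distance is squared Euclidean over co-observed features divided by
the co-observed count (so samples with different missingness patterns are
comparable).  Neighbours lacking the feature are skipped and the next
nearest substituted; a feature observed in no training sample falls back
to the training feature mean.  Observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import FeatureMatrix
from .io import ValidationError


def log_transform(matrix: FeatureMatrix) -> FeatureMatrix:
    """Natural log of every observed cell; missing stays missing.

    Intensities are strictly positive by construction, so no pseudocount
    is applied; a non-positive cell is reported with its coordinates.
    """
    vals = matrix.values.to_numpy(dtype=float)
    bad = ~np.isnan(vals) & (vals <= 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"non-positive intensity at feature {matrix.feature_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}"
        )
    out = matrix.copy()
    out.values = pd.DataFrame(
        np.log(vals), index=matrix.values.index, columns=matrix.values.columns
    )
    return out


@dataclass
class NormalizationReference:
    """Stored target distribution for train-referenced quantile normalization.

    ``reference_quantiles`` is the non-decreasing vector of target values
    on the fractional-rank grid ``linspace(0, 1, n_features_fitted)``.
    """

    reference_quantiles: np.ndarray

    def __post_init__(self) -> None:
        self.reference_quantiles = np.asarray(self.reference_quantiles, dtype=float)
        if self.reference_quantiles.ndim != 1 or len(self.reference_quantiles) < 2:
            raise ValidationError("reference_quantiles must be a vector of length >= 2")
        if (np.diff(self.reference_quantiles) < 0).any():
            raise ValidationError("reference_quantiles must be non-decreasing")

    @property
    def n_features_fitted(self) -> int:
        return len(self.reference_quantiles)


def fit_quantile_reference(train: FeatureMatrix) -> NormalizationReference:
    """Mean distribution of the training samples on a common rank grid.

    Each sample's sorted observed values are linearly interpolated onto
    the fractional-rank grid of length ``n_features``, so samples with
    unequal observed counts contribute comparably; the reference is the
    per-rank mean over samples.
    """
    vals = train.values.to_numpy(dtype=float)
    p, n = vals.shape
    if n < 2:
        raise ValidationError("need at least 2 training samples")
    grid = np.linspace(0.0, 1.0, p)
    acc = np.zeros(p)
    for j in range(n):
        col = vals[:, j]
        obs = np.sort(col[~np.isnan(col)])
        if len(obs) < 2:
            raise ValidationError(
                f"sample {train.sample_ids[j]!r} has fewer than 2 observed values"
            )
        acc += np.interp(grid, np.linspace(0.0, 1.0, len(obs)), obs)
    return NormalizationReference(reference_quantiles=acc / n)


def apply_quantile_single(
    sample: pd.Series | np.ndarray, ref: NormalizationReference
) -> pd.Series | np.ndarray:
    """Project one sample (with missingness) onto the stored reference.

    Observed values are replaced by the reference quantiles at their
    fractional ranks (linear interpolation); tied values share the mean
    of their tied rank positions; missing cells stay missing.  The output
    is a monotone transform of the input's observed values.
    """
    is_series = isinstance(sample, pd.Series)
    x = sample.to_numpy(dtype=float) if is_series else np.asarray(sample, dtype=float)
    obs_mask = ~np.isnan(x)
    m = int(obs_mask.sum())
    if m < 2:
        raise ValidationError("sample must have at least 2 observed values")
    obs = x[obs_mask]
    order = np.argsort(obs, kind="stable")
    grid = np.linspace(0.0, 1.0, ref.n_features_fitted)
    # target value for each sorted rank position 0..m-1
    targets = np.interp(np.linspace(0.0, 1.0, m), grid, ref.reference_quantiles)
    new_sorted = targets.copy()
    sorted_obs = obs[order]
    # ties share the mean of their tied positions' targets
    start = 0
    for i in range(1, m + 1):
        if i == m or sorted_obs[i] != sorted_obs[start]:
            if i - start > 1:
                new_sorted[start:i] = targets[start:i].mean()
            start = i
    out_obs = np.empty(m)
    out_obs[order] = new_sorted
    out = np.full_like(x, np.nan)
    out[obs_mask] = out_obs
    if is_series:
        return pd.Series(out, index=sample.index, name=sample.name)
    return out


def normalize_matrix(matrix: FeatureMatrix, ref: NormalizationReference) -> FeatureMatrix:
    """Apply single-sample projection to every column independently."""
    out = matrix.copy()
    vals = out.values
    for sid in vals.columns:
        vals[sid] = apply_quantile_single(vals[sid], ref)
    return out


@dataclass
class ImputationModel:
    """KNN gap-filling model: the normalized training matrix plus k."""

    k: int
    train_values: pd.DataFrame  # features x training samples, may contain NaN

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        usable = (self.train_values.notna().sum(axis=0) > 0).sum()
        if self.k > usable:
            raise ValidationError(
                f"k={self.k} exceeds the {usable} training samples with observed features"
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.train_values.index


def knn_impute_fit(train: FeatureMatrix, k: int = 5) -> ImputationModel:
    """Store the (normalized) training matrix as the neighbour pool."""
    return ImputationModel(k=k, train_values=train.values.copy())


def _impute_column(
    x: np.ndarray,
    train: np.ndarray,
    train_obs: np.ndarray,
    feat_mean: np.ndarray,
    k: int,
    self_col: int | None = None,
) -> np.ndarray:
    """Fill one sample's missing entries from the training pool.

    ``self_col`` excludes the sample itself when the target is one of the
    training columns (a sample is never its own neighbour).
    """
    obs = ~np.isnan(x)
    if obs.all():
        return x
    co = obs[:, None] & train_obs  # p x n co-observed indicator
    diff = np.where(co, (train - x[:, None]), 0.0)
    counts = co.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(counts > 0, (diff**2).sum(axis=0) / counts, np.inf)
    if self_col is not None:
        d2[self_col] = np.inf
    order = np.argsort(d2, kind="stable")
    order = order[np.isfinite(d2[order])]
    out = x.copy()
    for i in np.flatnonzero(~obs):
        donors = order[train_obs[i, order]][:k]
        if len(donors) == 0:
            out[i] = feat_mean[i]
        else:
            out[i] = train[i, donors].mean()
    return out


def knn_impute_apply(
    model: ImputationModel, target: FeatureMatrix | pd.Series
) -> FeatureMatrix | pd.Series:
    """Fill every missing cell of the target from the training pool.

    Already-observed cells pass through unchanged; a complete target is
    returned as-is.  When the target *is* the training matrix (same
    column labels), each sample is excluded from its own neighbour pool.
    """
    train = model.train_values.to_numpy(dtype=float)
    train_obs = ~np.isnan(train)
    with np.errstate(invalid="ignore"):
        feat_mean = np.nanmean(np.where(train_obs, train, np.nan), axis=1)
    feat_mean = np.where(np.isnan(feat_mean), 0.0, feat_mean)

    if isinstance(target, pd.Series):
        if not target.index.equals(model.feature_ids):
            raise ValidationError("target features do not match the imputation model")
        filled = _impute_column(target.to_numpy(dtype=float), train, train_obs, feat_mean, model.k)
        return pd.Series(filled, index=target.index, name=target.name)

    if not target.values.index.equals(model.feature_ids):
        raise ValidationError("target features do not match the imputation model")
    out = target.copy()
    train_cols = {sid: j for j, sid in enumerate(model.train_values.columns)}
    vals = out.values.to_numpy(dtype=float)
    for j, sid in enumerate(out.values.columns):
        vals[:, j] = _impute_column(
            vals[:, j], train, train_obs, feat_mean, model.k, self_col=train_cols.get(sid)
        )
    out.values = pd.DataFrame(vals, index=out.values.index, columns=out.values.columns)
    return out


def median_rsd(qc: FeatureMatrix) -> float:
    """Median relative standard deviation over fully observed QC features.

    Computed on natural-scale intensities of pooled-QC replicate columns:
    per-feature RSD = sd/mean over replicates, restricted to features
    present in 100% of the QC columns; the median across those features
    summarizes overall process variability.
    """
    vals = qc.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValidationError("need at least 2 QC replicate columns")
    full = ~np.isnan(vals).any(axis=1)
    if not full.any():
        raise ValidationError("no feature observed in all QC columns")
    sub = vals[full]
    rsd = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    return float(np.median(rsd))


def preprocess_chain(
    matrix: FeatureMatrix,
    train_ids: Sequence[str],
    k: int = 5,
) -> tuple[FeatureMatrix, NormalizationReference, ImputationModel]:
    """log → QN (train-referenced) → KNN impute, leakage-free.

    The reference and the imputer are fitted on the training columns
    only; every column (train and test alike) is then projected and
    imputed one sample at a time.  Returns the completed matrix plus the
    two fitted artifacts for later single-sample use.
    """
    logged = log_transform(matrix)
    ref = fit_quantile_reference(logged.subset_samples(train_ids))
    normalized = normalize_matrix(logged, ref)
    imputer = knn_impute_fit(normalized.subset_samples(train_ids), k=k)
    completed = knn_impute_apply(imputer, normalized)
    return completed, ref, imputer
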