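"""Virtual-lock-mass (VLM) feature alignment against a metabolite library.

Mass measurement error on an Orbitrap-class instrument is relative: a
peak's observed m/z deviates from the true mass by a few parts per
million, so the absolute error grows with mass.  A fixed-Dalton matching
window is therefore wrong at both ends of the scan range.  Instead, each
library metabolite anchors a *VLM box* — an m/z interval of half-width
``ppm_tol`` parts per million around the theoretical mass — and every
sample's peaks are assigned to the box containing them.  Boxes whose raw
intervals overlap are shrunk to the midpoint between adjacent centers so
that no m/z value can fall in two boxes; containment is closed on the low
bound and open on the high bound to keep disjointness exact.

After assignment the per-sample intensities form a feature × sample
matrix.  Two filters mirror the standard untargeted workflow: features
annotated as plant products or drugs (and their metabolites) are removed,
and features present in fewer than ``min_presence_frac`` of samples
(default 20%; exactly-at-cutoff survives) are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import PeakTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class AlignmentConfig:
    """Knobs for box construction, assignment, and filtering.

    ppm_tol
        Half-width of a box in parts per million.  Default 5, the
        instrument-level mass accuracy bound of an Orbitrap run.
    rt_tol
        Optional retention-time gate in minutes; ``None`` (default)
        disables the gate and matching is mass-only.
    min_presence_frac
        Minimum fraction of samples a feature must be observed in.
    excluded_categories
        Library categories dropped after matrix construction.
    multi_peak_policy
        Rule when several peaks of one sample fall in one box:
        ``"max"`` keeps the most intense peak, ``"sum"`` adds them.
    """

    ppm_tol: float = 5.0
    rt_tol: float | None = None
    min_presence_frac: float = 0.20
    excluded_categories: frozenset = frozenset({"plant", "drug"})
    multi_peak_policy: str = "max"

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0:
            raise ValidationError("ppm_tol must be positive")
        if not 0 <= self.min_presence_frac <= 1:
            raise ValidationError("min_presence_frac must be in [0, 1]")
        if self.multi_peak_policy not in ("max", "sum"):
            raise ValidationError("multi_peak_policy must be 'max' or 'sum'")
        self.excluded_categories = frozenset(self.excluded_categories)


@dataclass
class FeatureMatrix:
    """Features × samples intensity matrix with explicit missingness.

    ``annotations`` is indexed by feature_id with columns metabolite_id,
    name, mz_mean, rt_mean; ``values`` shares the feature index and has
    one column per sample, with NaN marking a missing measurement.
    """

    annotations: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        # values may be raw intensities (positive) or log/normalized data
        # (any sign); positivity of raw data is enforced at build time
        if not self.annotations.index.equals(self.values.index):
            raise ValidationError("annotation and value rows must share the feature index")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            annotations=self.annotations.loc[feature_ids],
            values=self.values.loc[feature_ids],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(annotations=self.annotations, values=self.values[list(sample_ids)])

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(self.annotations.copy(), self.values.copy())


def build_vlm_boxes(
    runs: Iterable[PeakTable],
    library: pd.DataFrame,
    config: AlignmentConfig,
) -> pd.DataFrame:
    """Anchor one candidate box per library mass; drop boxes no peak hits.

    Returns a DataFrame sorted by ``mz_center`` with columns
    metabolite_id, name, category, mz_center, mz_lo, mz_hi, rt_lo, rt_hi
    (RT bounds are ±inf when the gate is off or the library has no
    expected RT).  Raw intervals that overlap are truncated at the
    midpoint between the adjacent centers, restoring disjointness.
    """
    lib = library.sort_values("mz_theoretical", kind="stable").reset_index(drop=True)
    centers = lib["mz_theoretical"].to_numpy(dtype=float)
    if len(centers) == 0:
        raise ValidationError("library is empty")
    if (np.diff(centers) == 0).any():
        i = int(np.flatnonzero(np.diff(centers) == 0)[0])
        raise ValidationError(
            f"library entries {lib['metabolite_id'][i]!r} and "
            f"{lib['metabolite_id'][i + 1]!r} share mass {centers[i]}; "
            "cannot anchor distinct boxes"
        )
    half = config.ppm_tol * 1e-6
    lo = centers * (1 - half)
    hi = centers * (1 + half)
    mid = (centers[:-1] + centers[1:]) / 2
    hi[:-1] = np.minimum(hi[:-1], mid)
    lo[1:] = np.maximum(lo[1:], mid)

    rt_exp = lib["rt_expected"].to_numpy(dtype=float)
    if config.rt_tol is not None:
        rt_lo = np.where(np.isnan(rt_exp), -np.inf, rt_exp - config.rt_tol)
        rt_hi = np.where(np.isnan(rt_exp), np.inf, rt_exp + config.rt_tol)
    else:
        rt_lo = np.full(len(centers), -np.inf)
        rt_hi = np.full(len(centers), np.inf)

    boxes = pd.DataFrame(
        {
            "metabolite_id": lib["metabolite_id"].to_numpy(),
            "name": lib["name"].to_numpy(),
            "category": lib["category"].to_numpy(),
            "mz_center": centers,
            "mz_lo": lo,
            "mz_hi": hi,
            "rt_lo": rt_lo,
            "rt_hi": rt_hi,
        }
    )

    hits = np.zeros(len(boxes), dtype=bool)
    for run in runs:
        idx = assign_peak_indices(run, boxes, config)
        hits[idx[idx >= 0]] = True
    dropped = int((~hits).sum())
    if dropped:
        logger.info("dropping %d boxes matched by no peak in any run", dropped)
    return boxes.loc[hits].reset_index(drop=True)


def assign_peak_indices(
    run: PeakTable, boxes: pd.DataFrame, config: AlignmentConfig
) -> np.ndarray:
    """Per-peak box row index (−1 when the peak falls in no box).

    Peaks are located by binary search on the sorted box bounds;
    containment is ``mz_lo <= mz < mz_hi``, then the optional RT gate.
    """
    mz = run.peaks["mz"].to_numpy(dtype=float)
    rt = run.peaks["rt"].to_numpy(dtype=float)
    lo = boxes["mz_lo"].to_numpy(dtype=float)
    hi = boxes["mz_hi"].to_numpy(dtype=float)
    idx = np.searchsorted(lo, mz, side="right") - 1
    ok = (idx >= 0) & (mz < hi[np.clip(idx, 0, len(hi) - 1)])
    if config.rt_tol is not None:
        rt_lo = boxes["rt_lo"].to_numpy(dtype=float)
        rt_hi = boxes["rt_hi"].to_numpy(dtype=float)
        safe = np.clip(idx, 0, len(lo) - 1)
        ok &= (rt >= rt_lo[safe]) & (rt <= rt_hi[safe])
    return np.where(ok, idx, -1)


def assign_peaks(
    run: PeakTable, boxes: pd.DataFrame, config: AlignmentConfig
) -> dict[str, float]:
    """Map feature ids (anchoring metabolite ids) to this run's intensity.

    Multiple peaks of the run landing in one box are resolved by
    ``multi_peak_policy`` (default: keep the maximum intensity).
    Unmatched peaks are counted and logged, never errors.
    """
    idx = assign_peak_indices(run, boxes, config)
    unmatched = int((idx < 0).sum())
    if unmatched:
        logger.debug("%s: %d of %d peaks unassigned", run.sample_id, unmatched, len(idx))
    intensity = run.peaks["intensity"].to_numpy(dtype=float)
    out: dict[str, float] = {}
    fids = boxes["metabolite_id"].to_numpy()
    for j, inten in zip(idx, intensity):
        if j < 0:
            continue
        fid = fids[j]
        if fid in out:
            out[fid] = out[fid] + inten if config.multi_peak_policy == "sum" else max(out[fid], inten)
        else:
            out[fid] = inten
    return out


def build_matrix(
    runs: Sequence[PeakTable], boxes: pd.DataFrame, config: AlignmentConfig
) -> FeatureMatrix:
    """Assemble the feature × sample matrix from per-run assignments.

    Cells are NaN where a run had no peak in the box.  ``mz_mean`` and
    ``rt_mean`` are averaged over all assigned peaks (pre-policy), so the
    annotation reflects every observation of the feature.
    """
    sample_ids = [r.sample_id for r in runs]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError("duplicate sample_id among runs")
    n_feat = len(boxes)
    vals = np.full((n_feat, len(runs)), np.nan)
    mz_sum = np.zeros(n_feat)
    rt_sum = np.zeros(n_feat)
    n_obs = np.zeros(n_feat, dtype=int)
    for col, run in enumerate(runs):
        idx = assign_peak_indices(run, boxes, config)
        sel = idx >= 0
        np.add.at(mz_sum, idx[sel], run.peaks["mz"].to_numpy()[sel])
        np.add.at(rt_sum, idx[sel], run.peaks["rt"].to_numpy()[sel])
        np.add.at(n_obs, idx[sel], 1)
        inten = run.peaks["intensity"].to_numpy(dtype=float)
        col_vals = np.full(n_feat, np.nan)
        for j, v in zip(idx[sel], inten[sel]):
            if np.isnan(col_vals[j]):
                col_vals[j] = v
            elif config.multi_peak_policy == "sum":
                col_vals[j] += v
            else:
                col_vals[j] = max(col_vals[j], v)
        vals[:, col] = col_vals
    with np.errstate(invalid="ignore"):
        mz_mean = np.where(n_obs > 0, mz_sum / np.maximum(n_obs, 1), boxes["mz_center"])
        rt_mean = np.where(n_obs > 0, rt_sum / np.maximum(n_obs, 1), np.nan)
    ann = pd.DataFrame(
        {
            "metabolite_id": boxes["metabolite_id"].to_numpy(),
            "name": boxes["name"].to_numpy(),
            "mz_mean": mz_mean,
            "rt_mean": rt_mean,
        },
        index=pd.Index(boxes["metabolite_id"].to_numpy(), name="feature_id"),
    )
    values = pd.DataFrame(vals, index=ann.index, columns=sample_ids)
    if (values.to_numpy() <= 0).any():
        raise ValidationError("raw intensities must be positive")
    return FeatureMatrix(annotations=ann, values=values)


def exclude_categories(
    matrix: FeatureMatrix, library: pd.DataFrame, config: AlignmentConfig
) -> FeatureMatrix:
    """Drop features whose library category is excluded (plant/drug by default)."""
    cat = library.set_index("metabolite_id")["category"]
    mids = matrix.annotations["metabolite_id"]
    unknown = ~mids.isin(cat.index)
    if unknown.any():
        raise ValidationError(f"unknown metabolite_id {mids[unknown].iloc[0]!r}")
    keep = ~mids.map(cat).isin(config.excluded_categories)
    return matrix.subset_features(matrix.feature_ids[keep.to_numpy()])


def presence_filter(matrix: FeatureMatrix, min_presence_frac: float) -> FeatureMatrix:
    """Keep features observed in at least ``min_presence_frac`` of samples.

    The boundary is inclusive: a feature present in exactly the cutoff
    fraction survives (features present in *less than* the cutoff are
    excluded).
    """
    if not 0 <= min_presence_frac <= 1:
        raise ValidationError("min_presence_frac must be in [0, 1]")
    if matrix.shape[1] == 0 or matrix.shape[0] == 0:
        return matrix
    frac = matrix.values.notna().sum(axis=1) / matrix.shape[1]
    keep = frac >= min_presence_frac
    return matrix.subset_features(matrix.feature_ids[keep.to_numpy()])


def align_cohort(
    runs: Sequence[PeakTable], library: pd.DataFrame, config: AlignmentConfig
) -> tuple[FeatureMatrix, dict]:
    """Full cascade: boxes → matrix → category exclusion → presence filter.

    Returns the filtered matrix and a report dict with the feature counts
    at each stage (raw, after exclusion, after presence filtering).
    """
    boxes = build_vlm_boxes(runs, library, config)
    raw = build_matrix(runs, boxes, config)
    no_contaminants = exclude_categories(raw, library, config)
    final = presence_filter(no_contaminants, config.min_presence_frac)
    report = {
        "n_boxes": len(boxes),
        "n_features_raw": raw.shape[0],
        "n_features_after_exclusion": no_contaminants.shape[0],
        "n_features_after_presence": final.shape[0],
        "n_samples": len(runs),
    }
    return final, report
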