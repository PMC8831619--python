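"""Reading and writing the pipeline's delimited-text artifacts.

Three input artifacts feed the pipeline: per-sample peak tables
(``mz``, ``rt``, ``intensity``), a metabolite reference library
(theoretical positive-mode masses with an endogenous/plant/drug category
flag), and a sample manifest (sample id, class label, optional age group
and train/test split).  All are tab-separated with a mandatory header by
default; a comma delimiter is accepted via the ``sep`` argument.

Peak tables deliberately carry no feature identities — identity is
assigned only by alignment against the library, mirroring untargeted
acquisition.  Trained models and feature matrices serialize to versioned,
human-readable single files; floats are written with shortest round-trip
representation so deserialization is bit-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

#: The five cohort class labels.
LABELS = ("normal", "endometrial", "breast", "cervical", "ovarian")

#: Cancer classes in the fixed order used for tie-breaking.
CANCER_CLASSES = ("endometrial", "breast", "cervical", "ovarian")

#: Library category flags.
CATEGORIES = ("endogenous", "plant", "drug")


class FormatError(ValueError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """A record violates a domain invariant (e.g. non-positive intensity)."""


@dataclass
class PeakTable:
    """One sample's detected peaks: (m/z, retention time, intensity) triples.

    Peaks are kept sorted by m/z ascending.  Absent peaks are absent
    records, never zero intensities.
    """

    sample_id: str
    peaks: pd.DataFrame  # columns: mz, rt, intensity; sorted by mz

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be nonempty")
        self.peaks = self.peaks.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.peaks)


def _read_delimited(path: str | Path, sep: str, required: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_peak_table(path: str | Path, sample_id: str | None = None, sep: str = "\t") -> PeakTable:
    """Read one sample's peak table; peaks are returned sorted by m/z.

    The sample id defaults to the file stem.  Raises
    :class:`ValidationError` (with the offending 1-based data row) for
    non-positive intensities or masses, and :class:`FormatError` for a
    missing column.
    """
    path = Path(path)
    df = _read_delimited(path, sep, ("mz", "rt", "intensity"))
    for col, ok in (
        ("mz", lambda v: v > 0),
        ("rt", lambda v: v >= 0),
        ("intensity", lambda v: v > 0),
    ):
        bad = ~df[col].map(ok) | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValidationError(f"{path}: invalid {col} value at data row {row}")
    df = df[["mz", "rt", "intensity"]].astype(float)
    df = df.sort_values("mz", kind="stable").reset_index(drop=True)
    return PeakTable(sample_id=sample_id or path.stem, peaks=df)


def _fmt(x: float) -> str:
    # repr gives the shortest string that round-trips the float exactly
    return repr(float(x))


def write_peak_table(table: PeakTable, path: str | Path, sep: str = "\t") -> None:
    """Write a peak table; values round-trip exactly through :func:`read_peak_table`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(sep.join(("mz", "rt", "intensity")) + "\n")
        for row in table.peaks.itertuples(index=False):
            fh.write(sep.join((_fmt(row.mz), _fmt(row.rt), _fmt(row.intensity))) + "\n")


def read_library(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read the metabolite reference library, sorted by theoretical m/z.

    Columns: metabolite_id, name, mz_theoretical, rt_expected (optional,
    may be empty), category in {endogenous, plant, drug}.  Duplicate ids
    and unknown category tokens are rejected.
    """
    df = _read_delimited(path, sep, ("metabolite_id", "name", "mz_theoretical", "category"))
    if df["metabolite_id"].duplicated().any():
        dup = df.loc[df["metabolite_id"].duplicated(), "metabolite_id"].iloc[0]
        raise ValidationError(f"duplicate metabolite_id {dup!r}")
    bad = ~df["category"].isin(CATEGORIES)
    if bad.any():
        tok = df.loc[bad, "category"].iloc[0]
        raise ValidationError(
            f"unknown category {tok!r}; allowed: {', '.join(CATEGORIES)}"
        )
    if (df["mz_theoretical"] <= 0).any():
        raise ValidationError("mz_theoretical must be positive")
    if "rt_expected" not in df.columns:
        df["rt_expected"] = np.nan
    df = df[["metabolite_id", "name", "mz_theoretical", "rt_expected", "category"]]
    return df.sort_values("mz_theoretical", kind="stable").reset_index(drop=True)


def write_library(library: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    library.to_csv(path, sep=sep, index=False)


def read_manifest(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read the sample manifest (sample_id, label, optional age_group/split).

    Labels are validated against the five-class set; duplicate sample ids
    are rejected.
    """
    df = _read_delimited(path, sep, ("sample_id", "label"))
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    bad = ~df["label"].isin(LABELS)
    if bad.any():
        tok = df.loc[bad, "label"].iloc[0]
        raise ValidationError(f"unknown label {tok!r}; allowed: {', '.join(LABELS)}")
    if "split" in df.columns:
        known = df["split"].isin(("train", "test")) | df["split"].isna()
        if not known.all():
            tok = df.loc[~known, "split"].iloc[0]
            raise ValidationError(f"unknown split {tok!r}; allowed: train, test")
    keep = [c for c in ("sample_id", "label", "age_group", "split") if c in df.columns]
    return df[keep].reset_index(drop=True)


def write_manifest(manifest: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    manifest.to_csv(path, sep=sep, index=False)


# --- feature matrix serialization -------------------------------------------

def write_feature_matrix(matrix, path: str | Path, sep: str = "\t") -> None:
    """Export a FeatureMatrix as TSV: annotation columns then one column
    per sample; empty cell = missing.  Floats use shortest round-trip form."""
    ann = matrix.annotations
    with open(path, "w") as fh:
        header = ["feature_id", "metabolite_id", "name", "mz_mean", "rt_mean"]
        header += list(matrix.values.columns)
        fh.write(sep.join(header) + "\n")
        vals = matrix.values.to_numpy()
        for i, fid in enumerate(matrix.values.index):
            a = ann.loc[fid]
            cells = [str(fid), str(a["metabolite_id"]), str(a["name"]),
                     _fmt(a["mz_mean"]), _fmt(a["rt_mean"])]
            for v in vals[i]:
                cells.append("" if np.isnan(v) else _fmt(v))
            fh.write(sep.join(cells) + "\n")


def read_feature_matrix(path: str | Path, sep: str = "\t"):
    """Inverse of :func:`write_feature_matrix`."""
    from .alignment import FeatureMatrix

    df = pd.read_csv(path, sep=sep, dtype={"feature_id": str, "metabolite_id": str})
    meta_cols = ["feature_id", "metabolite_id", "name", "mz_mean", "rt_mean"]
    for col in meta_cols:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    ann = df[meta_cols].set_index("feature_id")
    values = df[sample_cols].astype(float)
    values.index = ann.index
    return FeatureMatrix(annotations=ann, values=values)


# --- model serialization -----------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def _binary_to_dict(model) -> dict:
    return {
        "intercept": model.intercept,
        "coefficients": list(map(float, model.coefficients)),
        "threshold": model.threshold,
        "class_weighting": model.class_weighting,
        "feature_ids": list(model.feature_ids),
    }


def _binary_from_dict(d: dict):
    from .models import TrainedBinaryModel

    return TrainedBinaryModel(
        intercept=float(d["intercept"]),
        coefficients=np.asarray(d["coefficients"], dtype=float),
        threshold=float(d["threshold"]),
        class_weighting=d["class_weighting"],
        feature_ids=tuple(d["feature_ids"]),
    )


def save_model(model, path: str | Path) -> None:
    """Serialize a TrainedBinaryModel or MulticlassModel to versioned JSON.

    JSON numbers are emitted via ``repr`` semantics, so coefficients
    round-trip bit-exactly.
    """
    from .models import MulticlassModel, TrainedBinaryModel

    if isinstance(model, TrainedBinaryModel):
        payload = {"format_version": _MODEL_FORMAT_VERSION, "kind": "binary",
                   "model": _binary_to_dict(model)}
    elif isinstance(model, MulticlassModel):
        payload = {
            "format_version": _MODEL_FORMAT_VERSION,
            "kind": "ovr",
            "components": {lbl: _binary_to_dict(m) for lbl, m in model.components.items()},
            "feature_ids": list(model.feature_ids),
        }
    else:  # pragma: no cover - defensive
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def save_normalization_reference(ref, path: str | Path) -> None:
    """Versioned JSON for the quantile-normalization reference."""
    with open(path, "w") as fh:
        json.dump(
            {"format_version": 1,
             "reference_quantiles": list(map(float, ref.reference_quantiles))},
            fh,
        )


def load_normalization_reference(path: str | Path):
    from .preprocess import NormalizationReference

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != 1:
        raise FormatError(f"unsupported reference format version in {path}")
    return NormalizationReference(
        reference_quantiles=np.asarray(payload["reference_quantiles"], dtype=float)
    )


def save_imputer(model, path: str | Path) -> None:
    """Versioned JSON for the KNN imputation model (NaN cells as null)."""
    tv = model.train_values
    vals = [[None if np.isnan(v) else float(v) for v in row] for row in tv.to_numpy()]
    with open(path, "w") as fh:
        json.dump(
            {"format_version": 1, "k": model.k,
             "feature_ids": list(map(str, tv.index)),
             "sample_ids": list(map(str, tv.columns)),
             "values": vals},
            fh,
        )


def load_imputer(path: str | Path):
    from .preprocess import ImputationModel

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != 1:
        raise FormatError(f"unsupported imputer format version in {path}")
    arr = np.array(
        [[np.nan if v is None else v for v in row] for row in payload["values"]],
        dtype=float,
    )
    tv = pd.DataFrame(arr, index=payload["feature_ids"], columns=payload["sample_ids"])
    return ImputationModel(k=int(payload["k"]), train_values=tv)


def load_model(path: str | Path):
    from .models import MulticlassModel

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise FormatError(f"unsupported model format version in {path}")
    if payload["kind"] == "binary":
        return _binary_from_dict(payload["model"])
    components = {lbl: _binary_from_dict(d) for lbl, d in payload["components"].items()}
    return MulticlassModel(components=components, feature_ids=tuple(payload["feature_ids"]))
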