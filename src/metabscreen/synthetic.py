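"""Synthetic serum-metabolomics cohorts with known ground truth.

The real screening study was run on commercially purchased sera that were
never deposited, so every downstream stage here is exercised on simulated
cohorts instead.  The generator emits per-sample peak tables, a metabolite
library, a manifest, and a :class:`GroundTruth` object recording the true
class of every sample, the planted class signatures, and the generating
metabolite of every emitted peak — which makes alignment recovery,
signature recovery, and classifier performance all directly testable.

Generative model, per sample:

* latent log-intensity of metabolite *m* is Normal(``base_log_intensity_mean``,
  ``base_log_intensity_sd``), plus a per-sample batch shift
  Normal(0, ``batch_scale_sd``) common to all metabolites, plus — when *m*
  is a signature metabolite of the sample's class — a shift of
  ``±effect_log2fc · ln 2`` whose sign is drawn once per metabolite;
* observed intensity is the exponential (log-normal intensities);
* observed m/z is ``mz_theoretical · (1 + e)`` with
  ``e ~ Normal(0, sigma_ppm · 1e−6)`` — mass error is multiplicative,
  i.e. proportional to mass, as on a real Orbitrap;
* retention time is the metabolite's fixed library draw plus small
  per-sample jitter;
* peaks are then deleted by two mechanisms: completely at random with
  probability ``missing_rate_random``, and intensity-dependently with a
  logistic probability rising below ``missing_intensity_knee`` on the
  latent log scale.

Everything is driven by one ``numpy`` Generator, so a fixed seed gives
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CANCER_CLASSES, LABELS, PeakTable, ValidationError


class ConfigurationError(ValueError):
    """The requested generator settings are infeasible."""


def _default_counts() -> dict[str, int]:
    # cohort composition of the screening study this generator emulates
    return {"normal": 250, "endometrial": 304, "breast": 303, "cervical": 250, "ovarian": 262}


@dataclass
class GeneratorConfig:
    """Cohort-level simulation settings (defaults are the study conditions).

    Counts follow the real cohort (250 normal / 304 endometrial /
    303 breast / 250 cervical / 262 ovarian); ``sigma_ppm`` defaults to
    1.5 ppm, comfortably inside the instrument's stated <5 ppm accuracy;
    the m/z scan range is 66.7–1000 Da; intensities are log-normal around
    e^13 ≈ 4.4e5 counts with log-sd 0.5 (≈65% CV on the natural scale),
    a typical serum LC-MS variability.
    """

    n_per_class: Mapping[str, int] = field(default_factory=_default_counts)
    library_size: int = 2000
    n_contaminants: int = 100
    n_signature_per_class: int = 40
    effect_log2fc: float = 1.5
    sigma_ppm: float = 1.5
    base_log_intensity_mean: float = 13.0
    base_log_intensity_sd: float = 0.5
    missing_rate_random: float = 0.05
    missing_intensity_knee: float | None = 11.0
    missing_knee_width: float = 0.7
    batch_scale_sd: float = 0.1
    rt_jitter_sd: float = 0.05
    mz_min: float = 66.7
    mz_max: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lbl, n in self.n_per_class.items():
            if lbl not in LABELS:
                raise ValidationError(f"unknown label {lbl!r}; allowed: {', '.join(LABELS)}")
            if n < 0:
                raise ValidationError("sample counts must be >= 0")
        if self.library_size < 1:
            raise ValidationError("library_size must be >= 1")
        if self.n_contaminants < 0 or self.n_signature_per_class < 0:
            raise ValidationError("counts must be >= 0")
        if not 0 <= self.missing_rate_random < 1:
            raise ValidationError("missing_rate_random must be in [0, 1)")
        if self.sigma_ppm < 0:
            raise ValidationError("sigma_ppm must be >= 0")
        if self.n_signature_per_class * len(CANCER_CLASSES) > self.library_size:
            raise ValidationError(
                "n_signature_per_class x 4 must not exceed library_size"
            )


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery testing.

    ``assignments`` maps each sample to the generating metabolite id of
    every emitted peak, aligned with the peak table's m/z-sorted rows.
    """

    true_label: dict[str, str]
    signature_map: dict[str, dict[str, float]]  # class -> metabolite_id -> log-intensity shift
    assignments: dict[str, np.ndarray]

    def n_assigned_peaks(self) -> int:
        return sum(len(a) for a in self.assignments.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, mids in self.assignments.items():
            for i, mid in enumerate(mids):
                rows.append((sid, i, mid))
        return pd.DataFrame(rows, columns=["sample_id", "peak_index", "metabolite_id"])


def make_library(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a reference library with resolvable mass spacing.

    Masses are log-uniform in the instrument scan range with a guaranteed
    minimum relative gap of ``4 × sigma_ppm × 1e−6`` between neighbours,
    so adjacent VLM boxes are resolvable by construction at default
    settings.  Contaminant entries (plant/drug) are a random subset.
    """
    rng = np.random.default_rng(config.seed)
    n = config.library_size + config.n_contaminants
    min_gap = max(4 * config.sigma_ppm * 1e-6, 1e-9)
    log_lo, log_hi = np.log(config.mz_min), np.log(config.mz_max)
    capacity = (log_hi - log_lo) / np.log1p(min_gap)
    if n > 0.5 * capacity:
        raise ConfigurationError(
            f"cannot place {n} masses with relative spacing {min_gap:.2e} in "
            f"[{config.mz_min}, {config.mz_max}]; request a smaller library"
        )
    masses: np.ndarray | None = None
    for _ in range(20):
        cand = np.sort(np.exp(rng.uniform(log_lo, log_hi, size=3 * n)))
        keep = [cand[0]]
        for m in cand[1:]:
            if m / keep[-1] - 1 > min_gap:
                keep.append(m)
            if len(keep) == n:
                break
        if len(keep) == n:
            masses = np.array(keep)
            break
    if masses is None:  # pragma: no cover - capacity check above makes this unreachable
        raise ConfigurationError("could not place the requested library; reduce its size")

    order = rng.permutation(n)  # which sorted slots become contaminants
    categories = np.array(["endogenous"] * n, dtype=object)
    contam = order[: config.n_contaminants]
    half = len(contam) // 2
    categories[contam[:half]] = "plant"
    categories[contam[half:]] = "drug"
    rt = rng.uniform(0.5, 11.0, size=n)
    ids = np.array([f"M{i:05d}" for i in range(n)], dtype=object)
    names = np.array(
        [f"metabolite-{i:05d}" if c == "endogenous" else f"{c}-compound-{i:05d}"
         for i, c in enumerate(categories)],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "metabolite_id": ids,
            "name": names,
            "mz_theoretical": masses,
            "rt_expected": rt,
            "category": categories,
        }
    )


def simulate_cohort(
    config: GeneratorConfig, library: pd.DataFrame
) -> tuple[list[PeakTable], pd.DataFrame, GroundTruth]:
    """Emit per-sample peak tables, a manifest, and ground truth."""
    rng = np.random.default_rng(config.seed + 1)
    lib = library.reset_index(drop=True)
    mz_true = lib["mz_theoretical"].to_numpy(dtype=float)
    rt_true = lib["rt_expected"].to_numpy(dtype=float)
    mids = lib["metabolite_id"].to_numpy()
    endogenous = mids[(lib["category"] == "endogenous").to_numpy()]

    # plant class signatures: disjoint endogenous subsets, one signed shift each
    n_sig = config.n_signature_per_class
    if n_sig * len(CANCER_CLASSES) > len(endogenous):
        raise ValidationError("not enough endogenous metabolites for the requested signatures")
    chosen = rng.choice(endogenous, size=n_sig * len(CANCER_CLASSES), replace=False)
    signature_map: dict[str, dict[str, float]] = {}
    shift_ln = config.effect_log2fc * np.log(2.0)
    for c, cls in enumerate(CANCER_CLASSES):
        block = chosen[c * n_sig : (c + 1) * n_sig]
        signs = rng.choice([-1.0, 1.0], size=n_sig)
        signature_map[cls] = {mid: float(s * shift_ln) for mid, s in zip(block, signs)}

    mid_pos = {mid: i for i, mid in enumerate(mids)}
    shift_vectors: dict[str, np.ndarray] = {}
    for lbl in LABELS:
        vec = np.zeros(len(mids))
        for mid, eff in signature_map.get(lbl, {}).items():
            vec[mid_pos[mid]] = eff
        shift_vectors[lbl] = vec

    sample_rows = []
    tables: list[PeakTable] = []
    assignments: dict[str, np.ndarray] = {}
    true_label: dict[str, str] = {}
    counter = 0
    for lbl in LABELS:
        n = int(config.n_per_class.get(lbl, 0))
        for _ in range(n):
            counter += 1
            sid = f"S{counter:05d}"
            latent = (
                config.base_log_intensity_mean
                + shift_vectors[lbl]
                + rng.normal(0.0, config.base_log_intensity_sd, size=len(mids))
                + rng.normal(0.0, config.batch_scale_sd)
            )
            mz_obs = mz_true * (1.0 + rng.normal(0.0, config.sigma_ppm * 1e-6, size=len(mids)))
            rt_obs = rt_true + rng.normal(0.0, config.rt_jitter_sd, size=len(mids))
            p_miss = np.full(len(mids), config.missing_rate_random)
            if config.missing_intensity_knee is not None:
                p_int = 1.0 / (
                    1.0 + np.exp((latent - config.missing_intensity_knee) / config.missing_knee_width)
                )
                p_miss = p_miss + (1.0 - p_miss) * p_int
            keep = rng.uniform(size=len(mids)) >= p_miss
            order = np.argsort(mz_obs[keep], kind="stable")
            peaks = pd.DataFrame(
                {
                    "mz": mz_obs[keep][order],
                    "rt": np.clip(rt_obs[keep][order], 0.0, None),
                    "intensity": np.exp(latent[keep][order]),
                }
            )
            tables.append(PeakTable(sample_id=sid, peaks=peaks))
            assignments[sid] = mids[keep][order].copy()
            true_label[sid] = lbl
            decade = rng.integers(3, 8)  # dominant 30-80y age bands of the cohort
            sample_rows.append((sid, lbl, f"{decade * 10 + 1}-{decade * 10 + 10}"))

    manifest = pd.DataFrame(sample_rows, columns=["sample_id", "label", "age_group"])
    truth = GroundTruth(true_label=true_label, signature_map=signature_map, assignments=assignments)
    return tables, manifest, truth


def pooled_qc_samples(
    cohort: Sequence[PeakTable],
    ground_truth: GroundTruth,
    every_k: int = 50,
    seed: int = 0,
    noise_sd: float = 0.05,
    sigma_ppm: float = 0.0,
) -> list[PeakTable]:
    """Technical-replicate peak tables of the pooled QC sample.

    Pooling a small volume of every experimental sample yields, per
    metabolite, the cohort-mean intensity on the natural scale (samples
    lacking the metabolite contribute zero, as a physical pool would).
    One replicate is emitted per ``every_k`` cohort samples (at least
    one), each with fresh multiplicative technical noise of log-sd
    ``noise_sd`` and m/z error of ``sigma_ppm``.
    """
    if not cohort:
        raise ValidationError("cohort must be nonempty")
    if every_k < 1:
        raise ValidationError("every_k must be >= 1")
    rng = np.random.default_rng(seed)

    sums: dict[str, float] = {}
    mz_by_mid: dict[str, float] = {}
    rt_by_mid: dict[str, float] = {}
    for table in cohort:
        mids = ground_truth.assignments[table.sample_id]
        inten = table.peaks["intensity"].to_numpy()
        mz = table.peaks["mz"].to_numpy()
        rt = table.peaks["rt"].to_numpy()
        for mid, v, m, r in zip(mids, inten, mz, rt):
            sums[mid] = sums.get(mid, 0.0) + v
            mz_by_mid.setdefault(mid, m)
            rt_by_mid.setdefault(mid, r)
    n = len(cohort)
    mids = sorted(sums)
    mean = np.array([sums[m] / n for m in mids])
    mz0 = np.array([mz_by_mid[m] for m in mids])
    rt0 = np.array([rt_by_mid[m] for m in mids])

    n_qc = max(1, n // every_k)
    out: list[PeakTable] = []
    for q in range(n_qc):
        inten = mean * np.exp(rng.normal(0.0, noise_sd, size=len(mids))) if noise_sd > 0 else mean.copy()
        mz = mz0 * (1.0 + rng.normal(0.0, sigma_ppm * 1e-6, size=len(mids))) if sigma_ppm > 0 else mz0.copy()
        order = np.argsort(mz, kind="stable")
        peaks = pd.DataFrame({"mz": mz[order], "rt": rt0[order], "intensity": inten[order]})
        out.append(PeakTable(sample_id=f"QC{q + 1:03d}", peaks=peaks))
    return out
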