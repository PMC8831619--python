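"""One-command orchestration: generate → align → preprocess → train →
predict → evaluate → rank, as a reproducible, logged run.

Every stochastic stage takes its seed from the run config, all artifacts
are written as delimited text or JSON with round-trip float formatting,
and nothing in the run output depends on wall-clock time — so two runs
with identical config produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io
from .alignment import AlignmentConfig, align_cohort
from .evaluation import confusion, metrics, ovr_evaluate
from .io import CANCER_CLASSES
from .models import LayeredScreen, split_train_test
from .preprocess import median_rsd, preprocess_chain
from .ranking import rank_features, top_k_report
from .synthetic import GeneratorConfig, make_library, pooled_qc_samples, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full synthetic-cohort run needs.

    ``generator`` drives the synthetic cohort; alignment, preprocessing,
    modeling, and evaluation settings mirror the stage-level configs.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    knn_k: int = 5
    frac_train: float = 0.5
    weighting: str = "balanced"
    regularization_strength: float = 1.0
    threshold: float | None = None  # None -> training Youden
    include_normals: bool = True
    plsda_components: int = 2
    plsda_folds: int = 7
    rank_top_k: int = 100
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        aln = d.pop("alignment", {})
        if isinstance(aln, dict) and "excluded_categories" in aln:
            aln["excluded_categories"] = frozenset(aln["excluded_categories"])
        return cls(
            generator=GeneratorConfig(**gen) if isinstance(gen, dict) else gen,
            alignment=AlignmentConfig(**aln) if isinstance(aln, dict) else aln,
            **d,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"]["n_per_class"] = dict(self.generator.n_per_class)
        d["alignment"]["excluded_categories"] = sorted(self.alignment.excluded_categories)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _round(x, nd=6):
    return None if x is None else round(float(x), nd)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; write artifacts; return the metrics dict.

    Artifacts: library.tsv, manifest.tsv (with split), matrix.tsv,
    normalized_matrix.tsv, model1.json, model2.json, predictions.tsv,
    metrics.json, ranking.tsv, run_manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    gen = GeneratorConfig(**{**asdict(cfg.generator), "seed": cfg.seed})

    logger.info("stage generate: library %d+%d, cohort %s",
                gen.library_size, gen.n_contaminants, dict(gen.n_per_class))
    library = make_library(gen)
    runs, manifest, truth = simulate_cohort(gen, library)
    io.write_library(library, outdir / "library.tsv")

    logger.info("stage align: %d runs", len(runs))
    matrix, align_report = align_cohort(runs, library, cfg.alignment)
    io.write_feature_matrix(matrix, outdir / "matrix.tsv")

    split = split_train_test(manifest, frac_train=cfg.frac_train, seed=cfg.seed + 1)
    manifest = manifest.copy()
    manifest["split"] = manifest["sample_id"].map(split.assignment)
    io.write_manifest(manifest, outdir / "manifest.tsv")
    train_ids = [s for s in matrix.sample_ids if split.assignment[s] == "train"]
    test_ids = [s for s in matrix.sample_ids if split.assignment[s] == "test"]

    logger.info("stage preprocess: %d train / %d test samples", len(train_ids), len(test_ids))
    completed, ref, imputer = preprocess_chain(matrix, train_ids, k=cfg.knn_k)
    io.write_feature_matrix(completed, outdir / "normalized_matrix.tsv")
    io.save_normalization_reference(ref, outdir / "reference.json")
    io.save_imputer(imputer, outdir / "imputer.json")

    labels = manifest.set_index("sample_id")["label"]
    logger.info("stage train: layered screen on %d samples", len(train_ids))
    model = LayeredScreen(
        completed.subset_samples(train_ids),
        labels.loc[train_ids],
        weighting=cfg.weighting,
        regularization_strength=cfg.regularization_strength,
    )
    results = model.fit(threshold=cfg.threshold)
    io.save_model(results.binary_model, outdir / "model1.json")
    io.save_model(results.ovr_model, outdir / "model2.json")

    logger.info("stage predict: %d test samples", len(test_ids))
    preds = results.predict(completed.subset_samples(test_ids))
    preds.to_csv(outdir / "predictions.tsv", sep="\t")

    # --- evaluation ----------------------------------------------------
    truth_binary = labels.loc[test_ids].map(lambda v: "normal" if v == "normal" else "cancer")
    cm1 = confusion(truth_binary, preds["stage1_label"], positive_label="cancer")
    m1 = metrics(cm1)
    blocks = {}
    for cls in CANCER_CLASSES:
        cm, mr = ovr_evaluate(preds, labels, cls, include_normals=cfg.include_normals)
        blocks[cls] = {
            "TP": cm.TP, "TN": cm.TN, "FP": cm.FP, "FN": cm.FN,
            "sensitivity": _round(mr.sensitivity),
            "specificity": _round(mr.specificity),
            "accuracy": _round(mr.accuracy),
        }
    cancer_test = [s for s in test_ids if labels[s] != "normal"]
    tissue_acc = float(
        (preds.loc[cancer_test, "final_label"] == labels.loc[cancer_test]).mean()
    )

    qc = pooled_qc_samples(runs, truth, every_k=50, seed=cfg.seed + 2)
    qc_matrix, _ = align_cohort(qc, library, cfg.alignment) if len(qc) >= 2 else (None, None)
    qc_rsd = median_rsd(qc_matrix) if qc_matrix is not None else None

    metrics_out = {
        "alignment": align_report,
        "stage1": {
            "TP": cm1.TP, "TN": cm1.TN, "FP": cm1.FP, "FN": cm1.FN,
            "threshold": _round(results.threshold),
            "sensitivity": _round(m1.sensitivity),
            "specificity": _round(m1.specificity),
            "accuracy": _round(m1.accuracy),
        },
        "ovr": blocks,
        "tissue_of_origin_accuracy": _round(tissue_acc),
        "qc_median_rsd": _round(qc_rsd),
    }
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics_out, fh, indent=1, sort_keys=True)

    logger.info("stage rank: top %d features", cfg.rank_top_k)
    ranking = rank_features(
        results.binary_model, names=completed.annotations["name"].to_dict()
    )
    k = min(cfg.rank_top_k, len(ranking))
    report = top_k_report(ranking, k, annotations=completed.annotations)
    report.to_csv(outdir / "ranking.tsv", sep="\t", index=False,
                  float_format="%.10g")

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(
            {
                "config": cfg.to_dict(),
                "config_hash": cfg.config_hash(),
                "stage_order": [
                    "generate", "align", "preprocess", "train",
                    "predict", "evaluate", "rank",
                ],
                "seeds": {"generator": cfg.seed, "split": cfg.seed + 1, "qc": cfg.seed + 2},
            },
            fh, indent=1, sort_keys=True,
        )
    return metrics_out
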