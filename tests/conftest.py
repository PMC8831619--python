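import numpy as np
import pandas as pd
import pytest

from metabscreen import (
    LABELS,
    AlignmentConfig,
    GeneratorConfig,
    LayeredScreen,
    align_cohort,
    make_library,
    preprocess_chain,
    simulate_cohort,
    split_train_test,
)


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        n_per_class={lbl: 20 for lbl in LABELS},
        library_size=120,
        n_contaminants=12,
        n_signature_per_class=10,
        effect_log2fc=1.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    library = make_library(small_config)
    runs, manifest, truth = simulate_cohort(small_config, library)
    return library, runs, manifest, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    library, runs, _, _ = small_cohort
    matrix, report = align_cohort(runs, library, AlignmentConfig())
    return matrix, report


@pytest.fixture(scope="session")
def small_fit(small_cohort, small_matrix):
    """Preprocessed + fitted layered screen on the small cohort."""
    _, _, manifest, _ = small_cohort
    matrix, _ = small_matrix
    split = split_train_test(manifest, frac_train=0.5, seed=5)
    train_ids = [s for s in matrix.sample_ids if split.assignment[s] == "train"]
    test_ids = [s for s in matrix.sample_ids if split.assignment[s] == "test"]
    completed, ref, imputer = preprocess_chain(matrix, train_ids, k=5)
    labels = manifest.set_index("sample_id")["label"]
    results = LayeredScreen(completed.subset_samples(train_ids), labels.loc[train_ids]).fit()
    return {
        "completed": completed,
        "labels": labels,
        "train_ids": train_ids,
        "test_ids": test_ids,
        "results": results,
        "reference": ref,
        "imputer": imputer,
    }
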