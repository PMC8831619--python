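"""Shared test helpers."""

import numpy as np
import pandas as pd

from metabscreen import FeatureMatrix


def make_matrix(values, feature_ids=None, sample_ids=None, mz=None) -> FeatureMatrix:
    """FeatureMatrix from a plain array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    fids = list(feature_ids) if feature_ids is not None else [f"F{i:03d}" for i in range(p)]
    sids = list(sample_ids) if sample_ids is not None else [f"S{j:03d}" for j in range(n)]
    mz = np.asarray(mz, dtype=float) if mz is not None else 100.0 + np.arange(p)
    ann = pd.DataFrame(
        {
            "metabolite_id": fids,
            "name": [f"name-{f}" for f in fids],
            "mz_mean": mz,
            "rt_mean": np.linspace(1.0, 10.0, p),
        },
        index=pd.Index(fids, name="feature_id"),
    )
    return FeatureMatrix(annotations=ann, values=pd.DataFrame(values, index=ann.index, columns=sids))
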