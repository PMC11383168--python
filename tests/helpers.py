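"""Shared test utilities."""

import numpy as np
import pandas as pd

from jointnet.io import ExpressionMatrix, SampleMetadata
from jointnet.simulate import simulate_nb_counts


def make_null_expression(seed, n_genes=60, n_per=10, groups=("hand", "hip", "knee"),
                         condition="unstim", dispersion=0.05):
    """Exchangeable-null expression matrix + metadata (no group effects)."""
    rng = np.random.default_rng(seed)
    sids = [f"{g}{i:02d}" for g in groups for i in range(n_per)]
    base = np.exp(rng.uniform(np.log(30.0), np.log(300.0), n_genes))
    counts = simulate_nb_counts(base[:, None] * np.ones((1, len(sids))), dispersion, seed=rng)
    genes = [f"M{k:03d}" for k in range(n_genes)]
    expr = ExpressionMatrix(pd.DataFrame(counts.astype(float), index=genes, columns=sids))
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": sids,
        "group": [g for g in groups for _ in range(n_per)],
        "condition": condition,
        "subject_id": sids,
    }).set_index("sample_id"))
    return expr, meta
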