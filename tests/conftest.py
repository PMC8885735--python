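from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from genexpa.tables import CT_SCALE, QUANTITY_SCALE, ExpressionTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(values: np.ndarray, samples, genes, scale,
               replicates=None) -> ExpressionTable:
    """Table from a (n_samples * n_replicates, n_genes) array."""
    values = np.asarray(values, dtype=float)
    n_rep = replicates or values.shape[0] // len(samples)
    index = pd.MultiIndex.from_product(
        [list(samples), range(1, n_rep + 1)], names=["sample", "replicate"]
    )
    return ExpressionTable(pd.DataFrame(values, index=index, columns=list(genes)),
                           scale)


def random_quantity_table(rng, n_samples=3, n_replicates=3, n_genes=4,
                          spread=1.0) -> ExpressionTable:
    """Lognormal-ish positive quantities with per-gene, per-sample structure."""
    samples = [f"S{i+1}" for i in range(n_samples)]
    genes = [f"G{i+1}" for i in range(n_genes)]
    log_q = (rng.normal(0, spread, (n_samples, 1, n_genes))
             + rng.normal(0, 0.3, (n_samples, n_replicates, n_genes)))
    values = 2.0 ** log_q.reshape(n_samples * n_replicates, n_genes)
    return make_table(values, samples, genes, QUANTITY_SCALE)


@pytest.fixture
def rng():
    return np.random.default_rng(20210228)


@pytest.fixture
def tiny_ct() -> ExpressionTable:
    """2 samples x 3 replicates x 4 genes, deterministic values."""
    rng = np.random.default_rng(7)
    values = 20.0 + rng.normal(0, 0.5, (6, 4))
    return make_table(values, ["A", "B"], ["g1", "g2", "g3", "g4"], CT_SCALE)
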