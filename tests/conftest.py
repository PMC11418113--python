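import numpy as np
import pandas as pd
import pytest

from ocsubtypes import BulkSimConfig, ExpressionMatrix, generate_bulk


@pytest.fixture(scope="session")
def small_bulk():
    """A modest planted 4-subtype dataset shared by read-only tests."""
    cfg = BulkSimConfig(n_cohorts=3, samples_per_cohort=30, n_genes=200,
                        n_signature_genes_per_subtype=20, seed=11)
    return generate_bulk(cfg)


@pytest.fixture(scope="session")
def noiseless_bulk():
    cfg = BulkSimConfig(n_cohorts=2, samples_per_cohort=25, n_genes=120,
                        n_signature_genes_per_subtype=12,
                        batch_sd=0.0, noise_sd=0.0, seed=3)
    return generate_bulk(cfg)


def make_matrix(values: np.ndarray, genes=None, samples=None, **annot):
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    ann = pd.DataFrame(annot, index=samples) if annot else None
    return ExpressionMatrix(df, ann)
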