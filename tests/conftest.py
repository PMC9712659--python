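import numpy as np
import pandas as pd
import pytest

from scmosaic.preprocess import lognormalize, qc_pipeline
from scmosaic.simulate import default_config, simulate_dataset
from scmosaic.types import CountMatrix


@pytest.fixture(scope="session")
def demo():
    """The reference synthetic study (seed 1): counts, meta, truth."""
    return simulate_dataset(default_config(1))


@pytest.fixture(scope="session")
def demo_norm(demo):
    """QC'd and log-normalized reference study: (norm, meta, qc_log)."""
    counts, meta, _ = demo
    return qc_pipeline(counts, meta)


def tiny_counts(values, cell_prefix="c", gene_prefix="g"):
    """CountMatrix from a plain nested list (cells × genes)."""
    arr = np.asarray(values)
    return CountMatrix(
        arr,
        np.array([f"{cell_prefix}{i}" for i in range(arr.shape[0])]),
        np.array([f"{gene_prefix}{j}" for j in range(arr.shape[1])]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def norm_from_values(values, cell_ids=None, gene_ids=None):
    """NormMatrix with the given raw counts, log-normalized."""
    counts = np.asarray(values)
    cm = CountMatrix(
        counts,
        np.array(cell_ids if cell_ids is not None
                 else [f"c{i}" for i in range(counts.shape[0])]),
        np.array(gene_ids if gene_ids is not None
                 else [f"g{j}" for j in range(counts.shape[1])]),
    )
    return lognormalize(cm)


def labels_series(ids, labels):
    return pd.Series(list(labels), index=list(ids))
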