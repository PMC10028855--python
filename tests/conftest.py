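import numpy as np
import pandas as pd
import pytest

from sigcompass import ExpressionDataset, load_default_catalog
from sigcompass.catalog import SignatureDefinition, SignatureGene


@pytest.fixture(scope="session")
def default_catalog():
    return load_default_catalog()


@pytest.fixture
def toy_dataset():
    """5 genes x 4 observations, log scale, no zeros."""
    rng = np.random.default_rng(42)
    mat = pd.DataFrame(
        rng.uniform(1.0, 8.0, (5, 4)),
        index=["GA", "GB", "GC", "GD", "GE"],
        columns=["o1", "o2", "o3", "o4"],
    )
    return ExpressionDataset(matrix=mat, metric="log", technology="bulk_rnaseq")


@pytest.fixture
def counts_dataset():
    rng = np.random.default_rng(7)
    mat = pd.DataFrame(
        rng.poisson(30.0, (6, 5)).astype(float),
        index=[f"G{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(5)],
    )
    return ExpressionDataset(matrix=mat, metric="counts", technology="bulk_rnaseq")


def make_sig(name="Toy_Test", method="zscore_mean", genes=None, **kw):
    genes = genes if genes is not None else [SignatureGene("GA", "up"), SignatureGene("GB", "up")]
    defaults = dict(
        topic="Test activity",
        tumor_types=("pan-cancer",),
        first_author="Test",
        reference_id="1",
        input_types=frozenset({"sequencing"}),
        required_scale="log",
        method=method,
        genes=tuple(genes),
    )
    defaults.update(kw)
    return SignatureDefinition(name=name, **defaults)


@pytest.fixture
def sig_factory():
    return make_sig
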