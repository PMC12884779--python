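import numpy as np
import pytest

from scper.preprocess import BulkExpressionMatrix, GeneByCellCounts
from scper.synthdata import SyntheticSpec, generate_sc


@pytest.fixture(scope="session")
def small_sc() -> GeneByCellCounts:
    """Three-type, two-batch reference small enough for fast unit tests."""
    spec = SyntheticSpec(
        n_genes=300,
        cell_types={"alpha": 120, "beta": 120, "gamma": 120},
        n_marker_genes_per_type=20,
        batch_effect_genes=40,
        seed=101,
    )
    return generate_sc(spec)


@pytest.fixture()
def tiny_counts() -> GeneByCellCounts:
    """Hand-sized matrix where every QC decision can be checked by eye."""
    rng = np.random.default_rng(7)
    counts = rng.poisson(2.0, size=(30, 40)).astype(float)
    return GeneByCellCounts(
        gene_ids=np.array([f"g{i}" for i in range(30)], dtype=object),
        cell_ids=np.array([f"c{j}" for j in range(40)], dtype=object),
        counts=counts,
        cell_type=np.array(["t1"] * 20 + ["t2"] * 20, dtype=object),
        batch=np.array(["b1", "b2"] * 20, dtype=object),
    )


@pytest.fixture()
def small_bulk(small_sc) -> BulkExpressionMatrix:
    rng = np.random.default_rng(11)
    values = rng.poisson(5.0, size=(small_sc.n_genes, 6)).astype(float)
    return BulkExpressionMatrix(
        gene_ids=small_sc.gene_ids,
        sample_ids=np.array([f"s{j}" for j in range(6)], dtype=object),
        values=values,
    )
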