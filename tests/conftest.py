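import numpy as np
import pandas as pd
import pytest

from crinet import (
    CNAMatrix,
    ExpressionMatrix,
    InteractionTable,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def small_genes():
    data = pd.DataFrame(
        [[2.0, 4.0, 6.0, 8.0], [5.0, 3.0, 1.0, 7.0], [1.0, 1.0, 2.0, 2.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data, "FPKM")


@pytest.fixture
def small_mirnas():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]],
        index=["m1", "m2"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data, "RPM")


@pytest.fixture
def small_table():
    return InteractionTable(pd.DataFrame(
        {
            "regulator": ["m1", "m1", "m2", "m2"],
            "target": ["g1", "g2", "g2", "g3"],
            "raw_score": [-0.5, -0.3, -0.2, -0.4],
            "rna_class": ["mRNA", "mRNA", "lncRNA", "pseudogene"],
            "norm_weight": [1.0, 0.6, 0.4, 0.8],
        }
    ))


def random_toy_instance(rng, n_genes=None, n_mirnas=None, n_samples=None):
    """Random small miRNA-gene system with positive weights, for oracle tests."""
    n_genes = n_genes or int(rng.integers(2, 11))
    n_mirnas = n_mirnas or int(rng.integers(1, 6))
    n_samples = n_samples or int(rng.integers(5, 21))
    genes = ExpressionMatrix(pd.DataFrame(
        rng.uniform(0, 20, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    ))
    mirnas = ExpressionMatrix(pd.DataFrame(
        rng.uniform(0, 20, size=(n_mirnas, n_samples)),
        index=[f"m{i}" for i in range(n_mirnas)],
        columns=[f"s{i}" for i in range(n_samples)],
    ))
    rows = []
    for m in mirnas.entity_ids:
        for g in genes.entity_ids:
            if rng.random() < 0.6:
                rows.append((m, g, -rng.uniform(0.05, 0.9)))
    if not rows:  # ensure at least one record
        rows.append((mirnas.entity_ids[0], genes.entity_ids[0], -0.5))
    df = pd.DataFrame(rows, columns=["regulator", "target", "raw_score"])
    df["rna_class"] = "mRNA"
    df["norm_weight"] = -df["raw_score"]
    return genes, mirnas, InteractionTable(df)
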