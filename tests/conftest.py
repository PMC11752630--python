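import numpy as np
import pandas as pd
import pytest

from apamirnet.datatypes import ApaMatrix, ClusterAssignment, ExpressionMatrix


@pytest.fixture
def toy_apa():
    """One gene, two isoforms (cleavage 100 / 300), four cells."""
    meta = pd.DataFrame({
        "gene_id": ["G1", "G1"],
        "site_id": ["G1:PA0", "G1:PA1"],
        "cleavage_pos": [100, 300],
    })
    values = np.array([
        [10.0, 20.0, 3.0, 1.0],   # proximal isoform
        [2.0, 8.0, 4.0, 6.0],     # distal isoform
    ])
    return ApaMatrix(values=values, site_meta=meta,
                     cell_ids=["c1", "c2", "c3", "c4"])


@pytest.fixture
def toy_clusters():
    return ClusterAssignment(pd.Series(
        {"c1": "A", "c2": "A", "c3": "B", "c4": "B"}))


@pytest.fixture
def toy_sites():
    return pd.DataFrame({
        "family_id": ["F1"],
        "gene_id": ["G1"],
        "start": [150],
        "end": [157],
    })


@pytest.fixture
def small_expr():
    rng = np.random.default_rng(0)
    values = rng.poisson(2.0, size=(6, 10)).astype(float)
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(6)],
        cell_ids=[f"c{i}" for i in range(10)],
    )
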