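import numpy as np
import pandas as pd
import pytest

import coexpand as cx


@pytest.fixture(scope="session")
def planted():
    """One medium dataset with a planted cluster, pool and shifted pathway."""
    cfg = cx.SyntheticConfig(n_genes=2000, seed=42)
    matrix, metadata, truth = cx.simulate_expression(cfg)
    return cfg, matrix, metadata, truth


@pytest.fixture(scope="session")
def gwas_list(planted):
    """A 23-gene 'GWAS hit' list: the planted cluster plus 16 background genes."""
    _, _, _, truth = planted
    rng = np.random.default_rng(7)
    extras = sorted(str(g) for g in rng.choice(truth.background, 16, replace=False))
    return cx.GeneList("gwas", sorted(truth.cluster) + extras)


@pytest.fixture()
def toy_matrix():
    """A tiny hand-made matrix with known structure."""
    data = pd.DataFrame(
        {
            "s1": [1.0, 2.0, 5.0, 3.0],
            "s2": [2.0, 4.0, 4.0, 3.1],
            "s3": [3.0, 6.0, 3.0, 2.9],
            "s4": [4.0, 8.0, 2.0, 3.2],
        },
        index=["up", "double", "down", "flat"],
    )
    return cx.ExpressionMatrix(data)


@pytest.fixture()
def toy_metadata():
    return cx.SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "diagnosis": ["case", "case", "case", "case"],
                "region": ["r1"] * 4,
                "dataset": ["toy"] * 4,
            }
        )
    )
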