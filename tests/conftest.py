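import numpy as np
import pandas as pd
import pytest


def make_long_table(values: np.ndarray, genotypes=None, environments=None,
                    blocks=None) -> pd.DataFrame:
    """Long-format table from an array y[genotype, environment, block]."""
    g, e, r = values.shape
    genotypes = genotypes or [f"G{i+1}" for i in range(g)]
    environments = environments or [f"E{j+1}" for j in range(e)]
    blocks = blocks or [f"B{k+1}" for k in range(r)]
    gi, ei, ri = np.meshgrid(range(g), range(e), range(r), indexing="ij")
    return pd.DataFrame({
        "genotype": np.asarray(genotypes, object)[gi.ravel()],
        "environment": np.asarray(environments, object)[ei.ravel()],
        "block": np.asarray(blocks, object)[ri.ravel()],
        "value": values.ravel().astype(float),
    })


def random_balanced_table(rng: np.random.Generator, g: int, e: int,
                          r: int) -> pd.DataFrame:
    """Random balanced table with block, main-plot and sub-plot noise."""
    y = (
        rng.normal(0, 2, (g, 1, 1))        # genotype effects
        + rng.normal(0, 2, (1, e, 1))      # environment effects
        + rng.normal(0, 1, (g, e, 1))      # interaction
        + rng.normal(0, 1, (1, 1, r))      # block effects
        + rng.normal(0, 1, (1, e, r))      # main-plot error
        + rng.normal(0, 1, (g, e, r))      # sub-plot error
        + 10.0
    )
    return make_long_table(y)


@pytest.fixture
def tiny_table() -> pd.DataFrame:
    """2 genotypes x 2 environments x 2 blocks with hand-checkable values."""
    return pd.DataFrame({
        "genotype": ["A"] * 4 + ["B"] * 4,
        "environment": ["E1", "E1", "E2", "E2"] * 2,
        "block": ["b1", "b2"] * 4,
        "value": [1.0, 3.0, 2.0, 4.0, 5.0, 7.0, 6.0, 8.0],
    })
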