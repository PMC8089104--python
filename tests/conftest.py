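import numpy as np
import pandas as pd
import pytest

from scmodules import lognormalize
from scmodules.synthetic import (
    PlantedModule,
    SyntheticConfig,
    generate_expression,
    synthetic_annotation,
)


def planted_module_config(
    n_cells=500,
    n_genes=600,
    n_modules=10,
    module_size=30,
    effect=2.0,
    seed=1,
    **kwargs,
):
    """Planted-module layout used across tests: modules occupy the trailing
    genes, each driven by one tissue level."""
    start = n_genes - n_modules * module_size
    mods = tuple(
        PlantedModule(
            genes=tuple(range(start + i * module_size, start + (i + 1) * module_size)),
            effect=effect,
            factor="tissue",
            level=f"tissue{i % 3}",
        )
        for i in range(n_modules)
    )
    return SyntheticConfig(
        n_cells=n_cells, n_genes=n_genes, planted_modules=mods, seed=seed, **kwargs
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """500 cells x 600 genes with 10 planted 30-gene tissue-driven modules."""
    return generate_expression(planted_module_config())


@pytest.fixture(scope="session")
def norm_planted(planted_dataset):
    matrix, _, _ = planted_dataset
    return lognormalize(matrix)


@pytest.fixture()
def small_matrix():
    """Deterministic 50x20 integer count matrix with default annotation."""
    rng = np.random.default_rng(7)
    values = rng.integers(0, 30, (50, 20)).astype(float)
    values[:, 0] += 1  # no zero-total cells
    from scmodules import CountMatrix

    return CountMatrix(
        values, synthetic_annotation(50), pd.Index([f"c{i}" for i in range(20)])
    )
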