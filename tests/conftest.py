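import numpy as np
import pandas as pd
import pytest

from sesnet.expression import NormalizedMatrix
from sesnet.synth import CountsConfig, generate_cohort, generate_counts


@pytest.fixture(scope="session")
def cohort300():
    return generate_cohort(300, seed=11)


@pytest.fixture(scope="session")
def counts300(cohort300):
    counts, truth = generate_counts(
        cohort300, CountsConfig(n_genes=300), seed=11
    )
    return counts, truth


def make_norm(values: np.ndarray, gene_prefix: str = "g") -> NormalizedMatrix:
    """Wrap a genes x samples array as a NormalizedMatrix with unit factors."""
    g, n = values.shape
    cols = pd.Index([f"s{j}" for j in range(n)])
    return NormalizedMatrix(
        values=pd.DataFrame(
            values, index=[f"{gene_prefix}{i}" for i in range(g)], columns=cols
        ),
        norm_factors=pd.Series(1.0, index=cols),
    )


@pytest.fixture
def block_matrix():
    """Three orthogonal 50-gene blocks, per-gene noise sd 0.3, n=200."""
    rng = np.random.default_rng(42)
    n, per_block = 200, 50
    latent = rng.standard_normal((3, n))
    rows = np.vstack(
        [
            latent[b][None, :] + 0.3 * rng.standard_normal((per_block, n))
            for b in range(3)
        ]
    )
    return make_norm(rows), np.repeat([1, 2, 3], per_block)
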