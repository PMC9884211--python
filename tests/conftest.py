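import numpy as np
import pytest

from psychnet import Network, SyntheticSpec, generate_factor_data


@pytest.fixture(scope="session")
def easy_data():
    """Well-separated 4-factor ordinal data (easy recovery regime)."""
    spec = SyntheticSpec(
        n_respondents=1000, n_factors=4, items_per_factor=5,
        loading=0.7, factor_corr=0.2, seed=20,
    )
    return generate_factor_data(spec)


@pytest.fixture(scope="session")
def easy_network(easy_data):
    from psychnet import corr_matrix, estimate_network

    data, _ = easy_data
    return estimate_network(corr_matrix(data, method="pearson"))


def random_correlation(rng: np.random.Generator, p: int) -> np.ndarray:
    """Random well-conditioned correlation matrix."""
    a = rng.standard_normal((p, p + 3))
    s = a @ a.T / (p + 3)
    d = np.sqrt(np.diag(s))
    r = s / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def two_clique_network(weight: float = 0.5, bridge: float = 0.0) -> Network:
    """Two 4-cliques, optionally joined by one (possibly negative) edge."""
    w = np.zeros((8, 8))
    for block in (range(0, 4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = weight
    if bridge:
        w[0, 4] = w[4, 0] = bridge
    return Network(weights=w, node_ids=tuple(str(i) for i in range(8)))
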