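import numpy as np
import pytest

from mokpe.model import DtiNetwork, EmbeddingConfig
from mokpe.stiefel import OptimizerOptions
from mokpe.synthetic import SyntheticSpec, generate_network


@pytest.fixture(scope="session")
def planted():
    """A small noise-free network with planted 3-d geometry, plus its latents."""
    spec = SyntheticSpec(n_drugs=30, n_targets=15, R_true=3,
                         interaction_quantile=0.08, noise_sd=0.0, seed=7)
    return generate_network(spec)


@pytest.fixture(scope="session")
def planted_network(planted):
    return planted[0]


@pytest.fixture
def fast_config():
    """Embedding config with a reduced inner budget for quick unit-test fits."""
    return EmbeddingConfig(
        R=3, outer_iters=8, seed=1,
        optimizer=OptimizerOptions(max_iters=60),
    )


@pytest.fixture
def tiny_network():
    """A hand-sized 6-drug x 4-target network."""
    rng = np.random.default_rng(42)
    n_d, n_t = 6, 4
    pts_d = rng.standard_normal((n_d, 2)) / np.sqrt(n_d)
    pts_t = rng.standard_normal((n_t, 2)) / np.sqrt(n_t)

    def kmat(a, b, s):
        d2 = np.sum((a[:, None] - b[None]) ** 2, axis=2)
        return np.exp(-d2 / (2 * s**2))

    sd = kmat(pts_d, pts_d, 0.8)
    st = kmat(pts_t, pts_t, 0.8)
    np.fill_diagonal(sd, 1.0)
    np.fill_diagonal(st, 1.0)
    cross = kmat(pts_d, pts_t, 0.8)
    adj = (cross > np.quantile(cross, 0.75)).astype(float)
    return DtiNetwork(
        drug_ids=tuple(f"d{i}" for i in range(n_d)),
        target_ids=tuple(f"t{j}" for j in range(n_t)),
        adjacency=adj,
        sim_drugs=sd,
        sim_targets=st,
    )
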