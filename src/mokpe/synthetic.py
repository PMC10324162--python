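"""Synthetic interaction networks with a planted low-dimensional geometry.

Latent drug and target points are drawn in R_true dimensions at the scale of
Stiefel-constrained coordinate rows; similarities are Gaussian kernel values
of the latent points (optionally noised), and interactions are the top
quantile of cross-domain kernel values.  Every pipeline stage is therefore
testable without downloading the gold-standard data sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mokpe.model import DtiNetwork
from mokpe.stiefel import _qr_positive

__all__ = ["SyntheticSpec", "generate_network", "generate_sequences"]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted network."""

    n_drugs: int = 54
    n_targets: int = 26
    R_true: int = 5
    interaction_quantile: float = 0.0641
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.interaction_quantile < 1.0:
            raise ValueError("interaction_quantile must lie in (0, 1)")
        if self.R_true < 1:
            raise ValueError("R_true must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = np.sum((A[:, None, :] - B[None, :, :]) ** 2, axis=2)
    return np.exp(-d2 / (2.0 * sigma**2))


def _noisy_similarity(K: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    """Symmetrized, clipped-Gaussian-noised kernel matrix with unit diagonal."""
    if noise_sd > 0:
        K = K + rng.normal(0.0, noise_sd, size=K.shape)
    K = (K + K.T) / 2.0
    K = np.clip(K, 0.0, 1.0)
    np.fill_diagonal(K, 1.0)
    return K


def generate_network(spec: SyntheticSpec) -> tuple[DtiNetwork, dict[str, np.ndarray]]:
    """Sample a network whose three matrices share one latent geometry.

    Returns the network and the ground-truth latent coordinates
    ``{"drugs": ..., "targets": ...}``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nd, nt, r = spec.n_drugs, spec.n_targets, spec.R_true
    # latent blocks are genuine Stiefel points (QR of a Gaussian), so the
    # planted geometry is exactly reachable by the constrained embedding and
    # rows carry the Stiefel-typical scale sum ||row||^2 = R
    U = _qr_positive(rng.standard_normal((nd, r)))
    V = _qr_positive(rng.standard_normal((nt, r)))

    n_bar = (nd + nt) / 2.0
    sig_c = np.sqrt(2.0 * r / n_bar)
    sig_d = np.sqrt(2.0 * r / nd)
    sig_t = np.sqrt(2.0 * r / nt)

    sim_drugs = _noisy_similarity(_kernel(U, U, sig_d), spec.noise_sd, rng)
    sim_targets = _noisy_similarity(_kernel(V, V, sig_t), spec.noise_sd, rng)

    cross = _kernel(U, V, sig_c)
    threshold = np.quantile(cross, 1.0 - spec.interaction_quantile)
    adjacency = (cross > threshold).astype(float)
    if adjacency.sum() == 0:
        raise ValueError("parameters produced a network with zero interactions")

    width_d = len(str(nd))
    width_t = len(str(nt))
    network = DtiNetwork(
        drug_ids=tuple(f"D{i + 1:0{width_d}d}" for i in range(nd)),
        target_ids=tuple(f"hsa{j + 1:0{width_t}d}" for j in range(nt)),
        adjacency=adjacency,
        sim_drugs=sim_drugs,
        sim_targets=sim_targets,
    )
    return network, {"drugs": U, "targets": V}


def generate_sequences(
    n: int, length: int = 100, mutation_rate: float = 0.1, seed: int = 0,
    alphabet: str = _AMINO_ACIDS,
) -> list[str]:
    """Descendants of one random ancestor by i.i.d. substitution.

    Pairwise normalized local-alignment similarity between descendants
    decreases in expectation as ``mutation_rate`` grows.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    ancestor = rng.integers(len(letters), size=length)
    out = []
    for _ in range(n):
        child = ancestor.copy()
        mutate = rng.random(length) < mutation_rate
        child[mutate] = rng.integers(len(letters), size=int(mutate.sum()))
        out.append("".join(letters[child]))
    return out
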