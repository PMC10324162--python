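"""Kernel-preserving embedding over two Stiefel manifolds.

Drug coordinates X_d (an element of St(N_d, R)) and target coordinates X_t
(St(N_t, R)) are chosen so Gaussian kernel values between rows reproduce the
observed interaction scores and within-domain similarity scores.  Training
alternates Riemannian LBFGS solves over the two blocks; unseen drugs are
placed afterwards by an unconstrained out-of-sample solve against their
similarity profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from mokpe.scoring import (
    DEFAULT_INTERACTION_SCORE,
    ScoreSet,
    build_interaction_scores,
    validate_similarity_matrix,
)
from mokpe.stiefel import (
    OptimizerOptions,
    OptimizerTrace,
    StiefelPoint,
    lrbfgs_minimize,
    random_stiefel,
)

__all__ = [
    "DtiNetwork",
    "EmbeddingConfig",
    "Embedding",
    "gaussian_kernel",
    "objective",
    "euclidean_gradient_drugs",
    "euclidean_gradient_targets",
    "fit",
    "embed_new_drug",
    "predict_pair_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DtiNetwork:
    """The three observed matrices with aligned identifier lists.

    ``adjacency`` is binary N_d x N_t (1 = known interaction); ``sim_drugs``
    and ``sim_targets`` are symmetric similarity matrices in [0, 1] with unit
    diagonal (NaN entries allowed and treated as masked).
    """

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    adjacency: np.ndarray
    sim_drugs: np.ndarray
    sim_targets: np.ndarray

    def __post_init__(self):
        drug_ids = tuple(str(d) for d in self.drug_ids)
        target_ids = tuple(str(t) for t in self.target_ids)
        if len(set(drug_ids)) != len(drug_ids):
            raise ValueError("duplicate drug ids")
        if len(set(target_ids)) != len(target_ids):
            raise ValueError("duplicate target ids")
        adj = np.asarray(self.adjacency, dtype=float)
        if adj.shape != (len(drug_ids), len(target_ids)):
            raise ValueError(
                f"adjacency shape {adj.shape} inconsistent with "
                f"{len(drug_ids)} drugs x {len(target_ids)} targets"
            )
        if not np.all(np.isin(adj, (0.0, 1.0))):
            raise ValueError("adjacency must be binary")
        sd = validate_similarity_matrix(np.asarray(self.sim_drugs), "sim_drugs")
        st = validate_similarity_matrix(np.asarray(self.sim_targets), "sim_targets")
        if sd.shape != (len(drug_ids),) * 2:
            raise ValueError("sim_drugs shape inconsistent with drug ids")
        if st.shape != (len(target_ids),) * 2:
            raise ValueError("sim_targets shape inconsistent with target ids")
        object.__setattr__(self, "drug_ids", drug_ids)
        object.__setattr__(self, "target_ids", target_ids)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "sim_drugs", sd)
        object.__setattr__(self, "sim_targets", st)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_interactions(self) -> int:
        return int(self.adjacency.sum())


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyper-parameters of the embedding.

    ``sigma`` is the Gaussian kernel width: a scalar (shared), a
    (cross, drug, target) triple, or None for the scale-aware default
    sigma = sqrt(2 R / N) per term, N being the relevant block size (so the
    typical squared inter-point distance of Stiefel-constrained rows).
    ``k_nearest`` optionally restricts within-domain terms to each object's
    k most similar neighbors.
    """

    R: int = 10
    sigma: float | tuple[float, float, float] | None = None
    lambda_drugs: float = 1.0
    lambda_targets: float = 1.0
    outer_iters: int = 25
    outer_tol: float = 1e-6
    interaction_score: float = DEFAULT_INTERACTION_SCORE
    k_nearest: int | None = None
    optimizer: OptimizerOptions = field(default_factory=OptimizerOptions)
    seed: int = 0

    def __post_init__(self):
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if self.outer_iters < 1:
            raise ValueError("outer_iters must be >= 1")
        if self.lambda_drugs < 0 or self.lambda_targets < 0:
            raise ValueError("term weights must be nonnegative")
        if self.sigma is not None:
            sigmas = (
                (self.sigma,) * 3 if np.isscalar(self.sigma) else tuple(self.sigma)
            )
            if len(sigmas) != 3 or any(s <= 0 for s in sigmas):
                raise ValueError("sigma must be positive (scalar or triple)")

    def resolve_sigmas(self, n_drugs: int, n_targets: int) -> tuple[float, float, float]:
        """Concrete (cross, drug, target) kernel widths for given block sizes."""
        if self.sigma is not None:
            if np.isscalar(self.sigma):
                return (float(self.sigma),) * 3
            return tuple(float(s) for s in self.sigma)  # type: ignore[return-value]
        n_bar = (n_drugs + n_targets) / 2.0
        return (
            float(np.sqrt(2.0 * self.R / n_bar)),
            float(np.sqrt(2.0 * self.R / n_drugs)),
            float(np.sqrt(2.0 * self.R / n_targets)),
        )


@dataclass
class Embedding:
    """A trained embedding: one coordinate block per domain plus diagnostics."""

    X_d: StiefelPoint
    X_t: StiefelPoint
    config: EmbeddingConfig
    sigmas: tuple[float, float, float]
    final_loss: float
    loss_trace: list[float]  # loss after init and after every inner solve
    outer_losses: list[float]  # loss at the end of each outer iteration
    inner_traces: list[tuple[str, OptimizerTrace]] = field(default_factory=list)

    @property
    def drug_coords(self) -> np.ndarray:
        return self.X_d.matrix

    @property
    def target_coords(self) -> np.ndarray:
        return self.X_t.matrix


def gaussian_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """exp(-||x - y||^2 / (2 sigma^2)); 1 iff x == y."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d2 = float(np.sum((np.asarray(x, float) - np.asarray(y, float)) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _kernel_matrix(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-cdist(A, B, "sqeuclidean") / (2.0 * sigma**2))


def _upper_mask(mask: np.ndarray) -> np.ndarray:
    """Strictly-upper-triangular part of an observation mask (pairs i < j)."""
    return np.triu(mask, k=1)


def objective(
    X_d: np.ndarray,
    X_t: np.ndarray,
    scores: ScoreSet,
    sigmas: tuple[float, float, float],
    lambda_drugs: float = 1.0,
    lambda_targets: float = 1.0,
) -> float:
    """Masked squared-error between observed scores and embedded kernel values.

    Unobserved (NaN) entries contribute nothing; within-domain sums run over
    unordered pairs i < j.
    """
    X_d = np.asarray(X_d, float)
    X_t = np.asarray(X_t, float)
    if np.any(~np.isfinite(X_d)) or np.any(~np.isfinite(X_t)):
        raise ValueError("non-finite coordinates")
    sig_c, sig_d, sig_t = sigmas

    total = 0.0
    mc = scores.mask_c
    if mc.any():
        K = _kernel_matrix(X_d, X_t, sig_c)
        total += float(np.sum((scores.s_c[mc] - K[mc]) ** 2))
    md = _upper_mask(scores.mask_d)
    if md.any():
        K = _kernel_matrix(X_d, X_d, sig_d)
        total += lambda_drugs * float(np.sum((scores.s_d[md] - K[md]) ** 2))
    mt = _upper_mask(scores.mask_t)
    if mt.any():
        K = _kernel_matrix(X_t, X_t, sig_t)
        total += lambda_targets * float(np.sum((scores.s_t[mt] - K[mt]) ** 2))
    return total


def _pair_weights(s: np.ndarray, K: np.ndarray, mask: np.ndarray, sigma: float):
    """Per-pair gradient weights 2 (s - K) K / sigma^2, zero where masked."""
    w = np.zeros_like(K)
    w[mask] = 2.0 * (s[mask] - K[mask]) * K[mask] / sigma**2
    return w


def euclidean_gradient_drugs(
    X_d: np.ndarray,
    X_t: np.ndarray,
    scores: ScoreSet,
    sigmas: tuple[float, float, float],
    lambda_drugs: float = 1.0,
    lambda_targets: float = 1.0,
) -> np.ndarray:
    """Gradient of :func:`objective` with respect to the drug block X_d."""
    X_d = np.asarray(X_d, float)
    X_t = np.asarray(X_t, float)
    sig_c, sig_d, _ = sigmas
    grad = np.zeros_like(X_d)

    mc = scores.mask_c
    if mc.any():
        K = _kernel_matrix(X_d, X_t, sig_c)
        W = _pair_weights(scores.s_c, K, mc, sig_c)  # N_d x N_t
        grad += W.sum(axis=1, keepdims=True) * X_d - W @ X_t
    md = scores.mask_d & ~np.eye(X_d.shape[0], dtype=bool)
    if md.any():
        K = _kernel_matrix(X_d, X_d, sig_d)
        W = lambda_drugs * _pair_weights(scores.s_d, K, md, sig_d)
        W = (W + W.T) / 2.0  # symmetrize: each unordered pair counted once
        grad += W.sum(axis=1, keepdims=True) * X_d - W @ X_d
    return grad


def euclidean_gradient_targets(
    X_d: np.ndarray,
    X_t: np.ndarray,
    scores: ScoreSet,
    sigmas: tuple[float, float, float],
    lambda_drugs: float = 1.0,
    lambda_targets: float = 1.0,
) -> np.ndarray:
    """Gradient of :func:`objective` with respect to the target block X_t."""
    X_d = np.asarray(X_d, float)
    X_t = np.asarray(X_t, float)
    sig_c, _, sig_t = sigmas
    grad = np.zeros_like(X_t)

    mc = scores.mask_c
    if mc.any():
        K = _kernel_matrix(X_d, X_t, sig_c)
        W = _pair_weights(scores.s_c, K, mc, sig_c)
        grad += W.sum(axis=0)[:, None] * X_t - W.T @ X_d
    mt = scores.mask_t & ~np.eye(X_t.shape[0], dtype=bool)
    if mt.any():
        K = _kernel_matrix(X_t, X_t, sig_t)
        W = lambda_targets * _pair_weights(scores.s_t, K, mt, sig_t)
        W = (W + W.T) / 2.0
        grad += W.sum(axis=1, keepdims=True) * X_t - W @ X_t
    return grad


def _knn_mask(sim: np.ndarray, k: int) -> np.ndarray:
    """Symmetric mask keeping, for each object, its k most similar neighbors."""
    n = sim.shape[0]
    filled = np.nan_to_num(sim, nan=-np.inf)
    np.fill_diagonal(filled, -np.inf)
    mask = np.zeros((n, n), dtype=bool)
    k = min(k, n - 1)
    if k > 0:
        idx = np.argsort(-filled, axis=1)[:, :k]
        rows = np.repeat(np.arange(n), k)
        mask[rows, idx.ravel()] = True
        mask |= mask.T
    return mask & ~np.isnan(sim)


def build_score_set(network: DtiNetwork, cfg: EmbeddingConfig) -> ScoreSet:
    """Assemble the masked score matrices the loss actually sees."""
    s_c = build_interaction_scores(network.adjacency, cfg.interaction_score)
    s_d = network.sim_drugs.copy()
    s_t = network.sim_targets.copy()
    if cfg.k_nearest is not None:
        s_d = np.where(_knn_mask(s_d, cfg.k_nearest), s_d, np.nan)
        s_t = np.where(_knn_mask(s_t, cfg.k_nearest), s_t, np.nan)
    return ScoreSet(s_c=s_c, s_d=s_d, s_t=s_t)


def _warn_isolated(scores: ScoreSet, network: DtiNetwork):
    off_diag_d = scores.mask_d & ~np.eye(network.n_drugs, dtype=bool)
    lonely_drugs = ~(scores.mask_c.any(axis=1) | off_diag_d.any(axis=1))
    off_diag_t = scores.mask_t & ~np.eye(network.n_targets, dtype=bool)
    lonely_targets = ~(scores.mask_c.any(axis=0) | off_diag_t.any(axis=1))
    for kind, lonely, ids in (
        ("drug", lonely_drugs, network.drug_ids),
        ("target", lonely_targets, network.target_ids),
    ):
        for i in np.flatnonzero(lonely):
            logger.warning(
                "%s %s has no observed scores; it stays at its random "
                "initialization", kind, ids[i]
            )


def fit(network: DtiNetwork, cfg: EmbeddingConfig | None = None) -> Embedding:
    """Train the embedding by alternating manifold solves (drugs, then targets).

    Runs ``cfg.outer_iters`` outer iterations, stopping early once the loss
    improvement stays below ``cfg.outer_tol`` for two consecutive outer
    iterations.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or EmbeddingConfig()
    if cfg.R > min(network.n_drugs, network.n_targets):
        raise ValueError(
            f"R={cfg.R} exceeds the smaller block size "
            f"min({network.n_drugs}, {network.n_targets})"
        )
    sigmas = cfg.resolve_sigmas(network.n_drugs, network.n_targets)
    scores = build_score_set(network, cfg)
    _warn_isolated(scores, network)

    X_d = random_stiefel(network.n_drugs, cfg.R, cfg.seed)
    X_t = random_stiefel(network.n_targets, cfg.R, cfg.seed + 1)

    def loss(xd: np.ndarray, xt: np.ndarray) -> float:
        return objective(xd, xt, scores, sigmas, cfg.lambda_drugs, cfg.lambda_targets)

    current = loss(X_d.matrix, X_t.matrix)
    trace = [current]
    outer_losses: list[float] = []
    inner_traces: list[tuple[str, OptimizerTrace]] = []
    small_improvements = 0

    for outer in range(cfg.outer_iters):
        X_d, t_d = lrbfgs_minimize(
            f=lambda xd: loss(xd, X_t.matrix),
            grad=lambda xd: euclidean_gradient_drugs(
                xd, X_t.matrix, scores, sigmas, cfg.lambda_drugs, cfg.lambda_targets
            ),
            X0=X_d,
            opts=cfg.optimizer,
        )
        trace.append(loss(X_d.matrix, X_t.matrix))
        inner_traces.append(("drugs", t_d))

        X_t, t_t = lrbfgs_minimize(
            f=lambda xt: loss(X_d.matrix, xt),
            grad=lambda xt: euclidean_gradient_targets(
                X_d.matrix, xt, scores, sigmas, cfg.lambda_drugs, cfg.lambda_targets
            ),
            X0=X_t,
            opts=cfg.optimizer,
        )
        new = loss(X_d.matrix, X_t.matrix)
        trace.append(new)
        inner_traces.append(("targets", t_t))
        outer_losses.append(new)

        improvement = (outer_losses[-2] if outer else current) - new
        small_improvements = small_improvements + 1 if improvement < cfg.outer_tol else 0
        if small_improvements >= 2:
            logger.info("outer loop converged after %d iterations", outer + 1)
            break

    return Embedding(
        X_d=X_d,
        X_t=X_t,
        config=cfg,
        sigmas=sigmas,
        final_loss=outer_losses[-1],
        loss_trace=trace,
        outer_losses=outer_losses,
        inner_traces=inner_traces,
    )


def embed_new_drug(
    emb: Embedding, sim_profile: np.ndarray, cfg: EmbeddingConfig | None = None
) -> np.ndarray:
    """Place an unseen drug into a trained embedding from its similarity profile.

    ``sim_profile`` holds similarities to the training drugs (NaN = missing).
    The new coordinate minimizes the squared kernel-preservation error over
    the observed entries, unconstrained in R^R, starting from the
    similarity-weighted mean of the training-drug rows.
    """
    cfg = cfg or emb.config
    profile = np.asarray(sim_profile, dtype=float)
    if profile.shape != (emb.X_d.n,):
        raise ValueError(
            f"profile length {profile.shape} does not match {emb.X_d.n} training drugs"
        )
    obs = ~np.isnan(profile)
    if not obs.any():
        raise ValueError("cannot embed: similarity profile is entirely missing")
    sims = profile[obs]
    anchors = emb.drug_coords[obs]
    sigma = emb.sigmas[1]

    total = sims.sum()
    weights = sims / total if total > 0 else np.full(sims.shape, 1.0 / sims.size)
    x0 = weights @ anchors

    def fun(x):
        d2 = np.sum((x[None, :] - anchors) ** 2, axis=1)
        kappa = np.exp(-d2 / (2.0 * sigma**2))
        resid = sims - kappa
        value = float(np.sum(resid**2))
        grad = (2.0 * resid * kappa / sigma**2) @ (x[None, :] - anchors)
        return value, grad

    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
    return np.asarray(res.x, dtype=float)


def predict_pair_scores(
    drug_vecs: np.ndarray, emb: Embedding, cfg: EmbeddingConfig | None = None
) -> np.ndarray:
    """Kernel scores between given drug coordinates and every embedded target.

    Entry (i, j) is the cross-domain Gaussian kernel between drug vector i
    and target row j; ranking by these scores equals ranking by negative
    embedded Euclidean distance.
    """
    drug_vecs = np.atleast_2d(np.asarray(drug_vecs, dtype=float))
    if drug_vecs.size == 0:
        return np.empty((0, emb.X_t.n))
    if drug_vecs.shape[1] != emb.X_t.R:
        raise ValueError(
            f"drug vectors have dimension {drug_vecs.shape[1]}, expected {emb.X_t.R}"
        )
    return _kernel_matrix(drug_vecs, emb.target_coords, emb.sigmas[0])
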