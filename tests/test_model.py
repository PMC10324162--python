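import logging

import numpy as np
import pytest

from mokpe.model import (
    DtiNetwork,
    Embedding,
    EmbeddingConfig,
    build_score_set,
    embed_new_drug,
    euclidean_gradient_drugs,
    euclidean_gradient_targets,
    fit,
    gaussian_kernel,
    objective,
    predict_pair_scores,
)
from mokpe.scoring import ScoreSet
from mokpe.stiefel import OptimizerOptions, StiefelPoint


def random_scores(n_d, n_t, seed, density=0.7):
    rng = np.random.default_rng(seed)
    def mat(shape, symmetric=False):
        m = rng.random(shape)
        mask = rng.random(shape) < density
        m = np.where(mask, m, np.nan)
        if symmetric:
            m = np.triu(m, 1)
            m = m + m.T
            np.fill_diagonal(m, 1.0)
        return m
    return ScoreSet(
        s_c=np.where(rng.random((n_d, n_t)) < density, 0.9, np.nan),
        s_d=mat((n_d, n_d), symmetric=True),
        s_t=mat((n_t, n_t), symmetric=True),
    )


class TestGaussianKernel:
    def test_coincident_points(self):
        assert gaussian_kernel(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 0.5) == 1.0

    def test_distance_sigma_sqrt2(self):
        x = np.array([0.0])
        y = np.array([np.sqrt(2.0) * 0.7])
        assert gaussian_kernel(x, y, 0.7) == pytest.approx(np.exp(-1.0))

    def test_three_four_five(self):
        v = gaussian_kernel(np.array([0.0, 0.0]), np.array([3.0, 4.0]), 5.0)
        assert v == pytest.approx(np.exp(-0.5))

    def test_sigma_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_kernel(np.zeros(2), np.ones(2), 0.0)


class TestObjective:
    def test_all_na_is_zero(self):
        scores = ScoreSet(
            s_c=np.full((2, 2), np.nan),
            s_d=np.full((2, 2), np.nan),
            s_t=np.full((2, 2), np.nan),
        )
        X_d = np.random.default_rng(0).standard_normal((2, 2))
        X_t = np.random.default_rng(1).standard_normal((2, 2))
        assert objective(X_d, X_t, scores, (1.0, 1.0, 1.0)) == 0.0

    def test_exactly_preserved_pair_is_zero(self):
        # distance chosen so kappa = 0.9 with sigma = 1
        d = np.sqrt(-2.0 * np.log(0.9))
        scores = ScoreSet(
            s_c=np.array([[0.9]]),
            s_d=np.array([[1.0]]),
            s_t=np.array([[1.0]]),
        )
        X_d = np.array([[0.0]])
        X_t = np.array([[d]])
        assert objective(X_d, X_t, scores, (1.0, 1.0, 1.0)) == pytest.approx(0.0, abs=1e-15)

    def test_hand_expanded_sum(self):
        # 2 drugs, 1 target, every entry observed, sigma = 1 everywhere
        x1, x2 = np.array([0.0, 0.0]), np.array([1.0, 0.0])
        z = np.array([0.0, 2.0])
        scores = ScoreSet(
            s_c=np.array([[0.9], [0.9]]),
            s_d=np.array([[1.0, 0.5], [0.5, 1.0]]),
            s_t=np.array([[1.0]]),
        )
        k = lambda a, b: np.exp(-np.sum((a - b) ** 2) / 2.0)
        expected = (
            (0.9 - k(x1, z)) ** 2
            + (0.9 - k(x2, z)) ** 2
            + 2.0 * (0.5 - k(x1, x2)) ** 2  # lambda_d = 2
        )
        got = objective(np.vstack([x1, x2]), z[None, :], scores,
                        (1.0, 1.0, 1.0), lambda_drugs=2.0)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nan_coordinates_rejected(self):
        scores = random_scores(2, 2, 0)
        with pytest.raises(ValueError, match="finite"):
            objective(np.full((2, 2), np.nan), np.zeros((2, 2)), scores,
                      (1.0, 1.0, 1.0))


def finite_difference(fun, X, h=1e-6):
    g = np.zeros_like(X)
    for idx in np.ndindex(X.shape):
        Xp, Xm = X.copy(), X.copy()
        Xp[idx] += h
        Xm[idx] -= h
        g[idx] = (fun(Xp) - fun(Xm)) / (2.0 * h)
    return g


class TestGradients:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_drug_gradient_matches_finite_differences(self, seed):
        scores = random_scores(3, 2, seed)
        rng = np.random.default_rng(seed + 100)
        X_d = rng.standard_normal((3, 2))
        X_t = rng.standard_normal((2, 2))
        sigmas = (0.9, 1.1, 0.8)
        fun = lambda xd: objective(xd, X_t, scores, sigmas, 1.3, 0.7)
        analytic = euclidean_gradient_drugs(X_d, X_t, scores, sigmas, 1.3, 0.7)
        fd = finite_difference(fun, X_d)
        np.testing.assert_allclose(analytic, fd, rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_target_gradient_matches_finite_differences(self, seed):
        scores = random_scores(3, 2, seed)
        rng = np.random.default_rng(seed + 100)
        X_d = rng.standard_normal((3, 2))
        X_t = rng.standard_normal((2, 2))
        sigmas = (0.9, 1.1, 0.8)
        fun = lambda xt: objective(X_d, xt, scores, sigmas, 1.3, 0.7)
        analytic = euclidean_gradient_targets(X_d, X_t, scores, sigmas, 1.3, 0.7)
        fd = finite_difference(fun, X_t)
        np.testing.assert_allclose(analytic, fd, rtol=1e-6, atol=1e-9)

    def test_zero_gradient_at_exact_fit(self):
        d = np.sqrt(-2.0 * np.log(0.9))
        scores = ScoreSet(s_c=np.array([[0.9]]), s_d=np.array([[1.0]]),
                          s_t=np.array([[1.0]]))
        X_d = np.array([[0.0]])
        X_t = np.array([[d]])
        np.testing.assert_allclose(
            euclidean_gradient_drugs(X_d, X_t, scores, (1.0, 1.0, 1.0)), 0.0,
            atol=1e-14)

    def test_within_domain_gradient_rows_sum_to_zero(self):
        # pairwise distances are translation invariant
        rng = np.random.default_rng(9)
        n = 5
        sim = rng.random((n, n))
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        scores = ScoreSet(
            s_c=np.full((n, 1), np.nan),
            s_d=sim,
            s_t=np.array([[1.0]]),
        )
        X_d = rng.standard_normal((n, 3))
        X_t = rng.standard_normal((1, 3))
        g = euclidean_gradient_drugs(X_d, X_t, scores, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-12)


class TestFit:
    def test_recovers_planted_geometry(self, planted_network, fast_config):
        emb = fit(planted_network, fast_config)
        assert emb.final_loss < 0.01 * emb.loss_trace[0]

    def test_single_outer_iteration_records_two_phases(self, tiny_network):
        cfg = EmbeddingConfig(R=2, outer_iters=1, seed=0,
                              optimizer=OptimizerOptions(max_iters=30))
        emb = fit(tiny_network, cfg)
        assert [phase for phase, _ in emb.inner_traces] == ["drugs", "targets"]

    def test_deterministic_given_seed(self, tiny_network):
        cfg = EmbeddingConfig(R=2, outer_iters=3, seed=5,
                              optimizer=OptimizerOptions(max_iters=30))
        a = fit(tiny_network, cfg)
        b = fit(tiny_network, cfg)
        assert a.final_loss == b.final_loss
        np.testing.assert_array_equal(a.drug_coords, b.drug_coords)
        np.testing.assert_array_equal(a.target_coords, b.target_coords)

    def test_loss_trace_non_increasing(self, tiny_network, fast_config):
        cfg = EmbeddingConfig(R=2, outer_iters=8, seed=2,
                              optimizer=OptimizerOptions(max_iters=40))
        emb = fit(tiny_network, cfg)
        trace = np.array(emb.loss_trace)
        assert np.all(np.diff(trace) <= 1e-10)

    def test_blocks_stay_orthonormal(self, tiny_network):
        cfg = EmbeddingConfig(R=2, outer_iters=5, seed=3,
                              optimizer=OptimizerOptions(max_iters=40))
        emb = fit(tiny_network, cfg)
        for block in (emb.X_d, emb.X_t):
            gram = block.matrix.T @ block.matrix
            assert np.max(np.abs(gram - np.eye(block.R))) <= 1e-10

    def test_larger_subspace_never_fits_worse_up_to_planted_rank(self, planted_network):
        # Stiefel blocks carry total column energy R, so manifolds for
        # different R do not nest; the non-increasing-loss trend is only
        # guaranteed while R stays at or below the planted dimensionality (3).
        losses = []
        for r in (1, 2, 3):
            cfg = EmbeddingConfig(R=r, outer_iters=10, seed=4,
                                  optimizer=OptimizerOptions(max_iters=80))
            losses.append(fit(planted_network, cfg).final_loss)
        assert losses[1] <= losses[0] * 1.05 + 1e-8
        assert losses[2] <= losses[1] * 1.05 + 1e-8

    def test_r_larger_than_block_rejected(self, tiny_network):
        with pytest.raises(ValueError, match="exceeds"):
            fit(tiny_network, EmbeddingConfig(R=5))

    def test_isolated_drug_warns(self, caplog):
        net = DtiNetwork(
            drug_ids=("d1", "d2"),
            target_ids=("t1",),
            adjacency=np.array([[1.0], [0.0]]),
            sim_drugs=np.array([[1.0, np.nan], [np.nan, 1.0]]),
            sim_targets=np.array([[1.0]]),
        )
        cfg = EmbeddingConfig(R=1, outer_iters=1, seed=0,
                              optimizer=OptimizerOptions(max_iters=5))
        with caplog.at_level(logging.WARNING, logger="mokpe.model"):
            fit(net, cfg)
        assert any("d2" in rec.message for rec in caplog.records)


class TestKnnMask:
    def test_within_domain_terms_restricted(self, planted_network):
        cfg_full = EmbeddingConfig(R=3, k_nearest=None)
        cfg_knn = EmbeddingConfig(R=3, k_nearest=3)
        full = build_score_set(planted_network, cfg_full)
        knn = build_score_set(planted_network, cfg_knn)
        assert knn.mask_d.sum() < full.mask_d.sum()
        # kept entries are a subset of the original observations
        assert not np.any(knn.mask_d & ~full.mask_d)
        np.testing.assert_array_equal(knn.mask_d, knn.mask_d.T)


@pytest.fixture(scope="module")
def trained(planted_network):
    cfg = EmbeddingConfig(R=3, outer_iters=10, seed=6,
                          optimizer=OptimizerOptions(max_iters=100))
    return fit(planted_network, cfg), cfg


class TestEmbedNewDrug:

    def test_self_consistency(self, trained):
        emb, cfg = trained
        sigma = emb.sigmas[1]
        X = emb.drug_coords
        i = 4
        d2 = np.sum((X[i] - X) ** 2, axis=1)
        profile = np.exp(-d2 / (2 * sigma**2))
        x_star = embed_new_drug(emb, profile, cfg)
        recovered = np.exp(-np.sum((x_star - X) ** 2, axis=1) / (2 * sigma**2))
        assert np.max(np.abs(recovered - profile)) <= 1e-3

    def test_single_similarity_one_forces_coincidence(self, trained):
        emb, cfg = trained
        profile = np.full(emb.X_d.n, np.nan)
        profile[2] = 1.0
        x_star = embed_new_drug(emb, profile, cfg)
        kappa = np.exp(-np.sum((x_star - emb.drug_coords[2]) ** 2)
                       / (2 * emb.sigmas[1] ** 2))
        assert kappa >= 0.999

    def test_uniform_profile_on_symmetric_pair(self):
        # two training drugs mirrored about the origin in St(2, 1)
        X_d = StiefelPoint(np.array([[1.0], [-1.0]]) / np.sqrt(2.0))
        X_t = StiefelPoint(np.array([[1.0]]))
        cfg = EmbeddingConfig(R=1, sigma=1.0)
        emb = Embedding(X_d=X_d, X_t=X_t, config=cfg, sigmas=(1, 1, 1),
                        final_loss=0.0, loss_trace=[0.0], outer_losses=[0.0])
        x_star = embed_new_drug(emb, np.array([0.5, 0.5]), cfg)
        d = np.abs(np.array([np.linalg.norm(x_star - X_d.matrix[0]),
                             np.linalg.norm(x_star - X_d.matrix[1])]))
        assert abs(d[0] - d[1]) <= 1e-6

    def test_all_missing_profile_rejected(self, trained):
        emb, cfg = trained
        with pytest.raises(ValueError, match="missing"):
            embed_new_drug(emb, np.full(emb.X_d.n, np.nan), cfg)


class TestPredictPairScores:
    def test_target_row_scores_one(self, trained):
        emb, cfg = trained
        scores = predict_pair_scores(emb.target_coords[1], emb, cfg)
        assert scores[0, 1] == pytest.approx(1.0)

    def test_ranking_matches_negative_distance(self, trained):
        emb, cfg = trained
        rng = np.random.default_rng(0)
        vec = rng.standard_normal(3) * 0.3
        scores = predict_pair_scores(vec, emb, cfg)[0]
        dist = np.linalg.norm(vec - emb.target_coords, axis=1)
        np.testing.assert_array_equal(np.argsort(-scores), np.argsort(dist))

    def test_empty_input(self, trained):
        emb, cfg = trained
        out = predict_pair_scores(np.empty((0, 3)), emb, cfg)
        assert out.shape == (0, emb.X_t.n)

    def test_dimension_mismatch(self, trained):
        emb, cfg = trained
        with pytest.raises(ValueError, match="dimension"):
            predict_pair_scores(np.zeros((2, 7)), emb, cfg)
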