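import numpy as np
import pytest

from temposeg.grid import CorrelationSpec, GridSpec, null_spec_for
from temposeg.latent import synthesize_latent
from temposeg.observer import (
    ObserverParams,
    _batch_segmentation_r2,
    _distance_weights,
    add_internal_noise,
    alignment_r2,
    binarize_affinity,
    decide_trial,
    fiedler_map,
    normalized_laplacian,
    segmentation_r2,
    weighted_similarity,
)


class TestInternalNoise:
    def test_unit_signal_rate_is_identity(self, rng):
        x = rng.standard_normal((4, 4, 10))
        assert np.array_equal(add_internal_noise(x, 1.0, 0), x)

    def test_zero_signal_rate_is_pure_noise(self, rng):
        x = rng.standard_normal((4, 4, 10))
        out1 = add_internal_noise(x, 0.0, 42)
        out2 = add_internal_noise(np.zeros_like(x), 0.0, 42)
        assert np.array_equal(out1, out2)  # independent of the stimulus

    def test_output_variance_follows_mixture_algebra(self, rng):
        s = 0.6
        x = rng.uniform(-1, 1, size=(8, 16, 30))
        outs = np.stack([add_internal_noise(x, s, seed) for seed in range(400)])
        var = outs.var(axis=0).mean()  # variance across noise draws, fixed stimulus
        assert var == pytest.approx((1 - s) ** 2, rel=0.05)


class TestWeightedSimilarity:
    def test_infinite_sigma_recovers_plain_cosine(self, rng):
        grid = GridSpec(4, 4, 10)
        x = rng.standard_normal(grid.shape)
        from temposeg.validation import similarity_matrix

        assert np.allclose(weighted_similarity(x, np.inf, grid), similarity_matrix(x, grid))

    def test_adjacent_identical_cells_weighted_by_exp_minus_one(self):
        grid = GridSpec(2, 2, 5)
        x = np.tile(np.array([1.0, -0.5, 0.3, 0.8, -0.2]), (2, 2, 1))
        sim = weighted_similarity(x, 1.0, grid)
        assert sim[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)  # distance 1
        assert sim[0, 3] == pytest.approx(np.exp(-2.0), abs=1e-12)  # distance sqrt(2)

    def test_zero_sigma_reduces_to_identity(self, rng):
        grid = GridSpec(2, 2, 5)
        x = rng.standard_normal(grid.shape)
        sim = weighted_similarity(x, 0.0, grid)
        assert np.array_equal(sim, np.eye(4))


class TestAffinityAndLaplacian:
    def test_constant_similarity_binarizes_to_ones(self):
        assert np.array_equal(binarize_affinity(np.full((3, 3), 0.4)), np.ones((3, 3)))

    def test_two_block_toy_binarizes_block_diagonal(self):
        s = np.array([
            [1.0, 0.9, 0.1, 0.1],
            [0.9, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.9],
            [0.1, 0.1, 0.9, 1.0],
        ])
        a = binarize_affinity(s)
        expected = np.kron(np.eye(2), np.ones((2, 2)))
        assert np.array_equal(a, expected)
        assert np.array_equal(a, a.T)

    def test_laplacian_hand_example(self):
        lap = normalized_laplacian(np.ones((2, 2)))
        assert np.allclose(lap, [[0.5, -0.5], [-0.5, 0.5]])
        assert np.allclose(np.sort(np.linalg.eigvalsh(lap)), [0.0, 1.0])

    def test_identity_affinity_gives_zero_laplacian(self):
        assert np.allclose(normalized_laplacian(np.eye(5)), 0.0)

    def test_zero_degree_row_left_as_identity(self):
        a = np.zeros((3, 3))
        a[1, 2] = a[2, 1] = 1.0
        lap = normalized_laplacian(a)
        assert np.allclose(lap[0], [1.0, 0.0, 0.0])

    def test_spectrum_bounded_in_zero_two(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 10))
            a = (rng.random((n, n)) < 0.5).astype(float)
            a = np.triu(a, 1)
            a = a + a.T
            np.fill_diagonal(a, 1.0)
            w = np.linalg.eigvalsh(normalized_laplacian(a))
            assert w.min() >= -1e-9 and w.max() <= 2.0 + 1e-9


class TestFiedler:
    def test_disconnected_cliques_constant_per_clique(self):
        a = np.kron(np.eye(2), np.ones((3, 3)))
        grid = GridSpec(3, 2, 4)
        emap = fiedler_map(normalized_laplacian(a), grid)
        flat = emap.T.ravel()  # canonical column-major flattening
        assert np.allclose(flat[:3], flat[0], atol=1e-8)
        assert np.allclose(flat[3:], flat[3], atol=1e-8)

    def test_planted_two_clique_graph_split_exactly(self):
        # two 4-cliques joined by a single bridge edge: connected graph,
        # non-degenerate Fiedler eigenvalue, clean bipartition
        a = np.kron(np.eye(2), np.ones((4, 4)))
        a[3, 4] = a[4, 3] = 1.0
        grid = GridSpec(4, 2, 4)
        emap = fiedler_map(normalized_laplacian(a), grid)
        flat = emap.T.ravel()
        signs = np.sign(flat)
        assert len(set(signs[:4])) == 1
        assert len(set(signs[4:])) == 1
        assert signs[0] != signs[4]

    def test_map_reshape_round_trip(self, rng):
        grid = GridSpec(4, 2, 4)
        a = (rng.random((8, 8)) < 0.5).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        np.fill_diagonal(a, 1.0)
        lap = normalized_laplacian(a)
        emap = fiedler_map(lap, grid)
        _, vecs = np.linalg.eigh(lap)
        assert np.allclose(emap.T.ravel(), vecs[:, 1])


class TestAlignment:
    def test_sign_and_scale_invariance(self, full_grid, rng):
        target = full_grid.target_map()
        assert alignment_r2(target, target) == pytest.approx(1.0)
        assert alignment_r2(-target, target) == pytest.approx(1.0)
        g = rng.standard_normal(target.shape)
        base = alignment_r2(g, target)
        for c in (-3.0, 0.2, 7.0):
            assert alignment_r2(c * g, target) == pytest.approx(base, abs=1e-12)

    def test_constant_map_scores_zero(self, full_grid):
        assert alignment_r2(np.ones(full_grid.target_map().shape), full_grid.target_map()) == 0.0


class TestTrials:
    def test_decision_follows_alignment_ordering(self, full_grid):
        params = ObserverParams.naive()
        sig = synthesize_latent(CorrelationSpec(0.9, 0.1), full_grid, seed=0)
        nul = synthesize_latent(CorrelationSpec(0.9, 0.9, is_null=True), full_grid, seed=1)
        outcome = decide_trial(sig, nul, params, full_grid, seed_or_rng=0)
        assert outcome.decision == ("signal" if outcome.r2_signal > outcome.r2_null else "null")
        assert outcome.r2_signal > 0.8  # clean segmentation of a strong signal

    def test_exact_tie_resolved_by_fair_coin(self, full_grid):
        params = ObserverParams.naive()
        stim = synthesize_latent(CorrelationSpec(0.5, 0.5, is_null=True), full_grid, seed=2)
        rng = np.random.default_rng(7)
        outcomes = [decide_trial(stim, stim, params, full_grid, rng).decision
                    for _ in range(400)]
        p = np.mean([o == "signal" for o in outcomes])
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / 400)  # within 3 binomial SE

    def test_strong_signal_nearly_always_wins(self, full_grid):
        params = ObserverParams.naive()
        sigs = [synthesize_latent(CorrelationSpec(0.9, 0.1), full_grid, seed=s) for s in range(4)]
        nuls = [synthesize_latent(CorrelationSpec(0.9, 0.9, is_null=True), full_grid, seed=10 + s)
                for s in range(4)]
        rng = np.random.default_rng(0)
        wins = sum(
            decide_trial(sigs[i % 4], nuls[(i * 7) % 4], params, full_grid, rng).decision == "signal"
            for i in range(120)
        )
        assert wins / 120 >= 0.95

    def test_batch_pipeline_matches_single_trial_path(self, full_grid):
        params = ObserverParams(signal_rate=1.0, sigma_delta=5.0)  # deterministic at s=1
        stims = [synthesize_latent(CorrelationSpec(0.7, 0.2), full_grid, seed=s) for s in range(5)]
        flat = np.stack([full_grid.flatten_series(s.values) for s in stims])
        target = np.where(np.arange(full_grid.n_cells) < 64, 1.0, -1.0)
        batch = _batch_segmentation_r2(
            flat, params, full_grid, np.random.default_rng(0),
            _distance_weights(params.sigma_delta, full_grid), target,
        )
        singles = [segmentation_r2(s, params, full_grid, np.random.default_rng(0)) for s in stims]
        assert np.allclose(batch, singles, atol=1e-9)
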