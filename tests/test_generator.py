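import numpy as np
import pytest

from temposeg.grid import CorrelationSpec, ExperimentDesign, GridSpec
from temposeg.generator import (
    GeneratorConfig,
    LossBreakdown,
    LossWeights,
    _decode_backward,
    _decode_with_cache,
    _loss_and_grad,
    distribution_losses,
    generate_bank,
    model_forward,
    optimize_stimulus,
    sample_noise_prior,
    similarity_losses,
    total_loss,
    variance_expansion_loss,
)


class TestNoisePrior:
    def test_shape_and_determinism(self, full_grid):
        a = sample_noise_prior(full_grid, seed=4)
        b = sample_noise_prior(full_grid, seed=4)
        assert a.shape == (8, 16, 30)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, sample_noise_prior(full_grid, seed=5))

    def test_zero_mean_within_standard_error(self, full_grid):
        draws = np.concatenate(
            [sample_noise_prior(full_grid, seed=s).ravel() for s in range(30)]
        )
        assert draws.size >= 100_000
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean()) < 3 * se


class TestLossTerms:
    def test_identical_series_hit_unit_target(self):
        grid = GridSpec(2, 2, 6)
        series = np.array([0.5, -0.2, 0.8, 0.1, -0.6, 0.3])
        values = np.tile(series, (2, 2, 1))
        la, lb, lab = similarity_losses(values, CorrelationSpec(1.0, 1.0), grid)
        assert la == pytest.approx(0.0, abs=1e-12)
        assert lb == pytest.approx(0.0, abs=1e-12)
        assert lab == pytest.approx(0.0, abs=1e-12)

    def test_two_cell_within_loss_hand_value(self):
        # area A holds two series with cos exactly 0.5; target 0.3 -> loss 0.2
        grid = GridSpec(2, 2, 4)
        u = np.array([1.0, 0.0, 0.0, 0.0])
        v = np.array([0.5, np.sqrt(0.75), 0.0, 0.0])  # cos(u, v) = 0.5
        values = np.empty((2, 2, 4))
        values[0, 0] = u
        values[1, 0] = v
        values[0, 1] = u
        values[1, 1] = v
        la, lb, _ = similarity_losses(values, CorrelationSpec(0.3, 0.1), grid)
        assert la == pytest.approx(0.2, abs=1e-12)
        assert lb == pytest.approx(0.2, abs=1e-12)

    def test_similarity_loss_scale_invariant(self, rng):
        grid = GridSpec(2, 4, 8)
        x = rng.standard_normal(grid.shape)
        spec = CorrelationSpec(0.6, 0.2)
        assert similarity_losses(x, spec, grid) == pytest.approx(
            similarity_losses(3.7 * x, spec, grid)
        )

    def test_zero_norm_series_rejected(self):
        grid = GridSpec(2, 2, 4)
        values = np.ones((2, 2, 4))
        values[0, 0] = 0.0
        with pytest.raises(ValueError):
            similarity_losses(values, CorrelationSpec(0.5, 0.5), grid)

    def test_distribution_loss_hand_values(self, rng):
        grid = GridSpec(2, 2, 6)
        zeros = np.zeros(grid.shape)
        l_a, l_b, l_eq = distribution_losses(zeros, grid=grid)
        assert l_a == pytest.approx(1.0 / 3.0)
        assert l_b == pytest.approx(1.0 / 3.0)
        assert l_eq == 0.0
        # mirrored halves equalize exactly
        half = rng.standard_normal((4, 2, 10))
        mirrored = np.concatenate([half, half], axis=1)
        _, _, l_eq = distribution_losses(mirrored, grid=GridSpec(4, 4, 10))
        assert l_eq == pytest.approx(0.0, abs=1e-15)

    def test_uniform_tensor_meets_distribution_targets(self, rng):
        grid = GridSpec(8, 16, 30)
        values = rng.uniform(-1.0, 1.0, size=grid.shape)
        l_a, l_b, l_eq = distribution_losses(values, grid=grid)
        assert l_a < 0.03  # Var U(-1,1) = 1/3, mean 0, up to sampling noise
        assert l_b < 0.03
        assert l_eq < 0.03

    def test_variance_expansion_hand_value_and_homogeneity(self, rng):
        grid = GridSpec(2, 2, 30)
        values = np.empty(grid.shape)
        values[0, 0] = 1.0
        values[1, 0] = -1.0
        values[0, 1] = 1.0
        values[1, 1] = -1.0
        l_va, l_vb = variance_expansion_loss(values, grid)
        assert l_va == pytest.approx(-60.0)  # one pair, L1 distance 2 * 30
        assert l_vb == pytest.approx(-60.0)
        x = rng.standard_normal((4, 4, 10))
        single = variance_expansion_loss(x, GridSpec(4, 4, 10))
        double = variance_expansion_loss(2 * x, GridSpec(4, 4, 10))
        assert double[0] == pytest.approx(2 * single[0])
        assert np.allclose(variance_expansion_loss(np.ones((4, 4, 10)), GridSpec(4, 4, 10)), 0.0)

    def test_total_loss_grouping_and_linearity(self):
        unit = dict(l_within_a=1.0, l_within_b=1.0, l_cross=1.0, l_dist_a=1.0,
                    l_dist_b=1.0, l_equalize=1.0, l_var_a=1.0, l_var_b=1.0)
        ones = LossWeights(alpha1=1, alpha2=1, alpha3=1, alpha4=1, alpha5=1)
        assert total_loss(weights=ones, **unit) == pytest.approx(8.0)
        zeros = dict(unit, **{k: 0.0 for k in unit})
        assert total_loss(weights=ones, **zeros) == 0.0
        breakdown = LossBreakdown(total=0.0, **unit)
        base = total_loss(breakdown, LossWeights(0.3, 0.5, 0.7, 0.2, 0.1))
        scaled = total_loss(breakdown, LossWeights(0.6, 1.0, 1.4, 0.4, 0.2))
        assert scaled == pytest.approx(2 * base)

    def test_one_hot_weights_pick_single_component(self, rng):
        grid = GridSpec(2, 4, 8)
        x = rng.standard_normal(grid.shape)
        spec = CorrelationSpec(0.6, 0.2)
        la, lb, lab = similarity_losses(x, spec, grid)
        w = LossWeights(alpha1=0, alpha2=1, alpha3=0, alpha4=0, alpha5=0)
        bd, _, _, _ = _loss_and_grad(x, spec, w, grid)
        assert bd.total == pytest.approx(lab)


class TestDecoderAndGradients:
    @pytest.mark.parametrize("balance", ["none", "dc", "dc_match"])
    def test_analytic_gradient_matches_finite_differences(self, balance, rng):
        grid = GridSpec(3, 4, 7)
        spec = CorrelationSpec(0.6, 0.2)
        weights = LossWeights(alpha1=1.0, alpha2=0.8, alpha3=0.5, alpha4=0.4, alpha5=0.05)
        cfg = GeneratorConfig(balance=balance)
        x = 0.2 * rng.standard_normal(grid.shape)  # small: global rescale inactive

        def loss_of(xx):
            f, _ = _decode_with_cache(cfg, xx, grid)
            bd, _, _, _ = _loss_and_grad(f, spec, weights, grid)
            return bd.total

        f, cache = _decode_with_cache(cfg, x, grid)
        assert cache["c"] == 1.0
        bd, gf, _, _ = _loss_and_grad(f, spec, weights, grid)
        g = _decode_backward(cfg, gf, cache)
        h = 1e-6
        for _ in range(12):
            idx = tuple(rng.integers(0, s) for s in grid.shape)
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (loss_of(xp) - loss_of(xm)) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_forward_bounded_and_deterministic(self, small_grid, rng):
        cfg = GeneratorConfig()
        params = rng.standard_normal(small_grid.shape)
        noise = rng.standard_normal(small_grid.shape)
        out1 = model_forward(cfg, params, noise, small_grid)
        out2 = model_forward(cfg, params, noise, small_grid)
        assert out1.shape == small_grid.shape
        assert np.max(np.abs(out1)) <= 1.0
        assert np.array_equal(out1, out2)

    def test_forward_shape_mismatch_rejected(self, small_grid, rng):
        with pytest.raises(ValueError):
            model_forward(GeneratorConfig(), rng.standard_normal((2, 2, 3)), grid=small_grid)

    def test_balancing_layer_zeroes_area_frame_means(self, small_grid, rng):
        out = model_forward(GeneratorConfig(balance="dc_match"),
                            rng.standard_normal(small_grid.shape), grid=small_grid)
        split = small_grid.area_split_col
        assert np.allclose(out[:, :split, :].mean(axis=(0, 1)), 0.0, atol=1e-12)
        assert np.allclose(out[:, split:, :].mean(axis=(0, 1)), 0.0, atol=1e-12)
        rms_a = np.sqrt((out[:, :split, :] ** 2).mean(axis=(0, 1)))
        rms_b = np.sqrt((out[:, split:, :] ** 2).mean(axis=(0, 1)))
        assert np.allclose(rms_a, rms_b, atol=1e-12)


class TestOptimization:
    def test_converges_on_small_grid(self, small_grid):
        spec = CorrelationSpec(0.8, 0.2)
        stim, diag = optimize_stimulus(spec, small_grid, GeneratorConfig(), seed=11)
        assert diag["converged"]
        assert stim.measured_within == pytest.approx(0.8, abs=0.02)
        assert stim.measured_cross == pytest.approx(0.2, abs=0.02)
        assert np.max(np.abs(stim.values)) <= 1.0

    def test_seeded_determinism(self, small_grid):
        spec = CorrelationSpec(0.7, 0.3)
        cfg = GeneratorConfig(max_steps=120)
        a, _ = optimize_stimulus(spec, small_grid, cfg, seed=7)
        b, _ = optimize_stimulus(spec, small_grid, cfg, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_null_spec_measures_matched_similarities(self, small_grid):
        null = CorrelationSpec(0.5, 0.5, is_null=True)
        stim, diag = optimize_stimulus(null, small_grid, GeneratorConfig(), seed=3)
        assert abs(diag["measured_within"] - diag["measured_cross"]) < 0.06

    def test_loss_decreases_over_training(self, small_grid):
        """Median total loss across seeds drops from start to finish."""
        spec = CorrelationSpec(0.6, 0.2)
        cfg = GeneratorConfig(max_steps=200)
        drops = []
        for seed in range(5):
            _, diag = optimize_stimulus(spec, small_grid, cfg, seed=seed)
            trace = diag["loss_trace"]
            drops.append(trace[0] - trace[-1])
        assert np.median(drops) > 0

    def test_generate_bank_reduced_counts(self, small_grid):
        design = ExperimentDesign(levels=(0.2, 0.6), n_variants=2)
        cfg = GeneratorConfig(max_steps=10)  # counting only
        bank = generate_bank(design, small_grid, cfg, seed=1)
        assert len(bank.stimuli) == 5  # 3 signal + 2 null specs
        assert len(bank) == 10
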