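"""Quantile scaling, candidate calls, and the channel-scale eigenproblem."""

import warnings

import numpy as np
import pytest

from deconvcall import (
    CHANNELS,
    IntensityBlock,
    RatioSystem,
    SimulationConfig,
    build_ratio_system,
    candidate_calls,
    estimate_channel_scales,
    quantile_scale,
    simulate_reads,
    solve_channel_scales,
)


class TestQuantileScale:
    def test_divides_each_channel_by_its_quantile(self):
        rng = np.random.default_rng(0)
        values = rng.random((100, 10, 4))
        values[..., 2] *= 2.0
        block = IntensityBlock(values)
        scaled, factors = quantile_scale(block, q=0.95)
        expected = np.quantile(values.reshape(-1, 4), 0.95, axis=0)
        np.testing.assert_allclose(factors, expected)
        np.testing.assert_allclose(scaled.values, values / factors)

    def test_identical_channels_stay_identical(self):
        col = np.random.default_rng(1).random((50, 5, 1))
        block = IntensityBlock(np.repeat(col, 4, axis=2))
        scaled, _ = quantile_scale(block)
        for ch in range(1, 4):
            np.testing.assert_allclose(scaled.values[..., ch], scaled.values[..., 0])

    def test_gain_bias_equalized_at_the_quantile(self):
        cfg = SimulationConfig(
            n_reads=1000, n_cycles=20, channel_gain=np.array([1.0, 2.0, 1.0, 1.0]), seed=3
        )
        block, _ = simulate_reads(cfg)
        scaled, _ = quantile_scale(block, q=0.95)
        quantiles = np.quantile(scaled.values.reshape(-1, 4), 0.95, axis=0)
        np.testing.assert_allclose(quantiles, 1.0, atol=1e-12)

    def test_all_zero_channel_is_an_error(self):
        values = np.ones((10, 5, 4))
        values[..., 3] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            quantile_scale(IntensityBlock(values))


class TestCandidateCalls:
    def test_argmax_and_tie_break(self):
        values = np.array([[[0.1, 0.9, 0.2, 0.1], [0.3, 0.3, 0.3, 0.3]]])
        calls = candidate_calls(IntensityBlock(values))
        assert CHANNELS[calls[0, 0]] == "C"
        assert CHANNELS[calls[0, 1]] == "A"  # tie -> first channel in order

    def test_noise_free_calls_equal_truth(self, ideal_sim):
        _, block, truth = ideal_sim
        calls = candidate_calls(block)
        assert (np.array(CHANNELS)[calls] == truth).all()


class TestRatioSystem:
    def test_single_relation_encoding(self):
        values = np.zeros((1, 2, 4))
        values[0, 0, 0] = 2.0  # A called at cycle 0
        values[0, 1, 1] = 1.0  # C called at cycle 1
        block = IntensityBlock(values)
        system = build_ratio_system(block, candidate_calls(block))
        assert system.M == 1
        np.testing.assert_allclose(system.R[0], [1.0, -2.0, 0.0, 0.0])
        assert system.D[0, 0] == 1 and system.D[1, 1] == 1

    def test_homopolymer_contributes_no_rows(self):
        values = np.zeros((1, 4, 4))
        values[0, :, 0] = 1.0  # AAAA
        block = IntensityBlock(values)
        system = build_ratio_system(block, candidate_calls(block))
        assert system.M == 0

    def test_relation_count_matches_direct_loop(self):
        cfg = SimulationConfig(n_reads=500, n_cycles=25, noise_sd=0.05, seed=7)
        block, _ = simulate_reads(cfg)
        calls = candidate_calls(block)
        system = build_ratio_system(block, calls)
        expected = 0
        for r in range(500):  # independent counting oracle
            for c in range(24):
                if calls[r, c] != calls[r, c + 1]:
                    b_i = block.values[r, c, calls[r, c]]
                    b_j = block.values[r, c + 1, calls[r, c + 1]]
                    if b_j != 0 and 1 / 50 <= b_i / b_j <= 50:
                        expected += 1
        assert system.M == expected


class TestSolveChannelScales:
    def test_balanced_system_gives_uniform_scales(self):
        # every channel pair observed at ratio 1, equal counts
        rows = []
        for i in range(4):
            for j in range(4):
                if i != j:
                    row = np.zeros(4)
                    row[i], row[j] = 1.0, -1.0
                    rows.append(row)
        system = RatioSystem(np.array(rows), np.diag([6.0] * 4), 12)
        scales, _, _ = solve_channel_scales(system)
        np.testing.assert_allclose(scales.x, 0.5, atol=1e-12)

    def test_recovers_channel_gains_within_one_percent(self):
        gains = np.array([1.0, 2.0, 1.0, 1.0])
        cfg = SimulationConfig(n_reads=1000, n_cycles=50, channel_gain=gains, seed=3)
        block, _ = simulate_reads(cfg)
        system = build_ratio_system(block, candidate_calls(block))
        scales, lam, residual = solve_channel_scales(system)
        recovered = scales.x / scales.x[0]
        assert np.linalg.norm(recovered - gains) / np.linalg.norm(gains) < 0.01
        assert residual <= 1e-8  # R^T R x = lambda D x holds

    def test_eigen_residual_small_on_noisy_data(self):
        cfg = SimulationConfig(n_reads=500, n_cycles=30, noise_sd=0.1, seed=9)
        block, _ = simulate_reads(cfg)
        system = build_ratio_system(block, candidate_calls(block))
        scales, lam, residual = solve_channel_scales(system)
        A = system.R.T @ system.R
        np.testing.assert_allclose(
            A @ scales.x, lam * (system.D @ scales.x), atol=1e-8
        )

    def test_generalized_equals_plain_when_counts_equal(self):
        rng = np.random.default_rng(12)
        rows = []
        # relations chosen so that every channel participates equally often
        pairs = [(0, 1), (1, 2), (2, 3), (3, 0)] * 6
        for i, j in pairs:
            row = np.zeros(4)
            row[i], row[j] = 1.0, -np.exp(rng.normal(0, 0.05))
            rows.append(row)
        R = np.array(rows)
        counts = np.bincount([p[0] for p in pairs] + [p[1] for p in pairs])
        assert len(set(counts)) == 1  # D is a multiple of the identity
        gen, _, _ = solve_channel_scales(RatioSystem(R, np.diag(counts.astype(float)), len(rows)))
        eigvals, eigvecs = np.linalg.eigh(R.T @ R)
        plain = np.abs(eigvecs[:, 0])
        np.testing.assert_allclose(gen.x, plain / np.linalg.norm(plain), atol=1e-10)

    def test_degenerate_system_falls_back_to_unit_scales(self):
        system = RatioSystem(np.array([[1.0, -1.0, 0, 0]]), np.diag([1.0, 1, 0, 0]), 1)
        with pytest.warns(UserWarning, match="degenerate"):
            scales, _, _ = solve_channel_scales(system)
        np.testing.assert_allclose(scales.x, 0.5)

    def test_scale_equivariance(self):
        # multiplying one input channel by a constant multiplies its
        # recovered relative intensity by the same constant
        cfg = SimulationConfig(n_reads=800, n_cycles=40, seed=15)
        block, _ = simulate_reads(cfg)
        factor = 1.7
        boosted = IntensityBlock(block.values * np.array([1, 1, factor, 1]))
        s_base, _, _ = solve_channel_scales(
            build_ratio_system(block, candidate_calls(block))
        )
        s_boost, _, _ = solve_channel_scales(
            build_ratio_system(boosted, candidate_calls(boosted))
        )
        expected = s_base.x * np.array([1, 1, factor, 1])
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(s_boost.x, expected, atol=1e-6)


def test_composite_scales_track_gains():
    gains = np.array([1.0, 2.0, 1.0, 1.0])
    cfg = SimulationConfig(n_reads=800, n_cycles=40, channel_gain=gains, seed=21)
    block, _ = simulate_reads(cfg)
    scales = estimate_channel_scales(block)
    recovered = scales.x / scales.x[0]
    np.testing.assert_allclose(recovered, gains, rtol=0.02)
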