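"""Iterative support detection: thresholding, the X-solve, and the loop."""

import itertools
import warnings

import numpy as np
import pytest

from deconvcall import (
    CHANNELS,
    ConvolutionKernel,
    ISDConfig,
    IntensityBlock,
    SimulationConfig,
    convolve_forward,
    hard_threshold,
    isd_deconvolve,
    make_windows,
    simulate_reads,
    solve_X_subproblem,
)
from deconvcall.isd import build_convolution_matrix
from tests.conftest import TRUE_CROSSTALK, TRUE_PHASING


def _kernels_for(n_cycles, width=20):
    windows = make_windows(n_cycles, width)
    kernels = [
        ConvolutionKernel(TRUE_CROSSTALK, TRUE_PHASING, i)
        for i in range(len(windows))
    ]
    return kernels, windows


def exhaustive_best_support(K_dense, b, n_cycles):
    """Independent oracle: enumerate all one-channel-per-cycle supports,
    score each by the residual of its support-constrained LS fit."""
    best, best_score = None, np.inf
    for supp in itertools.product(range(4), repeat=n_cycles):
        cols = [4 * c + ch for c, ch in enumerate(supp)]
        v, *_ = np.linalg.lstsq(K_dense[:, cols], b, rcond=None)
        score = np.sum((K_dense[:, cols] @ v - b) ** 2)
        if score < best_score:
            best, best_score = supp, score
    return best, best_score


class TestHardThreshold:
    def test_keeps_strongest_channel_value(self):
        aux = hard_threshold(np.array([[[0.1, 0.9, 0.2, 0.1]]]))
        np.testing.assert_allclose(aux.w, [[[0.0, 0.9, 0.0, 0.0]]])
        assert aux.support.sum() == 1

    def test_normalized_argmax_with_channel_scales(self):
        values = np.array([[[0.6, 0.5, 0.0, 0.0]]])
        scales = np.array([[2.0, 1.0, 1.0, 1.0]])
        aux = hard_threshold(values, scales)
        # normalized (0.3, 0.5, 0, 0) -> keep C, retaining its raw value
        np.testing.assert_allclose(aux.w, [[[0.0, 0.5, 0.0, 0.0]]])

    def test_negative_kept_values_clip_to_zero(self):
        aux = hard_threshold(np.array([[[-0.2, -0.1, -0.4, -0.3]]]))
        assert not aux.w.any()
        assert aux.support.sum() == 1

    def test_fixed_alpha_matches_entrywise_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, size=(4, 6, 4))
        alpha = 0.7
        aux = hard_threshold(values, alpha=alpha)
        for v, w in zip(values.reshape(-1), aux.w.reshape(-1)):
            assert w == (v if abs(v) > alpha else 0.0)


class TestSolveXSubproblem:
    def test_beta_zero_identity_kernel_returns_B(self):
        rng = np.random.default_rng(0)
        B = rng.random((4 * 10, 3))
        kernels, windows = [ConvolutionKernel.identity()], make_windows(10)
        K = build_convolution_matrix(kernels, windows, 10)
        X = solve_X_subproblem(B, K, np.zeros_like(B), 0.0, ISDConfig())
        np.testing.assert_allclose(X, B, atol=1e-6)

    def test_large_beta_pins_X_to_w(self):
        rng = np.random.default_rng(1)
        kernels, windows = _kernels_for(15)
        K = build_convolution_matrix(kernels, windows, 15)
        B = rng.random((60, 2))
        w = rng.random((60, 2))
        X = solve_X_subproblem(B, K, w, 1e9, ISDConfig())
        assert np.linalg.norm(X - w) / np.linalg.norm(w) < 1e-6

    def test_matches_dense_stacked_least_squares(self):
        # 1 read, 6 cycles: compare against an independent dense solve of
        # the stacked system [K; sqrt(beta) W^1/2] X = [B; sqrt(beta) W^1/2 w]
        rng = np.random.default_rng(2)
        kernels, windows = _kernels_for(6)
        K = build_convolution_matrix(kernels, windows, 6)
        B = rng.random((24, 1))
        w = rng.random((24, 1))
        beta = 3.7
        weights = rng.random(24) + 0.5
        cfg = ISDConfig(ridge=0.0)
        X = solve_X_subproblem(B, K, w, beta, cfg, penalty_weights=weights)
        stacked_A = np.vstack([K.toarray(), np.sqrt(beta * weights)[:, None] * np.eye(24)])
        stacked_b = np.vstack([B, np.sqrt(beta * weights)[:, None] * w])
        expected, *_ = np.linalg.lstsq(stacked_A, stacked_b, rcond=None)
        np.testing.assert_allclose(X, expected, atol=1e-8)

    def test_operator_matches_forward_convolution(self):
        rng = np.random.default_rng(3)
        X = rng.random((5, 37, 4))
        kernels, windows = _kernels_for(37, width=10)
        K = build_convolution_matrix(kernels, windows, 37)
        flat = (K @ X.reshape(5, -1).T).T.reshape(5, 37, 4)
        np.testing.assert_allclose(flat, convolve_forward(X, kernels, windows), atol=1e-12)


class TestISDDeconvolve:
    def test_noise_free_support_equals_truth(self, biased_noisefree):
        cfg, block, truth = biased_noisefree
        kernels, windows = cfg.kernels()
        res = isd_deconvolve(block, kernels, windows)
        called = np.array(CHANNELS)[res.latent.calls]
        assert (called == truth).all()
        assert res.converged

    def test_one_hot_input_with_identity_kernel_is_fixed_point(self):
        cfg = SimulationConfig(n_reads=50, n_cycles=20, seed=13)
        block, _ = simulate_reads(cfg)  # already one-hot
        windows = make_windows(20)
        res = isd_deconvolve(block, [ConvolutionKernel.identity()], windows)
        np.testing.assert_allclose(res.latent.values, block.values, atol=1e-6)
        assert res.converged

    def test_support_has_exactly_one_entry_per_cycle(self, biased_noisefree):
        cfg, block, _ = biased_noisefree
        kernels, windows = cfg.kernels()
        res = isd_deconvolve(block, kernels, windows)
        np.testing.assert_array_equal(res.latent.support.sum(axis=2), 1)
        assert (res.latent.values >= 0).all()

    def test_matches_exhaustive_enumeration_on_tiny_instances(self):
        kernels, windows = _kernels_for(5)
        K_dense = build_convolution_matrix(kernels, windows, 5).toarray()
        ties = 0
        for seed in range(8):
            cfg = SimulationConfig(
                n_reads=1,
                n_cycles=5,
                crosstalk_true=TRUE_CROSSTALK,
                phasing_true=TRUE_PHASING,
                noise_sd=0.05,
                seed=seed,
            )
            block, _ = simulate_reads(cfg)
            b = block.values.reshape(-1)
            best, best_score = exhaustive_best_support(K_dense, b, 5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = isd_deconvolve(block, kernels, windows)
            got = tuple(int(c) for c in res.latent.calls[0])
            if got != best:
                cols = [4 * c + ch for c, ch in enumerate(got)]
                v, *_ = np.linalg.lstsq(K_dense[:, cols], b, rcond=None)
                score = np.sum((K_dense[:, cols] @ v - b) ** 2)
                assert score == pytest.approx(best_score, abs=1e-9)
                ties += 1

    def test_objective_descends_within_each_iteration(self):
        cfg = SimulationConfig(
            n_reads=100,
            n_cycles=30,
            crosstalk_true=TRUE_CROSSTALK,
            phasing_true=TRUE_PHASING,
            noise_sd=0.1,
            channel_gain=np.array([1.0, 1.6, 0.8, 1.2]),
            seed=17,
        )
        block, _ = simulate_reads(cfg)
        kernels, windows = cfg.kernels()
        res = isd_deconvolve(block, kernels, windows)
        assert res.objective_trace
        for _, f_before, f_after_w, f_after_x in res.objective_trace:
            assert f_after_w <= f_before + 1e-9
            assert f_after_x <= f_after_w + 1e-9

    def test_returned_signal_is_sparser_than_input(self, biased_noisefree):
        cfg, block, _ = biased_noisefree
        kernels, windows = cfg.kernels()
        res = isd_deconvolve(block, kernels, windows)
        assert res.latent.l0_norm() <= np.count_nonzero(block.values)
        # noise-free blurred one-hot input: exactly one non-zero per cycle
        assert res.latent.l0_norm() == block.n_reads * block.n_cycles

    def test_idempotent_on_its_own_noise_free_output(self, biased_noisefree):
        cfg, block, _ = biased_noisefree
        kernels, windows = cfg.kernels()
        first = isd_deconvolve(block, kernels, windows)
        reblurred = convolve_forward(first.latent.values, kernels, windows)
        second = isd_deconvolve(IntensityBlock(reblurred), kernels, windows)
        np.testing.assert_array_equal(first.latent.support, second.latent.support)

    def test_fast_mode_is_single_pass(self, biased_noisefree):
        cfg, block, truth = biased_noisefree
        kernels, windows = cfg.kernels()
        res = isd_deconvolve(block, kernels, windows, fast=True)
        assert res.n_iterations == 1
        called = np.array(CHANNELS)[res.latent.calls]
        assert (called == truth).all()  # noise-free: even one pass is exact


def test_strictly_increasing_beta_schedule_enforced():
    with pytest.raises(ValueError, match="increasing"):
        ISDConfig(beta_schedule=(1.0, 1.0, 2.0))
    with pytest.raises(ValueError):
        ISDConfig(beta_schedule=())
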