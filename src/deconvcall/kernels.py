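"""Kernel estimation and the blind-deconvolution training loop.

The kernel is estimated in two steps given a latent-signal estimate:

1. Cross-talk: using only the first four cycles — where phasing has had
   little chance to act — regress observed quadruplets on latent
   quadruplets to get the 4x4 channel-mixing matrix.  On the first pass
   the phasing taps are fixed to the lag-0 spike; on later passes of the
   blind loop the current phasing profile is applied to the latent signal
   first, so neighbour-cycle leakage does not bias the off-diagonals.
2. Phasing: with cross-talk fixed, fit the (2L+1) scalar lag weights per
   window by least squares; the phasing profile is assumed identical
   across channels.

Blind deconvolution alternates (i) ISD deconvolution with the current
kernels and (ii) the two-step kernel re-estimation from the thresholded
latent signal, until the kernels stop changing.  The inherent scale
ambiguity (k*c, X/c fit equally well) is fixed by normalizing the
cross-talk diagonal to 1 and each phasing profile to sum 1; residual
scale is absorbed into X.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    ChannelScales,
    ConvolutionKernel,
    IntensityBlock,
    LatentSignal,
    N_CHANNELS,
    Window,
    make_windows,
)
from .isd import ISDConfig, ISDResult, isd_deconvolve


class RankDeficiencyError(ValueError):
    """Training data cannot identify the requested kernel parameters."""


@dataclass
class BlindConfig:
    """Configuration of the blind-deconvolution training loop."""

    window_size: int = 20
    n_lags: int = 1
    isd: ISDConfig = field(default_factory=ISDConfig)
    max_outer_iters: int = 25
    kernel_tol: float = 1e-6
    quantile: float = 0.95

    def __post_init__(self) -> None:
        if not 1 <= self.n_lags <= 3:
            raise ValueError("n_lags must be between 1 and 3")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass
class BlindResult:
    kernels: list[ConvolutionKernel]
    windows: list[Window]
    latent: LatentSignal
    deconvolved: np.ndarray
    scales: list[ChannelScales]
    objective_traces: list[list[tuple[int, float, float, float]]]
    n_outer_iterations: int
    converged: bool


def estimate_crosstalk(
    block: IntensityBlock | np.ndarray,
    X: LatentSignal | np.ndarray,
    n_cycles_used: int = 4,
    phasing: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares 4x4 cross-talk matrix from the first few cycles.

    Minimizes sum ||C x_c - b_c||^2 over cycles 0..n_cycles_used-1 of all
    reads.  With ``phasing=None`` the taps are fixed to the lag-0 spike;
    given a profile, the latent signal is phasing-convolved first so that
    known neighbour-cycle leakage is accounted for.  Negative entries are
    clipped to 0 and columns scaled so the diagonal is 1.
    """
    B = block.values if isinstance(block, IntensityBlock) else np.asarray(block)
    Xv = X.values if isinstance(X, LatentSignal) else np.asarray(X)
    if B.shape[1] < n_cycles_used:
        raise ValueError(f"need at least {n_cycles_used} cycles")

    present = (Xv[:, :n_cycles_used, :] != 0).any(axis=(0, 1))
    if not present.all():
        missing = [("A", "C", "G", "T")[i] for i in range(4) if not present[i]]
        raise RankDeficiencyError(
            f"base(s) {missing} never occur in the first {n_cycles_used} "
            "cycles of the training reads; use a larger training sample"
        )
    if phasing is not None:
        L = (len(phasing) - 1) // 2
        conv = np.zeros_like(Xv[:, :n_cycles_used, :])
        for t in range(-L, L + 1):
            for c in range(n_cycles_used):
                src = c - t
                if 0 <= src < Xv.shape[1]:
                    conv[:, c, :] += phasing[t + L] * Xv[:, src, :]
        Xmat = conv.reshape(-1, N_CHANNELS)
    else:
        Xmat = Xv[:, :n_cycles_used, :].reshape(-1, N_CHANNELS)
    Bmat = B[:, :n_cycles_used, :].reshape(-1, N_CHANNELS)

    coef, *_ = np.linalg.lstsq(Xmat, Bmat, rcond=None)
    C = coef.T  # rows: observed channel, cols: source channel
    C = np.clip(C, 0.0, None)
    diag = np.diag(C)
    if (diag <= 0).any():
        raise RankDeficiencyError(
            "estimated cross-talk has a non-positive diagonal entry"
        )
    return C / diag[None, :]


def estimate_phasing(
    block: IntensityBlock | np.ndarray,
    X: LatentSignal | np.ndarray,
    crosstalk: np.ndarray,
    window: Window,
    n_lags: int = 1,
) -> np.ndarray:
    """Least-squares phasing profile for one window, cross-talk fixed.

    Minimizes ||KX - B||^2 over the 2L+1 lag weights restricted to the
    window's cycles; weights are clipped at 0 and normalized to sum 1.
    If the window holds fewer than 2L+1 cycles, L shrinks to fit.
    """
    B = block.values if isinstance(block, IntensityBlock) else np.asarray(block)
    Xv = X.values if isinstance(X, LatentSignal) else np.asarray(X)
    n_cycles = B.shape[1]
    if window.end_cycle > n_cycles:
        raise ValueError("window exceeds cycle range")
    L = n_lags
    while 2 * L + 1 > window.width and L > 0:
        L -= 1

    mixed = np.einsum("ij,rcj->rci", crosstalk, Xv)
    cyc = window.cycles()
    target = B[:, cyc, :].reshape(-1)
    cols = []
    for t in range(-L, L + 1):
        src = cyc - t
        ok = (src >= 0) & (src < n_cycles)
        col = np.zeros((B.shape[0], window.width, N_CHANNELS))
        col[:, ok, :] = mixed[:, src[ok], :]
        cols.append(col.reshape(-1))
    G = np.column_stack(cols)
    p, *_ = np.linalg.lstsq(G, target, rcond=None)
    p = np.clip(p, 0.0, None)
    total = p.sum()
    if total <= 0:
        raise RankDeficiencyError("phasing fit collapsed to all-zero weights")
    p = p / total
    if L < n_lags:  # pad back to the requested lag range
        pad = n_lags - L
        p = np.concatenate([np.zeros(pad), p, np.zeros(pad)])
    return p


def blind_deconvolve(
    block: IntensityBlock,
    cfg: BlindConfig | None = None,
) -> BlindResult:
    """Jointly estimate kernels and latent signal from a training block.

    Alternates ISD deconvolution (kernels fixed) with two-step kernel
    re-estimation (latent signal fixed), recomputing channel scales every
    iteration, until the relative Frobenius change of the stacked kernel
    parameters falls below ``cfg.kernel_tol``.
    """
    cfg = cfg or BlindConfig()
    windows = make_windows(block.n_cycles, cfg.window_size)
    kernels = [
        ConvolutionKernel.identity(cfg.n_lags, i) for i in range(len(windows))
    ]

    def pack(ks):
        return np.concatenate(
            [np.concatenate([k.crosstalk.ravel(), k.phasing]) for k in ks]
        )

    traces = []
    res: ISDResult | None = None
    converged = False
    outer = 0
    for outer in range(1, cfg.max_outer_iters + 1):
        res = isd_deconvolve(
            block,
            kernels,
            windows,
            cfg.isd,
            recompute_scales=True,
            quantile=cfg.quantile,
        )
        traces.append(res.objective_trace)
        prev_phasing = kernels[0].phasing if outer > 1 else None
        crosstalk = estimate_crosstalk(block, res.latent, phasing=prev_phasing)
        new_kernels = [
            ConvolutionKernel(
                crosstalk,
                estimate_phasing(block, res.latent, crosstalk, win, cfg.n_lags),
                i,
            )
            for i, win in enumerate(windows)
        ]
        old, new = pack(kernels), pack(new_kernels)
        change = np.linalg.norm(new - old) / max(np.linalg.norm(old), 1e-12)
        kernels = new_kernels
        if change < cfg.kernel_tol:
            converged = True
            break

    # final deconvolution under the converged kernels
    res = isd_deconvolve(
        block,
        kernels,
        windows,
        cfg.isd,
        recompute_scales=True,
        quantile=cfg.quantile,
    )
    return BlindResult(
        kernels=kernels,
        windows=windows,
        latent=res.latent,
        deconvolved=res.deconvolved,
        scales=res.scales,
        objective_traces=traces + [res.objective_trace],
        n_outer_iterations=outer,
        converged=converged,
    )
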