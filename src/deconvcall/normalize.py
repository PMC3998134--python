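"""Channel intensity normalization.

Per-channel intensity levels differ (dye brightness, optics), and the
number of calls per channel differs, so relative channel scales cannot be
read off directly.  Instead of normalizing individual reads, the relative
intensity x of the four channels is estimated jointly from *ratios of
successive, differing candidate calls* across many reads: each pair of
neighbouring cycles called as different bases (i at cycle c with intensity
b_i, j at cycle c+1 with intensity b_j) yields one homogeneous relation

    x_i - r_k x_j = 0,        r_k = b_i / b_j ,

stacked into R x = 0.  Minimizing ||Rx||^2 subject to a norm constraint is
a Rayleigh-quotient problem; because channels are called with different
frequencies the quotient is normalized by the diagonal call-count matrix
D, giving the generalized eigenproblem

    R^T R x = lambda D x

whose eigenvector of smallest eigenvalue (sign-fixed positive, unit norm)
is the vector of relative channel intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import ChannelScales, IntensityBlock, N_CHANNELS, Window

#: Relations with observed intensity ratio outside this range are dropped
#: as numerically untrustworthy.
RATIO_BOUNDS = (1.0 / 50.0, 50.0)


@dataclass
class RatioSystem:
    """Stacked pairwise-ratio relations R (M x 4) and call-count matrix D."""

    R: np.ndarray
    D: np.ndarray
    M: int

    def __post_init__(self) -> None:
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        self.D = np.asarray(self.D, dtype=float)
        if self.R.shape[1] != N_CHANNELS or self.D.shape != (4, 4):
            raise ValueError("R must be M x 4 and D 4 x 4")


def quantile_scale(
    block: IntensityBlock,
    q: float = 0.95,
    window: Window | None = None,
) -> tuple[IntensityBlock, np.ndarray]:
    """Divide each channel by its q-quantile over all reads and cycles.

    Restricted to ``window`` cycles when given.  Returns the scaled block
    and the 4-vector of scale factors.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    values = block.values
    if window is not None:
        values = values[:, window.start_cycle : window.end_cycle, :]
    factors = np.quantile(values.reshape(-1, N_CHANNELS), q, axis=0)
    if (factors <= 0).any():
        bad = [i for i in range(N_CHANNELS) if factors[i] <= 0]
        raise ValueError(
            f"degenerate channel(s) {bad}: non-positive {q:.0%} quantile"
        )
    return IntensityBlock(values / factors, block.read_ids), factors


def candidate_calls(block: IntensityBlock) -> np.ndarray:
    """Strongest channel per (read, cycle); ties go to the earlier channel
    in A < C < G < T order (argmax keeps the first maximum)."""
    return block.values.argmax(axis=2)


def build_ratio_system(
    block: IntensityBlock,
    calls: np.ndarray,
    window: Window | None = None,
) -> RatioSystem:
    """Collect one relation per successive pair of differing calls.

    For cycles (c, c+1) within a read (both inside ``window`` if given)
    whose candidate calls are different channels i != j, emit the row
    (+1 at i, -r at j) with r the ratio of the observed called-channel
    intensities; D counts channel participations.
    """
    calls = np.asarray(calls)
    if calls.shape != block.values.shape[:2]:
        raise ValueError("calls shape does not match block")
    c0, c1 = 0, block.n_cycles
    if window is not None:
        c0, c1 = window.start_cycle, window.end_cycle

    left = calls[:, c0 : c1 - 1]
    right = calls[:, c0 + 1 : c1]
    reads, cyc = np.nonzero(left != right)
    i = left[reads, cyc]
    j = right[reads, cyc]
    b_i = block.values[reads, c0 + cyc, i]
    b_j = block.values[reads, c0 + cyc + 1, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = b_i / b_j
    lo, hi = RATIO_BOUNDS
    ok = np.isfinite(r) & (r >= lo) & (r <= hi)
    i, j, r = i[ok], j[ok], r[ok]

    M = i.size
    R = np.zeros((M, N_CHANNELS))
    rows = np.arange(M)
    R[rows, i] = 1.0
    R[rows, j] = -r
    counts = np.bincount(i, minlength=4) + np.bincount(j, minlength=4)
    return RatioSystem(R=R, D=np.diag(counts.astype(float)), M=M)


def solve_channel_scales(
    system: RatioSystem,
) -> tuple[ChannelScales, float, float]:
    """Smallest-eigenvalue solution of ``R^T R x = lambda D x``.

    Returns (scales, eigenvalue, residual) with ``residual =
    ||R^T R x - lambda D x||``.  Degenerate systems (too few relations, a
    channel never observed, an indefinite D) fall back: first to the plain
    eigenproblem of R^T R, then to unit scales, each with a warning.
    """
    if system.M < N_CHANNELS or (np.diag(system.D) <= 0).any():
        warnings.warn(
            "ratio system is degenerate (fewer than 4 relations or a "
            "channel never observed); falling back",
            stacklevel=2,
        )
        if system.M >= N_CHANNELS:
            return _plain_eigen(system)
        return ChannelScales.unit(), float("nan"), float("nan")

    A = system.R.T @ system.R
    try:
        eigvals, eigvecs = scipy.linalg.eigh(A, system.D)
    except scipy.linalg.LinAlgError:
        warnings.warn(
            "generalized eigenproblem failed; using plain eigenproblem",
            stacklevel=2,
        )
        return _plain_eigen(system)
    return _finish(A, system.D, eigvals, eigvecs, system)


def _plain_eigen(system: RatioSystem):
    A = system.R.T @ system.R
    eigvals, eigvecs = scipy.linalg.eigh(A)
    return _finish(A, np.eye(N_CHANNELS), eigvals, eigvecs, system)


def _finish(A, D, eigvals, eigvecs, system):
    x = eigvecs[:, 0]
    lam = float(eigvals[0])
    # sign-fix to positive; a mixed-sign eigenvector means the relations
    # are inconsistent enough that no positive scale vector fits
    if (x <= 0).all():
        x = -x
    if (x <= 0).any():
        warnings.warn(
            "smallest eigenvector is not single-signed; using unit scales",
            stacklevel=3,
        )
        return ChannelScales.unit(), lam, float("nan")
    x = x / np.linalg.norm(x)
    residual = float(np.linalg.norm(A @ x - lam * (D @ x)))
    return ChannelScales(x), lam, residual


def estimate_channel_scales(
    block: IntensityBlock,
    q: float = 0.95,
    window: Window | None = None,
    min_calls_per_channel: int = 5,
) -> ChannelScales:
    """Composite per-channel scale for one window: quantile factor times
    the ratio-system eigenvector, unit-normalized.

    This is the working normalization used during support detection: the
    quantile factor captures the bulk of the channel amplitude difference,
    the eigenvector the residual relative intensity of successive calls.
    With too little data per channel (fewer than ``min_calls_per_channel``
    candidate calls for any channel, or fewer than 2 x that many
    relations) neither component is trustworthy and unit scales are
    returned.
    """
    scaled, factors = quantile_scale(block, q=q, window=window)
    calls = candidate_calls(scaled)
    counts = np.bincount(calls.reshape(-1), minlength=N_CHANNELS)
    if (counts < min_calls_per_channel).any():
        return ChannelScales.unit()
    sub = Window(0, scaled.n_cycles) if window is not None else None
    system = build_ratio_system(scaled, calls, sub)
    if system.M < 2 * min_calls_per_channel:
        return ChannelScales.unit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scales, _, _ = solve_channel_scales(system)
    return ChannelScales(factors * scales.x)
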