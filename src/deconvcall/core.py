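"""Core domain types and the forward convolution model.

The observed fluorescence signal ``B`` of a sequencing-by-synthesis run is
modelled as the convolution of a latent sparse incorporation signal ``X``
with a kernel describing cross-talk between dye channels (instantaneous,
a 4x4 mixing matrix) and phasing/pre-phasing (leakage of signal into
neighbouring cycles), plus noise:

    B = K X + N

The kernel is separable: at cycle lag ``t`` it equals ``phasing[t] *
crosstalk``, with the phasing profile shared across channels.  Kernels are
held constant within non-overlapping windows of cycles (nominal width 20).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed channel order used everywhere: column 0 is A, 1 is C, 2 is G, 3 is T.
CHANNELS = ("A", "C", "G", "T")
N_CHANNELS = 4

BASE_TO_INDEX = {b: i for i, b in enumerate(CHANNELS)}


class ConfigurationError(ValueError):
    """Inconsistent configuration (e.g. window/kernel count mismatch)."""


@dataclass
class IntensityBlock:
    """Per-cluster fluorescence intensities: ``values[read, cycle, channel]``.

    Negative values are permitted on input (background-subtracted sequencer
    output can dip below zero); ``has_negative`` flags their presence.
    """

    values: np.ndarray
    read_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != N_CHANNELS:
            raise ValueError(
                f"intensity values must be [n_reads x n_cycles x 4], got shape "
                f"{self.values.shape}"
            )
        if self.values.shape[1] < 1:
            raise ValueError("need at least one cycle")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity values must be finite")
        if not self.read_ids:
            self.read_ids = [f"read_{i}" for i in range(self.values.shape[0])]
        if len(self.read_ids) != self.values.shape[0]:
            raise ValueError("read_ids length does not match number of reads")

    @property
    def n_reads(self) -> int:
        return self.values.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.values.shape[1]

    @property
    def has_negative(self) -> bool:
        return bool((self.values < 0).any())

    def subset(self, index: np.ndarray) -> "IntensityBlock":
        index = np.asarray(index)
        return IntensityBlock(
            self.values[index], [self.read_ids[i] for i in index]
        )


@dataclass
class ConvolutionKernel:
    """Separable kernel for one window: ``k(t) = phasing[t] * crosstalk``.

    ``phasing`` has odd length ``2L+1`` covering lags ``-L..+L`` (index ``L``
    is lag 0, the in-cycle signal; earlier indices are pre-phasing, later
    indices phasing).
    """

    crosstalk: np.ndarray
    phasing: np.ndarray
    window_index: int = 0

    def __post_init__(self) -> None:
        self.crosstalk = np.asarray(self.crosstalk, dtype=float)
        self.phasing = np.asarray(self.phasing, dtype=float)
        if self.crosstalk.shape != (N_CHANNELS, N_CHANNELS):
            raise ValueError("crosstalk must be 4x4")
        if (self.crosstalk < 0).any():
            raise ValueError("crosstalk entries must be non-negative")
        if (np.diag(self.crosstalk) <= 0).any():
            raise ValueError("crosstalk diagonal must be strictly positive")
        if self.phasing.ndim != 1 or self.phasing.size % 2 != 1:
            raise ValueError("phasing profile must be 1-D with odd length")
        if (self.phasing < 0).any():
            raise ValueError("phasing weights must be non-negative")
        L = self.n_lags
        if self.phasing[L] < self.phasing.max():
            raise ValueError("the lag-0 phasing weight must be the largest")

    @property
    def n_lags(self) -> int:
        """Half-width L of the phasing profile (lags -L..+L)."""
        return (self.phasing.size - 1) // 2

    @classmethod
    def identity(cls, n_lags: int = 1, window_index: int = 0) -> "ConvolutionKernel":
        """The unbiased instrument: no cross-talk, all weight at lag 0."""
        phasing = np.zeros(2 * n_lags + 1)
        phasing[n_lags] = 1.0
        return cls(np.eye(N_CHANNELS), phasing, window_index)


@dataclass
class LatentSignal:
    """Deconvolved sparse signal ``X`` and its detected support.

    On the support values are >= 0; off the support they are exactly 0.
    After convergence of support detection there is exactly one support
    entry per (read, cycle) — the base-call.
    """

    values: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support = np.asarray(self.support, dtype=bool)
        if self.values.shape != self.support.shape:
            raise ValueError("values and support shapes differ")
        if (self.values[~self.support] != 0).any():
            raise ValueError("values must be exactly 0 off the support")
        if (self.values[self.support] < 0).any():
            raise ValueError("values must be >= 0 on the support")

    @property
    def calls(self) -> np.ndarray:
        """Called channel index per (read, cycle): argmax of the support."""
        return self.support.argmax(axis=2)

    def l0_norm(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass
class ChannelScales:
    """Relative per-channel intensities (unit-norm, strictly positive)."""

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (N_CHANNELS,):
            raise ValueError("channel scales must be a 4-vector")
        if (self.x <= 0).any():
            raise ValueError("channel scales must be strictly positive")
        self.x = self.x / np.linalg.norm(self.x)

    @classmethod
    def unit(cls) -> "ChannelScales":
        return cls(np.ones(N_CHANNELS))


@dataclass
class BaseCallSet:
    """Called bases with raw quality ratios and (optionally) PHRED scores."""

    bases: np.ndarray  # [n_reads x n_cycles] of single characters
    raw_quality: np.ndarray  # in [0.5, 1.0]
    read_ids: list[str]
    phred: np.ndarray | None = None  # integer PHRED after calibration

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype="U1")
        self.raw_quality = np.asarray(self.raw_quality, dtype=float)
        if self.bases.shape != self.raw_quality.shape:
            raise ValueError("bases and raw_quality shapes differ")
        if ((self.raw_quality < 0.5) | (self.raw_quality > 1.0)).any():
            raise ValueError("raw quality must lie in [0.5, 1.0]")
        if self.phred is not None:
            self.phred = np.asarray(self.phred, dtype=int)
            if self.phred.shape != self.bases.shape:
                raise ValueError("phred shape differs from bases")
            if (self.phred < 0).any():
                raise ValueError("phred scores must be >= 0")

    @property
    def n_reads(self) -> int:
        return self.bases.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.bases.shape[1]

    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.bases]


@dataclass(frozen=True)
class Window:
    """Half-open cycle range [start_cycle, end_cycle), 0-based."""

    start_cycle: int
    end_cycle: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_cycle < self.end_cycle:
            raise ValueError("window must satisfy 0 <= start < end")

    @property
    def width(self) -> int:
        return self.end_cycle - self.start_cycle

    def cycles(self) -> np.ndarray:
        return np.arange(self.start_cycle, self.end_cycle)


def make_windows(n_cycles: int, width: int = 20) -> list[Window]:
    """Partition cycles into contiguous non-overlapping windows.

    The last window may be shorter than ``width`` when ``n_cycles`` is not a
    multiple of it.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if width < 1:
        raise ValueError("window width must be >= 1")
    return [
        Window(s, min(s + width, n_cycles)) for s in range(0, n_cycles, width)
    ]


def window_of_cycle(windows: list[Window], cycle: int) -> int:
    for i, w in enumerate(windows):
        if w.start_cycle <= cycle < w.end_cycle:
            return i
    raise ValueError(f"cycle {cycle} not covered by windows")


def convolve_forward(
    X: np.ndarray,
    kernels: list[ConvolutionKernel],
    windows: list[Window],
) -> np.ndarray:
    """Apply the forward model ``B = KX`` to a latent signal tensor.

    For a cycle ``c`` in window ``w`` the output quadruplet is

        B[:, c, :] = sum_t phasing_w[t] * crosstalk @ X[:, c - t, :]

    with lags outside the read truncated (zero-padded boundary).  The
    operation is deterministic and linear in ``X``.

    Parameters
    ----------
    X : array [n_reads x n_cycles x 4]
    kernels : one ConvolutionKernel per window
    windows : contiguous cycle windows covering all of X
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[2] != N_CHANNELS:
        raise ValueError("X must be [n_reads x n_cycles x 4]")
    if len(kernels) != len(windows):
        raise ConfigurationError(
            f"{len(kernels)} kernels supplied for {len(windows)} windows"
        )
    n_cycles = X.shape[1]
    B = np.zeros_like(X)
    for kern, win in zip(kernels, windows):
        L = kern.n_lags
        cyc = win.cycles()
        mixed = None
        for t in range(-L, L + 1):
            weight = kern.phasing[t + L]
            if weight == 0.0:
                continue
            src = cyc - t
            ok = (src >= 0) & (src < n_cycles)
            if not ok.any():
                continue
            if mixed is None:
                # crosstalk mixing is lag-independent; apply once per window
                mixed = np.einsum("ij,rcj->rci", kern.crosstalk, X)
            B[:, cyc[ok], :] += weight * mixed[:, src[ok], :]
    return B
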