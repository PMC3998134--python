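"""Synthetic sequencing-by-synthesis intensity generator.

Emulates the four intensity biases of Illumina-style instruments —
cross-talk between dye channels, phasing/pre-phasing leakage across
cycles, geometric signal decay, and additive background noise whose
standard deviation may grow linearly with cycle — on top of a one-hot
latent incorporation signal, so that every stage of the caller can be
tested against known ground truth.

Defaults describe the *ideal* instrument (identity cross-talk, no
phasing, no decay, no noise, unit gains); biased conditions are opted
into explicitly.  The generator is a test harness for the inverse
problem, not a calibrated model of any particular sequencer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .core import (
    BASE_TO_INDEX,
    CHANNELS,
    N_CHANNELS,
    ConvolutionKernel,
    IntensityBlock,
    make_windows,
    convolve_forward,
)


def dye_crosstalk(leak_ac: float = 0.25, leak_gt: float = 0.2) -> np.ndarray:
    """Diagonally dominant cross-talk preset with leakage within the
    spectrally close (A, C) and (G, T) dye pairs, plus mild cross-pair
    bleed, mimicking known four-dye chemistry."""
    C = np.eye(N_CHANNELS)
    a, c, g, t = range(4)
    C[a, c] = leak_ac
    C[c, a] = leak_ac * 0.6
    C[g, t] = leak_gt
    C[t, g] = leak_gt * 0.7
    C[a, g] = 0.05
    C[t, c] = 0.05
    return C


@dataclass
class SimulationConfig:
    """Parameters of the forward model used to generate intensities.

    decay_rate is the per-cycle multiplicative signal decay in (0, 1];
    noise_sd the additive Gaussian background sd at cycle 0, growing
    linearly by ``noise_slope`` per cycle; channel_gain per-channel
    amplitude biases.
    """

    n_reads: int = 100
    n_cycles: int = 50
    crosstalk_true: np.ndarray = field(
        default_factory=lambda: np.eye(N_CHANNELS)
    )
    phasing_true: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    decay_rate: float = 1.0
    noise_sd: float = 0.0
    noise_slope: float = 0.0
    channel_gain: np.ndarray = field(
        default_factory=lambda: np.ones(N_CHANNELS)
    )
    window_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        self.crosstalk_true = np.asarray(self.crosstalk_true, dtype=float)
        self.phasing_true = np.asarray(self.phasing_true, dtype=float)
        self.channel_gain = np.asarray(self.channel_gain, dtype=float)
        if not 0.0 < self.decay_rate <= 1.0:
            raise ValueError("decay_rate must be in (0, 1]")
        if self.noise_sd < 0 or self.noise_slope < 0:
            raise ValueError("noise parameters must be >= 0")
        if (self.channel_gain <= 0).any():
            raise ValueError("channel_gain must be strictly positive")

    def kernels(self) -> tuple[list[ConvolutionKernel], list]:
        """The true per-window kernels (identical across windows)."""
        phasing = self.phasing_true
        if phasing.size == 1:  # promote to lag form -1..+1
            phasing = np.array([0.0, float(phasing[0]), 0.0])
        windows = make_windows(self.n_cycles, self.window_size)
        kernels = [
            ConvolutionKernel(self.crosstalk_true, phasing, i)
            for i in range(len(windows))
        ]
        return kernels, windows


def _random_sequences(rng: np.random.Generator, n_reads: int, n_cycles: int):
    idx = rng.integers(0, N_CHANNELS, size=(n_reads, n_cycles))
    return idx


def _encode(sequences: list[str], n_cycles: int) -> np.ndarray:
    idx = np.empty((len(sequences), n_cycles), dtype=int)
    for i, seq in enumerate(sequences):
        if len(seq) != n_cycles:
            raise ValueError(
                f"sequence {i} has length {len(seq)}, expected {n_cycles}"
            )
        try:
            idx[i] = [BASE_TO_INDEX[b] for b in seq.upper()]
        except KeyError as exc:
            raise ValueError(f"non-ACGT base in sequence {i}: {exc}") from exc
    return idx


def simulate_reads(
    cfg: SimulationConfig, sequences: list[str] | None = None
) -> tuple[IntensityBlock, np.ndarray]:
    """Generate an intensity block plus its ground-truth base matrix.

    The latent signal is one-hot in the true base, scaled by the channel
    gain and by ``decay_rate**cycle``, convolved with the true kernel and
    perturbed by Gaussian noise of per-cycle sd
    ``noise_sd * (1 + noise_slope * cycle)``.  Fully reproducible from
    ``cfg.seed``.

    Returns
    -------
    (IntensityBlock, truth) where truth is an [n_reads x n_cycles] array
    of base characters.
    """
    rng = np.random.default_rng(cfg.seed)
    if sequences is None:
        base_idx = _random_sequences(rng, cfg.n_reads, cfg.n_cycles)
    else:
        if len(sequences) != cfg.n_reads:
            raise ValueError("number of sequences must equal cfg.n_reads")
        base_idx = _encode(sequences, cfg.n_cycles)

    n_reads, n_cycles = base_idx.shape
    X = np.zeros((n_reads, n_cycles, N_CHANNELS))
    reads = np.arange(n_reads)[:, None]
    cycles = np.arange(n_cycles)[None, :]
    amplitude = cfg.channel_gain[base_idx] * cfg.decay_rate ** cycles
    X[reads, cycles, base_idx] = amplitude

    kernels, windows = cfg.kernels()
    B = convolve_forward(X, kernels, windows)

    if cfg.noise_sd > 0 or cfg.noise_slope > 0:
        sd = cfg.noise_sd * (1.0 + cfg.noise_slope * np.arange(n_cycles))
        B = B + rng.standard_normal(B.shape) * sd[None, :, None]

    truth = np.array(CHANNELS, dtype="U1")[base_idx]
    block = IntensityBlock(B, [f"sim_{i}" for i in range(n_reads)])
    return block, truth


def simulate_from_fasta(
    path, cfg: SimulationConfig
) -> tuple[IntensityBlock, np.ndarray]:
    """Simulate reads whose true sequences are random substrings of the
    records in a FASTA file.

    Records shorter than ``cfg.n_cycles`` are an error; longer records
    contribute uniform-random windows of exactly ``n_cycles`` bases.
    Substring choice is reproducible from ``cfg.seed``.
    """
    records = [str(r.seq) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    for i, seq in enumerate(records):
        if len(seq) < cfg.n_cycles:
            raise ValueError(
                f"FASTA record {i} has length {len(seq)} < n_cycles "
                f"({cfg.n_cycles})"
            )
    rng = np.random.default_rng(cfg.seed)
    rec_idx = rng.integers(0, len(records), size=cfg.n_reads)
    sequences = []
    for ri in rec_idx:
        start = rng.integers(0, len(records[ri]) - cfg.n_cycles + 1)
        sequences.append(records[ri][start : start + cfg.n_cycles])
    return simulate_reads(cfg, sequences)
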