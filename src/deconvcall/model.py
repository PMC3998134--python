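"""Model/results interface for base-calling by blind deconvolution.

``BaseCallingModel`` wraps an intensity block; ``fit`` trains the
instrument model (per-window convolution kernels and channel scales) by
blind deconvolution on a random subset of reads and returns a
``BaseCallingResults`` carrying the estimates, convergence diagnostics
and a ``summary()`` table.  ``BaseCallingResults.call`` then base-calls
any compatible intensity block with the trained kernels, in the full
iterative mode or the single-pass fast mode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BaseCallSet,
    CHANNELS,
    ChannelScales,
    ConvolutionKernel,
    IntensityBlock,
    Window,
)
from .isd import ISDConfig, isd_deconvolve
from .kernels import BlindConfig, blind_deconvolve
from .quality import provisional_phred, raw_quality


class BaseCallingModel:
    """Blind-deconvolution base-caller for one intensity dataset.

    Parameters
    ----------
    block : IntensityBlock
        Observed intensities, [n_reads x n_cycles x 4] in A,C,G,T order.
    window_size : int
        Cycles per kernel window (kernel held constant within a window).
    n_lags : int
        Phasing half-width L; the profile covers lags -L..+L.
    """

    def __init__(
        self,
        block: IntensityBlock,
        window_size: int = 20,
        n_lags: int = 1,
        quantile: float = 0.95,
        isd_config: ISDConfig | None = None,
    ):
        self.block = block
        self.config = BlindConfig(
            window_size=window_size,
            n_lags=n_lags,
            isd=isd_config or ISDConfig(),
            quantile=quantile,
        )

    @classmethod
    def from_table(cls, path, dialect: str = "plain", **kwargs):
        from .io import read_intensity_table

        return cls(read_intensity_table(path, dialect), **kwargs)

    def fit(self, n_train: int = 1000, seed: int = 0) -> "BaseCallingResults":
        """Train kernels and scales on a random subset of reads.

        Samples ``n_train`` reads without replacement (all reads, with a
        warning, if the dataset is smaller) and runs blind deconvolution.
        """
        n = self.block.n_reads
        if n_train >= n:
            if n_train > n:
                warnings.warn(
                    f"requested {n_train} training reads but dataset has "
                    f"{n}; training on all reads",
                    stacklevel=2,
                )
            idx = np.arange(n)
        else:
            rng = np.random.default_rng(seed)
            idx = np.sort(rng.choice(n, size=n_train, replace=False))
        training = self.block.subset(idx)
        blind = blind_deconvolve(training, self.config)
        return BaseCallingResults(
            model=self,
            kernels=blind.kernels,
            windows=blind.windows,
            scales=blind.scales,
            training_index=idx,
            converged=blind.converged,
            n_outer_iterations=blind.n_outer_iterations,
            objective_traces=blind.objective_traces,
        )


@dataclass
class BaseCallingResults:
    """Fitted instrument model plus diagnostics."""

    model: BaseCallingModel | None
    kernels: list[ConvolutionKernel]
    windows: list[Window]
    scales: list[ChannelScales]
    training_index: np.ndarray = field(default_factory=lambda: np.array([], int))
    converged: bool = True
    n_outer_iterations: int = 0
    objective_traces: list = field(default_factory=list)

    @property
    def crosstalk(self) -> np.ndarray:
        return self.kernels[0].crosstalk

    @property
    def n_cycles(self) -> int:
        return self.windows[-1].end_cycle

    def call(
        self,
        block: IntensityBlock | None = None,
        mode: str = "slow",
        batch_size: int = 10000,
        recompute_scales: bool = False,
        isd_config: ISDConfig | None = None,
    ) -> BaseCallSet:
        """Base-call an intensity block with the trained kernels.

        ``mode='slow'`` runs the full ISD iteration; ``mode='fast'`` the
        non-iterative single-solve variant.  Reads are processed in
        batches (output is independent of the batch size); trained
        per-window channel scales are reused unless
        ``recompute_scales=True``.
        """
        if mode not in ("slow", "fast"):
            raise ValueError("mode must be 'slow' or 'fast'")
        if block is None:
            if self.model is None:
                raise ValueError("no block given and model not attached")
            block = self.model.block
        if block.n_cycles != self.n_cycles:
            raise ValueError(
                f"block has {block.n_cycles} cycles but the model was "
                f"trained on {self.n_cycles}"
            )
        cfg = isd_config or (
            self.model.config.isd if self.model is not None else ISDConfig()
        )
        bases = []
        quals = []
        for start in range(0, block.n_reads, batch_size):
            sub = block.subset(np.arange(start, min(start + batch_size, block.n_reads)))
            res = isd_deconvolve(
                sub,
                self.kernels,
                self.windows,
                cfg,
                scales=self.scales,
                recompute_scales=recompute_scales,
                fast=(mode == "fast"),
            )
            bases.append(np.array(CHANNELS, dtype="U1")[res.latent.calls])
            quals.append(raw_quality(res.deconvolved))
        raw = np.vstack(quals)
        return BaseCallSet(
            bases=np.vstack(bases),
            raw_quality=raw,
            read_ids=list(block.read_ids),
            phred=provisional_phred(raw),
        )

    def summary(self) -> str:
        """Human-readable account of the fitted instrument model."""
        lines = [
            "Blind-deconvolution base-calling model",
            "=" * 46,
            f"cycles: {self.n_cycles}   windows: {len(self.windows)}   "
            f"phasing lags: +/-{self.kernels[0].n_lags}",
            f"training reads: {len(self.training_index)}   "
            f"outer iterations: {self.n_outer_iterations}   "
            f"converged: {self.converged}",
            "",
            "Cross-talk matrix (rows: observed channel, cols: source):",
        ]
        header = "      " + "".join(f"{c:>8}" for c in CHANNELS)
        lines.append(header)
        for i, ch in enumerate(CHANNELS):
            row = "".join(f"{v:8.3f}" for v in self.crosstalk[i])
            lines.append(f"    {ch} {row}")
        lines.append("")
        lines.append("Per-window phasing profiles and channel scales:")
        for k, w, s in zip(self.kernels, self.windows, self.scales):
            prof = ", ".join(f"{v:.3f}" for v in k.phasing)
            sc = ", ".join(f"{v:.3f}" for v in s.x)
            lines.append(
                f"    [{w.start_cycle:3d},{w.end_cycle:3d})  "
                f"phasing [{prof}]  scales [{sc}]"
            )
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "channel_order": list(CHANNELS),
            "windows": [[w.start_cycle, w.end_cycle] for w in self.windows],
            "kernels": [
                {
                    "window_index": k.window_index,
                    "crosstalk": k.crosstalk.tolist(),
                    "phasing": k.phasing.tolist(),
                }
                for k in self.kernels
            ],
            "scales": [s.x.tolist() for s in self.scales],
            "converged": self.converged,
            "n_outer_iterations": self.n_outer_iterations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BaseCallingResults":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("channel_order") != list(CHANNELS):
            raise ValueError("model file has unexpected channel order")
        windows = [Window(a, b) for a, b in payload["windows"]]
        kernels = [
            ConvolutionKernel(
                np.array(k["crosstalk"]), np.array(k["phasing"]), k["window_index"]
            )
            for k in payload["kernels"]
        ]
        scales = [ChannelScales(np.array(s)) for s in payload["scales"]]
        return cls(
            model=None,
            kernels=kernels,
            windows=windows,
            scales=scales,
            converged=payload.get("converged", True),
            n_outer_iterations=payload.get("n_outer_iterations", 0),
        )
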