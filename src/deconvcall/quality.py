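"""Raw base-call quality ratios and calibration to PHRED scores.

The raw quality of a call is the ratio of the strongest channel to the
sum of the two strongest channels of the *deconvolved* (pre-threshold)
quadruplet, which lies in [0.5, 1.0]: 0.5 when the top two channels tie,
1.0 when a single channel carries all signal.

Raw ratios are calibrated against known correctness labels (simulation
ground truth here; an alignment-derived mask in production) by binning
into equal-count bins, measuring the empirical error rate per bin,
rectifying monotonicity by isotonic regression, and converting to
integer PHRED = -10 log10(err), capped at 41 (Illumina 1.8 convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

PHRED_CAP = 41


def raw_quality(deconvolved: np.ndarray) -> np.ndarray:
    """Per-(read, cycle) purity ratio s1 / (s1 + s2) of the two strongest
    channels (negatives clipped to 0 first); 0.5 when both vanish."""
    v = np.clip(np.asarray(deconvolved, dtype=float), 0.0, None)
    top2 = np.partition(v, -2, axis=-1)[..., -2:]
    s2, s1 = top2[..., 0], top2[..., 1]
    total = s1 + s2
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(total > 0, s1 / np.where(total > 0, total, 1.0), 0.5)
    return q


def provisional_phred(raw: np.ndarray) -> np.ndarray:
    """Uncalibrated PHRED from the naive error proxy 1 - raw quality.

    A placeholder for writing FASTQ before calibration labels exist.
    """
    p_err = np.clip(1.0 - np.asarray(raw, dtype=float), 10.0 ** (-PHRED_CAP / 10), 1.0)
    return np.minimum(np.round(-10.0 * np.log10(p_err)), PHRED_CAP).astype(int)


@dataclass
class QualityMap:
    """Piecewise-constant mapping from raw quality to PHRED.

    ``upper_edges[k]`` is the upper raw-quality edge of bin k (the last
    edge is 1.0); ``phred[k]`` the calibrated score of that bin.
    """

    upper_edges: np.ndarray
    phred: np.ndarray
    bin_error: np.ndarray
    bin_count: np.ndarray

    def apply(self, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        idx = np.searchsorted(self.upper_edges[:-1], raw, side="right")
        return self.phred[idx]

    def to_table(self, path) -> None:
        """Two-column text table: bin upper edge, PHRED."""
        with open(path, "w") as fh:
            fh.write("raw_quality_upper_edge\tphred\n")
            for edge, ph in zip(self.upper_edges, self.phred):
                fh.write(f"{edge:.6f}\t{int(ph)}\n")

    @classmethod
    def from_table(cls, path) -> "QualityMap":
        data = np.loadtxt(path, skiprows=1)
        data = np.atleast_2d(data)
        n = len(data)
        return cls(
            upper_edges=data[:, 0],
            phred=data[:, 1].astype(int),
            bin_error=np.full(n, np.nan),
            bin_count=np.zeros(n, dtype=int),
        )


def calibrate(
    raw: np.ndarray,
    correct: np.ndarray,
    n_bins: int = 20,
    cap: int = PHRED_CAP,
) -> tuple[QualityMap, np.ndarray]:
    """Calibrate raw quality ratios against correctness labels.

    Bins raw scores into ``n_bins`` equal-count bins (empty bins merge
    with their neighbour via duplicate quantile edges), computes the
    empirical error rate per bin, rectifies it to be non-increasing in
    raw quality by count-weighted isotonic regression, and converts to
    capped integer PHRED.  Returns the mapping and the per-call PHRED
    matrix.
    """
    raw = np.asarray(raw, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if raw.shape != correct.shape:
        raise ValueError("raw and correct shapes differ")
    flat_raw = raw.reshape(-1)
    flat_ok = correct.reshape(-1)
    if flat_raw.size == 0:
        raise ValueError("no calls to calibrate")

    qs = np.linspace(0.0, 1.0, n_bins + 1)[1:]
    edges = np.unique(np.quantile(flat_raw, qs))
    edges[-1] = max(edges[-1], 1.0)  # top bin always reaches 1.0
    bin_idx = np.searchsorted(edges[:-1], flat_raw, side="right")

    n_eff = len(edges)
    counts = np.bincount(bin_idx, minlength=n_eff)
    errors = np.bincount(bin_idx, weights=~flat_ok, minlength=n_eff)
    # merge any residual empty bin into its left neighbour
    keep = counts > 0
    edges, counts, errors = edges[keep], counts[keep], errors[keep]
    err_rate = errors / counts

    if len(edges) > 1:
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        err_rate = iso.fit_transform(
            np.arange(len(edges)), err_rate, sample_weight=counts
        )

    floor = 10.0 ** (-cap / 10.0)
    phred = np.round(-10.0 * np.log10(np.maximum(err_rate, floor)))
    phred = np.minimum(phred, cap).astype(int)
    phred = np.maximum.accumulate(phred)  # keep monotone after rounding

    qmap = QualityMap(
        upper_edges=edges,
        phred=phred,
        bin_error=err_rate,
        bin_count=counts,
    )
    return qmap, qmap.apply(raw)
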