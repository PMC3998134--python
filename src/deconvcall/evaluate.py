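"""Accuracy metrics for calls against known true sequences."""

from __future__ import annotations

import numpy as np

from .core import BaseCallSet


def evaluate_calls(calls: BaseCallSet, truth: np.ndarray) -> dict:
    """Compare a call set with a truth base matrix.

    Returns overall error rate, per-cycle error rates, the number of
    perfect reads, and — for comparability with alignment-filtered
    evaluations — the error rate restricted to reads with at most five
    substitution errors.
    """
    truth = np.asarray(truth, dtype="U1")
    if truth.shape != calls.bases.shape:
        raise ValueError(
            f"truth shape {truth.shape} != calls shape {calls.bases.shape}"
        )
    wrong = calls.bases != truth
    per_read_errors = wrong.sum(axis=1)
    le5 = per_read_errors <= 5
    n_reads, n_cycles = wrong.shape
    return {
        "n_reads": int(n_reads),
        "n_cycles": int(n_cycles),
        "error_rate": float(wrong.mean()),
        "per_cycle_error": wrong.mean(axis=0),
        "perfect_reads": int((per_read_errors == 0).sum()),
        "perfect_read_fraction": float((per_read_errors == 0).mean()),
        "reads_le5_errors": int(le5.sum()),
        "error_rate_le5": float(wrong[le5].mean()) if le5.any() else 0.0,
    }
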