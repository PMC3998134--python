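"""Readers and writers for intensity tables and sequence outputs.

Two tab-delimited intensity dialects are supported, both with channel
columns in the fixed order A, C, G, T within each cycle (nothing in the
data self-describes this, so it is a hard convention):

* ``plain`` — a header row, then one row per read of 4 * n_cycles numeric
  columns.  Transparently gzipped when the path ends in ``.gz``.  This is
  the simulator's native format.
* ``illumina_int`` — the classic ``_int.txt`` layout: four space-separated
  metadata fields (lane, tile, x, y), then one space-separated intensity
  quadruplet per cycle, with tabs between the metadata field and each
  cycle.

Sequence output is standard FASTA (wrapped at 70 columns) and 4-line
Sanger FASTQ (PHRED+33).
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CHANNELS, IntensityBlock, BaseCallSet, N_CHANNELS

DIALECTS = ("plain", "illumina_int")


class IntensityParseError(ValueError):
    pass


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_intensity_table(path, dialect: str = "plain") -> IntensityBlock:
    """Parse an intensity file into an IntensityBlock.

    The column count must be divisible by 4; n_cycles is inferred.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if dialect == "plain":
        return _read_plain(path)
    return _read_illumina_int(path)


def _read_plain(path) -> IntensityBlock:
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise IntensityParseError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise IntensityParseError(
            f"{path}: non-numeric or missing cell at data line {row + 2}"
        )
    n_cols = df.shape[1]
    if n_cols % N_CHANNELS != 0:
        raise IntensityParseError(
            f"{path}: {n_cols} columns is not a multiple of 4"
        )
    values = df.to_numpy().reshape(len(df), n_cols // 4, N_CHANNELS)
    return IntensityBlock(values, [f"read_{i}" for i in range(len(df))])


def _read_illumina_int(path) -> IntensityBlock:
    rows, ids = [], []
    n_cycles = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            meta = fields[0].split()
            if len(meta) != 4:
                raise IntensityParseError(
                    f"{path}:{lineno}: expected 4 metadata fields "
                    f"(lane tile x y), got {len(meta)}"
                )
            quads = []
            for cyc, chunk in enumerate(fields[1:]):
                parts = chunk.split()
                if len(parts) != N_CHANNELS:
                    raise IntensityParseError(
                        f"{path}:{lineno}: cycle {cyc} has {len(parts)} "
                        "values, expected 4"
                    )
                try:
                    quads.append([float(p) for p in parts])
                except ValueError as exc:
                    raise IntensityParseError(
                        f"{path}:{lineno}: non-numeric cell: {exc}"
                    ) from exc
            if n_cycles is None:
                n_cycles = len(quads)
            elif len(quads) != n_cycles:
                raise IntensityParseError(
                    f"{path}:{lineno}: ragged row ({len(quads)} cycles, "
                    f"expected {n_cycles})"
                )
            rows.append(quads)
            ids.append("_".join(meta))
    if not rows:
        raise IntensityParseError(f"{path}: empty intensity file")
    return IntensityBlock(np.asarray(rows, dtype=float), ids)


def write_intensity_table(
    block: IntensityBlock, path, dialect: str = "plain"
) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    if dialect == "plain":
        cols = [
            f"cycle{c}_{ch}"
            for c in range(block.n_cycles)
            for ch in CHANNELS
        ]
        df = pd.DataFrame(
            block.values.reshape(block.n_reads, -1), columns=cols
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        return
    with _open_text(path, "wt") as fh:
        for i in range(block.n_reads):
            meta = block.read_ids[i].split("_")
            if len(meta) != 4 or not all(_numeric(m) for m in meta):
                meta = ["1", "1", str(i), "0"]
            cycles = "\t".join(
                " ".join(f"{v:.2f}" for v in block.values[i, c])
                for c in range(block.n_cycles)
            )
            fh.write(" ".join(meta) + "\t" + cycles + "\n")


def _numeric(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def write_fasta(calls: BaseCallSet, path, width: int = 70) -> None:
    """FASTA output, sequences wrapped at ``width`` columns."""
    seqs = calls.sequences()
    with _open_text(path, "wt") as fh:
        for rid, seq in zip(calls.read_ids, seqs):
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fasta_sequences(sequences, ids, path, width: int = 70) -> None:
    """FASTA from raw sequence strings (e.g. simulator ground truth)."""
    with _open_text(path, "wt") as fh:
        for rid, seq in zip(ids, sequences):
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(calls: BaseCallSet, path) -> None:
    """4-line Sanger FASTQ with PHRED+33 qualities (scores 0..41)."""
    if calls.phred is None:
        raise ValueError("call set has no PHRED scores; calibrate first")
    if (calls.phred < 0).any() or (calls.phred > 41).any():
        bad = calls.phred[(calls.phred < 0) | (calls.phred > 41)]
        raise ValueError(
            f"PHRED scores out of encodable range [0, 41]: e.g. {bad.flat[0]}"
        )
    seqs = calls.sequences()
    with _open_text(path, "wt") as fh:
        for i, (rid, seq) in enumerate(zip(calls.read_ids, seqs)):
            qual = "".join(chr(33 + q) for q in calls.phred[i])
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_truth_fasta(path) -> tuple[np.ndarray, list[str]]:
    """Load a ground-truth FASTA as a base-character matrix (all records
    must share one length)."""
    from Bio import SeqIO

    seqs, ids = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs.append(str(rec.seq).upper())
        ids.append(rec.id)
    if not seqs:
        raise ValueError(f"no records in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("truth records have differing lengths")
    return np.array([list(s) for s in seqs], dtype="U1"), ids
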