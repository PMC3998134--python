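# deconvcall

Base-calling of sequencing-by-synthesis fluorescence intensities by
sparse blind deconvolution.

## The problem

Illumina-style sequencers read DNA one cycle at a time: at each cycle a
cluster of identical DNA fragments incorporates one labelled nucleotide,
and four fluorescence channels (A, C, G, T) are imaged. Ideally the
intensity quadruplet at each cycle would light up exactly one channel.
In practice the signal is distorted by four instrument biases:

* **cross-talk** — spectral overlap between dyes correlates the four
  channels within a cycle;
* **phasing / pre-phasing** — molecules in a cluster that fall behind or
  jump ahead leak signal into neighbouring cycles;
* **signal decay** — intensities shrink as cycles progress;
* **background noise** — the signal-to-noise ratio drops in late cycles.

`deconvcall` models the observed per-read signal **B** (cycles × 4
channels) as the convolution of a latent sparse incorporation signal
**X** — exactly one non-zero channel per cycle — with a kernel **K**
combining a 4×4 cross-talk matrix and a per-window phasing profile,
plus noise:

```
B = K X + N
```

Base-calling is then the inverse problem of recovering the support of
**X**: the non-zero channel at each cycle *is* the base-call. Because
neither **K** nor **X** is known, this is *blind* deconvolution, solved
by alternating

1. **X-step** — non-blind sparse deconvolution by *iterative support
   detection* (ISD): alternating a banded least-squares solve of
   `min ‖KX − B‖² + β‖X − w‖²` with adaptive hard thresholding (keep the
   strongest channel per cycle, in channel-normalized units) under an
   increasing penalty schedule β₁ < β₂ < … (an L0 exterior-penalty
   scheme);
2. **K-step** — least-squares kernel estimation in two stages:
   cross-talk from the first four cycles, then the phasing profile per
   20-cycle window with cross-talk held fixed.

Relative channel intensities are estimated per window from ratios of
successive differing candidate calls, via the generalized eigenproblem
`RᵀR x = λ D x` (smallest eigenvalue; **D** counts calls per channel),
sidestepping per-read normalization entirely.

Training runs the blind alternation on a sampled subset (default 1000
reads); calling deconvolves the full dataset with the trained kernels,
either iteratively (`slow`) or in a single solve-and-threshold pass
(`fast`). Per-call quality is the ratio of the strongest channel to the
sum of the two strongest after deconvolution (∈ [0.5, 1]), calibrated to
PHRED scores against correctness labels. The cost of calling is linear
in read length.

The package also ships a simulator that generates intensity data with
all four biases and known ground truth, so every stage is testable
without sequencer data.

## Worked example

```python
import numpy as np
from deconvcall import (BaseCallingModel, SimulationConfig, simulate_reads,
                        evaluate_calls, dye_crosstalk)

cfg = SimulationConfig(
    n_reads=2000, n_cycles=50,
    crosstalk_true=dye_crosstalk(0.3, 0.25),     # dye-pair leakage up to 0.3
    phasing_true=np.array([0.05, 0.9, 0.05]),    # 5% lead / 5% lag
    noise_sd=0.15, seed=42,
)
block, truth = simulate_reads(cfg)

results = BaseCallingModel(block).fit(n_train=1000, seed=42)
print(results.summary())

calls = results.call(mode="slow")
metrics = evaluate_calls(calls, truth)
print(f"error rate:    {metrics['error_rate']:.5f}")
print(f"perfect reads: {metrics['perfect_reads']} / {metrics['n_reads']}")
```

prints

```
Blind-deconvolution base-calling model
==============================================
cycles: 50   windows: 3   phasing lags: +/-1
training reads: 1000   outer iterations: 13   converged: True

Cross-talk matrix (rows: observed channel, cols: source):
             A       C       G       T
    A    1.000   0.283   0.048   0.000
    C    0.186   1.000   0.000   0.000
    G    0.001   0.010   1.000   0.249
    T    0.000   0.048   0.163   1.000

Per-window phasing profiles and channel scales:
    [  0, 20)  phasing [0.051, 0.898, 0.051]  scales [0.500, 0.500, 0.500, 0.500]
    [ 20, 40)  phasing [0.048, 0.901, 0.050]  scales [0.499, 0.500, 0.500, 0.502]
    [ 40, 50)  phasing [0.053, 0.900, 0.047]  scales [0.501, 0.499, 0.501, 0.499]

error rate:    0.00074
perfect reads: 1930 / 2000
```

The fitted cross-talk matrix and phasing profiles recover the generating
values (true off-diagonals 0.30/0.18/0.25/0.175, true profile
[0.05, 0.90, 0.05]) from noisy data, and calling at 15% noise leaves an
error rate of 7.4 × 10⁻⁴, below naive per-cycle argmax on the same
intensities (≈ 8 × 10⁻⁴; both are recomputed by
`scripts/acceptance.py`, see below).

The same pipeline is available from the shell:

```bash
deconvcall simulate --n-reads 2000 --n-cycles 50 --noise-sd 0.15 --seed 42 \
    --out ints.tsv --truth-out truth.fasta
deconvcall train --intensities ints.tsv --n-train 1000 --seed 42 --model-out model.json
deconvcall call --intensities ints.tsv --model model.json --mode slow \
    --fasta-out calls.fasta --fastq-out calls.fastq --raw-quality-out raw.tsv
deconvcall calibrate --calls calls.fastq --raw-quality raw.tsv \
    --truth truth.fasta --map-out qmap.tsv
deconvcall evaluate --calls calls.fasta --truth truth.fasta
```

Intensity tables are tab-delimited (channel order A, C, G, T within each
cycle); the classic `_int.txt` dialect with lane/tile/x/y metadata is
supported via `--dialect illumina_int`.

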