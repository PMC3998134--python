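# Methods

## Signal model

One sequencing read is a cycles × 4 matrix of fluorescence intensities,
one column per dye channel in fixed A, C, G, T order. The observed
signal B is modelled as a windowed linear convolution of a latent sparse
incorporation signal X with an instrument kernel, plus noise:

    B[c] = Σ_t  p_w(c)[t] · C · X[c − t]  +  N[c]

* **C** (4×4, non-negative, strictly positive diagonal) is the
  instantaneous cross-talk mixing between dye channels.
* **p_w** is the phasing profile of the window w containing cycle c: a
  non-negative weight per lag −L…+L with the lag-0 weight largest.
  Lags beyond the read are truncated (zero-padded boundary), which keeps
  the stacked operator K banded and well conditioned.
* The kernel is **separable** — one scalar lag profile shared by all
  channels times one mixing matrix — and is held constant within
  non-overlapping windows of 20 cycles (the last window may be shorter).
  Separability is what makes the two-step kernel estimation below
  identifiable; channel-specific phasing is out of scope.
* X is one-hot per cycle in the ideal case: its support *is* the base
  sequence.

The default phasing half-width is L = 1 (one pre-phasing and one
phasing tap, configurable up to 3). How many lags the instrument really
mixes is an open modelling question; one lead/lag tap captures the
first-order effect and keeps the operator bandwidth small.

Blind deconvolution has an inherent scale ambiguity (k·c and X/c fit
equally well). It is fixed by convention: the cross-talk diagonal is
normalized to 1, each phasing profile sums to 1, and all residual scale
is absorbed into X.

## Channel normalization

Channel amplitudes differ (dye brightness, optics, gains). Per-read
normalization is deliberately avoided; instead, per window:

1. each channel is divided by its 95th percentile across all reads and
   cycles (quantile scaling);
2. the strongest scaled channel per cycle gives candidate calls;
3. every successive pair of *differing* candidate calls (channel i at
   cycle c with intensity b_i, channel j at c+1 with b_j) contributes
   the homogeneous relation x_i − (b_i/b_j)·x_j = 0;
4. stacking M relations into R, the relative channel intensities x
   minimize the Rayleigh quotient xᵀRᵀRx / xᵀDx, where the diagonal D
   counts calls per channel and corrects for unequal calling
   frequencies. x is the generalized eigenvector of (RᵀR, D) with
   smallest eigenvalue, sign-fixed positive and scaled to unit Euclidean
   norm (overall scale is irrelevant downstream).

Numerical guards: relations with observed ratio outside [1/50, 50] are
dropped; a degenerate system (fewer than 4 relations, a channel never
called) falls back to the plain eigenproblem of RᵀR and then to unit
scales, with warnings; the working per-window scales used in support
detection are the *composite* quantile factor × eigenvector. When a
window offers fewer than 5 candidate calls for some channel or fewer
than 10 relations, unit scales are used outright — at that sample size
both components are noise and measurably harm support detection on tiny
blocks (single-read instances).

Ratios are taken between quantile-scaled intensities, so the
eigenvector captures residual channel imbalance after the bulk quantile
correction. Successive-cycle ratios are insensitive to per-read
amplitude but absorb one factor of per-cycle decay; with 20-cycle
windows this appears as a small window-level bias in the composite
scales and cancels in the normalized argmax that consumes them.

## Sparse recovery by iterative support detection

Given kernels, the latent signal solves an L0-penalized least-squares
problem split with an auxiliary variable w and an exterior penalty:

    min_{X,w}  ‖KX − B‖² + β‖S⁻¹(X − w)‖² + α‖w‖₀

* **w-step**: adaptive hard thresholding — per (read, cycle), keep the
  channel with the largest *normalized* value X/s (s from the channel
  scales above), retain its unnormalized value clipped at 0, zero the
  rest. The threshold α is implicitly set per cycle so exactly one
  entry survives. This is the exact minimizer of the weighted penalty
  over one-non-negative-entry-per-cycle signals.
* **X-step**: the banded normal equations
  (KᵀK + β S⁻² + ridge·I) X = KᵀB + β S⁻² w, solved by one sparse LU
  factorization shared across all reads in the batch (the operator is
  identical per read), with a small ridge (1e−8) keeping the β = 0 solve
  well posed.

The penalty is measured in channel-normalized units (weights 1/s²,
normalized to geometric mean 1 so β keeps its scale). With unit scales
this reduces to the plain Euclidean penalty. The weighting makes both
half-steps exact coordinate minimizers of one common objective, so the
objective is non-increasing across every half-step by construction —
the monotonicity is asserted in the tests rather than hoped for.

β follows the increasing schedule 1, 4, 16, 64, 256 (geometric; the
weight on support consistency grows as the support estimate firms up),
with up to 8 outer iterations (the last β repeats) and convergence
declared when the relative Frobenius change of X drops below 1e−4.
Channel scales are recomputed from the current deconvolved signal every
outer iteration during training, and frozen to the trained values
during production calling (which also makes output independent of batch
size). The initial X is the plain ridge-stabilized least-squares
deconvolution. Non-convergence returns the best iterate with a warning.

**Fast mode** is the non-iterative variant: one β = 0 solve followed by
a single hard threshold.

The support kept by thresholding retains the *unnormalized* intensity:
scales are a calling aid, not a signal correction.

## Kernel estimation

Given a latent-signal estimate (the thresholded one-hot signal):

* **Cross-talk** is fit by least squares on cycles 0–3 only, where
  phasing has had little opportunity to act: stack latent and observed
  quadruplets and solve min ‖C x_c − b_c‖². On the first pass of the
  blind loop the phasing taps are a lag-0 spike; on later passes the
  current phasing profile is applied to the latent signal before the
  regression, which removes the neighbour-cycle leakage bias exactly.
  (A fixed-effect intercept cannot do this job: with a one-hot latent
  design the intercept is collinear with the channel columns.)
  Negative entries are clipped and columns rescaled to unit diagonal.
  A base absent from the first four cycles of every training read makes
  C unidentifiable and raises an error advising a larger sample.
* **Phasing** is fit per window with C fixed: the 2L+1 lag weights enter
  linearly, so min ‖KX − B‖² restricted to the window's cycles is a
  small least-squares problem; weights are clipped at 0 and normalized
  to sum 1. Windows narrower than 2L+1 cycles shrink L and pad the
  profile back with zeros.

The blind loop alternates ISD deconvolution with this two-step kernel
re-estimation (cross-talk re-estimated every iteration — it is cheap
and keeps the alternation consistent), starting from the identity
instrument (C = I, lag-0 spike), until the relative Frobenius change of
the stacked kernel parameters falls below 1e−6, capped at 25
iterations. The alternation's fixed point on noise-free data is the
generating kernel to numerical precision, so the tolerance directly
sets recovery accuracy; 1e−6 costs a few seconds per 1000 training
reads and leaves kernel errors near 1e−6 where 1e−3 would stop at
~5e−4.

## Training / calling split

Training fits kernels and scales on a seeded random subset (default
1000 reads, clamped to the dataset with a warning). Calling streams any
number of reads in batches against the frozen model; one sparse
factorization per β value per batch makes the cost linear in read
length and in the number of reads. The model serializes to JSON
(explicit channel order, window boundaries, kernels, scales).

## Quality scores

Raw quality is s₁/(s₁+s₂) with s₁ ≥ s₂ the two largest channel values
of the *deconvolved pre-threshold* quadruplet (negatives clipped; 0.5
when both vanish). It lies in [0.5, 1.0] and is invariant to positive
rescaling of the quadruplet.

Calibration maps raw quality to PHRED against correctness labels
(simulation ground truth here; in production an alignment-derived
mask — no aligner is embedded): 20 equal-count bins (empty bins merge
with a neighbour), empirical error per bin, count-weighted isotonic
rectification (error non-increasing in raw quality), then
PHRED = −10·log₁₀(err) rounded, capped at 41 (Illumina 1.8 convention),
and made monotone after rounding. Calibration is global by default; the
mapping serializes as a two-column text table. Uncalibrated FASTQ output
carries a provisional score from the proxy err ≈ 1 − raw.

## Simulator

The generator emulates the four biases on top of a one-hot latent
signal: per-channel gain g, geometric decay d^cycle, convolution with a
true (C, p), and additive Gaussian noise with per-cycle standard
deviation σ·(1 + slope·cycle). Defaults are the *ideal* instrument
(identity C, no phasing, d = 1, σ = 0, unit gains); biased conditions
are opted into explicitly. The standard biased test instrument uses a
diagonally dominant C with leakage concentrated in the spectrally close
(A,C) and (G,T) dye pairs (off-diagonals up to 0.3) and profile
[0.05, 0.90, 0.05]. True sequences are uniform random or drawn as
seeded random substrings of FASTA records.

What the simulator does *not* model: optical/image-level effects,
cluster density and spatial correlation, indels, signal-dependent or
correlated noise, cycle-to-cycle kernel drift within a window. Passing
tests therefore demonstrate correct recovery of the stated generative
model, not instrument-grade accuracy on real flowcell data.

## Problem sizes and numerical choices in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on simulated
data at desk scale: 500–2000 reads × 50–100 cycles, training samples of
400–1000 reads, a 100 000-call simulation for quality calibration
(calibrated on one half, evaluated on the held-out half, so the
PHRED-20 check is out-of-sample rather than tautological), and 20
single-read 5-cycle instances for the exhaustive-enumeration
cross-check of ISD (4⁵ candidate supports each, scored by
support-constrained least squares). The timing check compares calling
at 100 vs 50 cycles on 2000 reads and asserts a ratio < 3 — a loose,
hardware-tolerant proxy for linear scaling in read length.

Tie-breaking is deterministic throughout: argmax ties resolve to the
earlier channel in A < C < G < T order.

## Known limitations

* Channel-scale estimation degrades at very low signal-to-noise (late
  cycles under strong decay); scales there can drift and the caller
  approaches naive argmax accuracy.
* Cross-talk is assumed cycle-invariant across the read (estimated from
  the first four cycles only); instruments with cycle-dependent mixing
  are not modelled.
* The ISD alternation is a heuristic for an NP-hard L0 problem; on tiny
  instances it matches exhaustive enumeration, but no global-optimality
  guarantee exists at scale.
* Binary Illumina formats (CIF/BCL) are not parsed; intensity input is
  the plain TSV or text `_int.txt` dialect.
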