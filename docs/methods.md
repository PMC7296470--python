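# Methods

## The estimator

`parwelch` computes Welch power-spectral-density (PSD) estimates of
multi-channel EEG.  For a channel x[n], n = 0..N−1, sampled at fs Hz:

1. **Segmentation.**  The signal is split into Ns overlapping segments of
   length L; segment i starts at i·(L − N_D) where N_D is the overlap in
   samples (50% overlap, N_D = L/2, by default).  Ns is maximal: the
   largest integer with (Ns−1)·(L−N_D) + L ≤ N.  Trailing samples that do
   not fill a whole segment are discarded and reported in
   `SegmentPlan.discarded_tail`.  Segment sample ranges are inclusive
   0-based `[start, start+L−1]`.
2. **Windowing.**  Each segment is tapered with w(n); the default is the
   Hamming window w(n) = 0.54 − 0.46·cos(2πn/(L−1)) (symmetric
   convention).  A periodic variant with denominator L is available, as
   are Hann and rectangular windows.
3. **Periodogram.**  With A_i(k) the length-L DFT of the windowed
   segment, φ_i(k) = |A_i(k)|² / (fs · L · U), where
   U = (1/L)·Σ w(n)² is the mean squared window coefficient.  This is the
   "density" scaling with units signal²/Hz.  The "eq6" scaling omits the
   1/fs factor and returns the bare normalised periodogram.  The two
   differ by exactly the constant fs (same code path, one division).
4. **One-sided reduction.**  For even L the one-sided spectrum keeps bins
   k = 0..L/2 and doubles every interior bin (not DC, not Nyquist) so the
   integrated density conserves total power (Parseval).  Odd L with
   one-sided output is rejected rather than guessed at.
5. **Averaging.**  S(k) = (1/Ns)·Σ_i φ_i(k), accumulated in ascending
   segment-index order.

Defaults (`WelchConfig()`): L = 64 samples, N_D = 32, symmetric Hamming,
density scaling, one-sided, no detrending — the canonical call for
256 Hz EEG, giving 4 Hz bins from 0 to 128 Hz.  These parameters trade
variance against frequency resolution: more segments (smaller L) average
more periodograms but widen the bins.

Detrending defaults to `none` (the window is applied to the raw
samples); `constant` subtracts each segment's mean first.  Reference
routines that detrend by default must have it disabled when comparing.

## Parallel execution

The scheduler follows a master–worker, map-reduce structure with five
stages: input, split, map, reduce, output.  Segments are assigned
round-robin — segment j to rank j mod size — so worker loads differ by
at most one; for 7 segments over 4 workers, rank 0 holds segments
{0, 4}, covering samples [0, 63] and [128, 191].  Rank 0 computes its
own share as well as coordinating.

Workers return periodograms tagged with their segment index.  The master
validates that the received indices are exactly {0..Ns−1} (a missing or
duplicated index signals a lost or repeated message and raises an
integrity error), re-sorts them into ascending segment order, and
averages.  Because the serial estimator and the reduce stage share one
accumulation routine with a fixed order, the parallel result is **bitwise
identical** to the serial one for every worker count, backend, and
message-arrival order.  This deliberately forgoes tree reduction; with
Ns in the tens, reduction cost is negligible and reproducibility is
worth more.

Three backends satisfy the same contract (map `worker_compute` over all
ranks, return the tagged results):

- `serial` — in-process sequential emulation; always available, the
  reference for determinism tests and the Ts baseline;
- `process` — local process pool (joblib/loky), one job per rank;
- `message-passing` — an mpi4py adapter for cluster deployment
  (broadcast task description, compute per rank, gather to rank 0).  It
  requires mpi4py and an MPI launcher and is not exercised by the
  default test suite.

For directories of many small files, `process_dir` offers two
granularities: `segment` (default; each file's segments are distributed
over the workers) and `file` (whole files farmed out, each computed
serially), the latter suiting workloads where per-file open/close
overhead dominates.  Both produce byte-identical output.

## Speedup benchmarking

`benchmark_speedup` measures speedup = Ts/Tp: the serial baseline Ts is
timed first with the sequential emulation backend, then each parallel
worker count is timed, taking the minimum wall time over the configured
repetitions on a monotonic clock (the minimum is the standard choice for
suppressing scheduler noise).  The serial row reports speedup exactly
1.0 by definition.  Wall-clock times are hardware-bound; the harness
reports them and the package's tests only verify the formula and table
structure, never absolute performance.

## File formats

The *middle file* is the plain-text interchange format every recording
is converted into: a `#MIDDLE 1.0` magic line, `#fs`, `#channels`, and
`#labels` headers, then one tab-separated row per time point with one
column per channel.  PSD output is a delimited table (`freq_hz` plus one
column per channel, one row per frequency bin) loadable directly in a
spreadsheet.  All numbers are rendered with 17 significant digits, which
round-trips IEEE doubles bit-exactly; both round trips are
property-tested.  One file per trial with channel columns was chosen
over one file per channel to keep a 64-electrode trial in a single
artifact.

## Synthetic data

The generator emulates the dimensions of a standard scalp-EEG study
dataset — 64 channels at 256 Hz, 1-second (256-sample) trials — with a
signal model of pure cosines plus white Gaussian noise (default
noise sd 1.0, one 8–13 Hz-range tone of amplitude 2 per channel).  Seeds
are fully deterministic: per-file seeds derive additively from the
master seed and are recorded in a manifest, so datasets are
byte-reproducible.  The model has **no** 1/f background, band-limited
rhythms, artifacts, or inter-channel correlation; passing tests
demonstrate correctness of the spectral arithmetic and scheduling, not
fidelity to real EEG.

## Numerical choices and verification

- DFT length equals the segment length L (no zero padding).
- The averaging divisor is the number of segments Ns.
- Oracle tests compare against a from-scratch direct-summation O(L²)
  DFT implementation (explicit loops, independent window formula) at
  relative tolerance 1e−10, and against `scipy.signal.welch` (with an
  explicit symmetric-Hamming window array and detrending disabled) at
  1e−12; the observed agreement is ~1e−14.
- A Parseval check on unit white noise (rectangular window, no overlap,
  N = 65536) verifies that the integrated one-sided density recovers the
  sample mean power; for that configuration the identity is exact up to
  rounding.
- Problem sizes in the test suite and acceptance script (channels up to
  N = 1024 for oracle sweeps, 25–100 seeded channels, 8192-sample
  benchmark workloads) were chosen to exercise every code path while
  keeping the whole suite under ten seconds.

## The sklearn adapter

`WelchPSD` exposes the estimator as a scikit-learn transformer mapping a
(n_channels, n_samples) matrix to (n_channels, n_bins) spectral
features, so PSD extraction composes with sklearn pipelines and model
selection.  It learns nothing from data: `fit` validates the input
shape against the segmentation parameters and freezes the frequency
axis (`freqs_`, `n_bins_`, `n_segments_`).

## Known limitations

- No multitaper or time-frequency (wavelet) estimation.
- Window types limited to Hamming, Hann, rectangular.
- The synthetic generator is not a physiological EEG simulator.
- The message-passing backend requires an external MPI stack and is
  untested where none is present.
- Wall-clock speedup depends entirely on the host; on a single CPU the
  process backend will not be faster than serial.
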