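"""Serial Welch PSD estimator.

The estimator averages windowed periodograms of overlapping segments:

1. split x[n], n = 0..N-1, into Ns segments of length L whose starts step
   by L - n_overlap (50% overlap with the defaults);
2. taper each segment with a window w(n) (Hamming by default) and take its
   length-L discrete Fourier transform A_i(k);
3. form the periodogram phi_i(k) = |A_i(k)|^2 / (fs * L * U) with U the
   mean squared window coefficient (drop the fs division for the "eq6"
   scaling variant);
4. average: S(k) = (1/Ns) * sum_i phi_i(k).

Accumulation over segments is always performed in ascending segment-index
order so that the floating-point result is bitwise reproducible; the
parallel scheduler relies on this (see :mod:`parwelch.scheduler`).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import ConfigError
from .types import (
    Periodogram,
    PSDResult,
    SegmentPlan,
    SignalChannel,
    WelchConfig,
    WindowVector,
)

__all__ = [
    "plan_segments",
    "segment_bounds",
    "make_window",
    "frequency_axis",
    "segment_periodogram",
    "average_periodograms",
    "welch_psd",
]


def plan_segments(n_samples: int, config: WelchConfig) -> SegmentPlan:
    """Derive the maximal overlapped segmentation of an ``n_samples`` signal.

    Segment i covers samples ``[i*step, i*step + L - 1]`` with
    ``step = L - n_overlap``; the number of segments is the largest Ns with
    ``(Ns-1)*step + L <= n_samples``.  For N=256, L=64, n_overlap=32 this
    yields the canonical 7 segments.

    Raises
    ------
    ConfigError
        If the signal is shorter than one segment.
    """
    L = config.seg_len
    if n_samples < L:
        raise ConfigError(
            f"signal shorter than one segment: N={n_samples} < L={L}"
        )
    step = config.step
    n_segments = (n_samples - L) // step + 1
    starts = tuple(i * step for i in range(n_segments))
    discarded = n_samples - (starts[-1] + L)
    return SegmentPlan(
        n_segments=n_segments,
        starts=starts,
        seg_len=L,
        discarded_tail=discarded,
    )


def segment_bounds(i: int, config: WelchConfig) -> tuple[int, int]:
    """Inclusive 0-based sample range covered by segment ``i``.

    With the defaults (L=64, 32-sample overlap) segment 0 covers [0, 63]
    and segment 4 covers [128, 191].
    """
    if i < 0:
        raise ConfigError(f"segment index must be non-negative, got {i}")
    start = i * config.step
    return start, start + config.seg_len - 1


def make_window(kind: str, convention: str, seg_len: int) -> WindowVector:
    """Build a window of length ``seg_len`` with its power normalisation U.

    ``convention="periodic"`` uses denominator L in the raised-cosine
    argument (w(n) = 0.54 - 0.46*cos(2*pi*n/L) for Hamming); ``"symmetric"``
    uses L-1, matching the convention of common reference PSD routines, and
    is the default used throughout the package.
    """
    if kind not in ("hamming", "hann", "rectangular"):
        raise ConfigError(f"unknown window kind {kind!r}")
    if convention not in ("symmetric", "periodic"):
        raise ConfigError(f"unknown window convention {convention!r}")
    if seg_len < 2:
        raise ConfigError(f"window length must be >= 2, got {seg_len}")
    n = np.arange(seg_len, dtype=np.float64)
    if kind == "rectangular":
        coeffs = np.ones(seg_len, dtype=np.float64)
    else:
        a0, a1 = (0.54, 0.46) if kind == "hamming" else (0.5, 0.5)
        denom = float(seg_len) if convention == "periodic" else float(seg_len - 1)
        coeffs = a0 - a1 * np.cos(2.0 * np.pi * n / denom)
    power_norm = float(np.mean(coeffs**2))
    return WindowVector(coefficients=coeffs, power_norm=power_norm)


def frequency_axis(seg_len: int, fs: float, sided: str) -> np.ndarray:
    """Frequency bin centres in Hz: k*fs/L.

    One-sided output runs k = 0..L/2 (DC to Nyquist inclusive) and requires
    even L; two-sided runs k = 0..L-1.
    """
    if sided == "one":
        if seg_len % 2 != 0:
            raise ConfigError(
                f"one-sided axis requires an even segment length, got {seg_len}"
            )
        k = np.arange(seg_len // 2 + 1, dtype=np.float64)
    elif sided == "two":
        k = np.arange(seg_len, dtype=np.float64)
    else:
        raise ConfigError(f"unknown sidedness {sided!r}")
    return k * (float(fs) / float(seg_len))


def segment_periodogram(
    channel: SignalChannel,
    plan: SegmentPlan,
    i: int,
    window: WindowVector,
    config: WelchConfig,
) -> Periodogram:
    """Windowed periodogram of segment ``i``.

    Extracts the segment's samples, optionally removes the segment mean
    (``detrend="constant"``), tapers with the window, and computes the
    length-L DFT.  One-sided output keeps bins 0..L/2 and doubles every
    interior bin (not DC, not Nyquist) so the total power is conserved.
    """
    if not 0 <= i < plan.n_segments:
        raise ConfigError(
            f"segment index {i} out of range for plan with Ns={plan.n_segments}"
        )
    L = config.seg_len
    if len(window) != L:
        raise ConfigError(
            f"window length {len(window)} does not match segment length {L}"
        )
    start, end = segment_bounds(i, config)
    seg = channel.samples[start : end + 1]
    if config.detrend == "constant":
        seg = seg - seg.mean()
    tapered = seg * window.coefficients
    spectrum = np.fft.fft(tapered, n=L)
    power = np.abs(spectrum) ** 2 / (L * window.power_norm)
    if config.scaling == "density":
        power = power / channel.fs
    if config.sided == "one":
        half = power[: L // 2 + 1].copy()
        half[1 : L // 2] *= 2.0
        power = half
    return Periodogram(segment_index=i, values=power)


def average_periodograms(
    periodograms: Sequence[Periodogram], n_segments: int
) -> np.ndarray:
    """Mean of segment periodograms, accumulated in ascending index order.

    Both the serial estimator and the parallel reduce stage funnel through
    this helper so their floating-point results are bitwise identical.
    """
    ordered = sorted(periodograms, key=lambda p: p.segment_index)
    acc = np.zeros_like(np.asarray(ordered[0].values, dtype=np.float64))
    for p in ordered:
        acc += p.values
    return acc / n_segments


def welch_psd(channel: SignalChannel, config: WelchConfig | None = None) -> PSDResult:
    """Welch PSD estimate of one channel: the mean of its Ns segment
    periodograms, with the frequency axis attached.

    Raises
    ------
    ConfigError
        If the channel is shorter than one segment.
    """
    if config is None:
        config = WelchConfig()
    plan = plan_segments(channel.n_samples, config)
    window = make_window(config.window_kind, config.window_convention, config.seg_len)
    periodograms = [
        segment_periodogram(channel, plan, i, window, config)
        for i in range(plan.n_segments)
    ]
    psd = average_periodograms(periodograms, plan.n_segments)
    freqs = frequency_axis(config.seg_len, channel.fs, config.sided)
    return PSDResult(
        label=channel.label,
        freqs=freqs,
        psd=psd,
        n_segments_used=plan.n_segments,
        config=config,
    )
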