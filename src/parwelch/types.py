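"""Domain containers for the Welch estimator.

All containers are plain frozen dataclasses over numpy arrays; they carry
no behaviour beyond construction-time validation.  Indices are 0-based
throughout and segment sample ranges are inclusive ``[start, end]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError

WINDOW_KINDS = ("hamming", "hann", "rectangular")
WINDOW_CONVENTIONS = ("symmetric", "periodic")
SCALINGS = ("density", "eq6")
SIDES = ("one", "two")
DETRENDS = ("none", "constant")


@dataclass(frozen=True)
class SignalChannel:
    """One channel: samples x[n], n = 0..N-1, at sampling rate ``fs`` Hz."""

    label: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ConfigError("channel samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ConfigError(f"channel {self.label!r} contains non-finite samples")
        if not self.fs > 0:
            raise ConfigError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class WelchConfig:
    """Estimator settings.

    Defaults reproduce the canonical EEG call: 64-sample Hamming segments
    with 50% (32-sample) overlap, one-sided density-scaled output, no
    detrending.

    ``scaling="density"`` gives units^2/Hz (periodogram divided by
    ``fs * L * U``); ``scaling="eq6"`` omits the ``fs`` division and gives
    the bare windowed periodogram ``|A(k)|^2 / (L * U)``.
    """

    seg_len: int = 64
    n_overlap: int = 32
    window_kind: str = "hamming"
    window_convention: str = "symmetric"
    scaling: str = "density"
    sided: str = "one"
    detrend: str = "none"

    def __post_init__(self) -> None:
        if not isinstance(self.seg_len, (int, np.integer)) or self.seg_len < 2:
            raise ConfigError(f"segment length must be an integer >= 2, got {self.seg_len}")
        if not 0 <= self.n_overlap < self.seg_len:
            raise ConfigError(
                f"overlap must satisfy 0 <= n_overlap < seg_len, "
                f"got n_overlap={self.n_overlap}, seg_len={self.seg_len}"
            )
        for name, value, allowed in (
            ("window_kind", self.window_kind, WINDOW_KINDS),
            ("window_convention", self.window_convention, WINDOW_CONVENTIONS),
            ("scaling", self.scaling, SCALINGS),
            ("sided", self.sided, SIDES),
            ("detrend", self.detrend, DETRENDS),
        ):
            if value not in allowed:
                raise ConfigError(f"unknown {name} {value!r}; expected one of {allowed}")
        if self.sided == "one" and self.seg_len % 2 != 0:
            raise ConfigError(
                f"one-sided output requires an even segment length, got {self.seg_len}"
            )

    @property
    def step(self) -> int:
        """Hop between consecutive segment starts: L - n_overlap."""
        return self.seg_len - self.n_overlap

    @property
    def n_bins(self) -> int:
        """Number of frequency bins K implied by segment length and sidedness."""
        return self.seg_len // 2 + 1 if self.sided == "one" else self.seg_len


@dataclass(frozen=True)
class WindowVector:
    """Window coefficients w(n), n = 0..L-1, and the mean squared
    coefficient U = (1/L) * sum w(n)^2 used to normalise periodograms."""

    coefficients: np.ndarray
    power_norm: float

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=np.float64)
        object.__setattr__(self, "coefficients", coeffs)

    def __len__(self) -> int:
        return int(self.coefficients.size)


@dataclass(frozen=True)
class SegmentPlan:
    """The overlapped segmentation of an N-sample channel.

    ``starts[i] = i * (L - n_overlap)``; trailing samples that do not fill a
    whole segment are discarded and counted in ``discarded_tail``.
    """

    n_segments: int
    starts: tuple
    seg_len: int
    discarded_tail: int


@dataclass(frozen=True)
class Periodogram:
    """Single-segment periodogram values over the frequency bins."""

    segment_index: int
    values: np.ndarray

    @property
    def n_bins(self) -> int:
        return int(np.asarray(self.values).size)


@dataclass(frozen=True)
class PSDResult:
    """Averaged Welch PSD for one channel, with its frequency axis in Hz."""

    label: str
    freqs: np.ndarray
    psd: np.ndarray
    n_segments_used: int
    config: WelchConfig = field(compare=False)
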