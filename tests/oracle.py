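"""Independent direct-summation Welch oracle used only by the tests.

Implements the whole chain — segmentation, raised-cosine window, DFT,
periodogram scaling, one-sided doubling, averaging — with explicit loops
and no FFT, independently of the package's implementation.  Deliberately
slow and simple.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_window(kind: str, convention: str, L: int) -> np.ndarray:
    if kind == "rectangular":
        return np.ones(L)
    a0, a1 = (0.54, 0.46) if kind == "hamming" else (0.5, 0.5)
    denom = L if convention == "periodic" else L - 1
    return np.array([a0 - a1 * math.cos(2.0 * math.pi * n / denom) for n in range(L)])


def oracle_dft(x: np.ndarray) -> np.ndarray:
    """O(L^2) discrete Fourier transform by direct summation."""
    L = len(x)
    out = np.empty(L, dtype=complex)
    n = np.arange(L)
    for k in range(L):
        out[k] = np.sum(x * np.exp(-2j * math.pi * n * k / L))
    return out


def oracle_welch(
    x: np.ndarray,
    fs: float,
    L: int,
    n_overlap: int,
    window_kind: str = "hamming",
    window_convention: str = "symmetric",
    scaling: str = "density",
    sided: str = "one",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD by direct summation; returns (freqs, psd)."""
    x = np.asarray(x, dtype=float)
    N = len(x)
    step = L - n_overlap
    w = oracle_window(window_kind, window_convention, L)
    U = np.sum(w**2) / L
    starts = []
    i = 0
    while i * step + L <= N:
        starts.append(i * step)
        i += 1
    periodograms = []
    for start in starts:
        seg = x[start : start + L]
        A = oracle_dft(seg * w)
        phi = np.abs(A) ** 2 / (L * U)
        if scaling == "density":
            phi = phi / fs
        if sided == "one":
            half = phi[: L // 2 + 1].copy()
            for k in range(1, L // 2):
                half[k] *= 2.0
            phi = half
        periodograms.append(phi)
    psd = np.zeros_like(periodograms[0])
    for phi in periodograms:
        psd += phi
    psd /= len(periodograms)
    K = L // 2 + 1 if sided == "one" else L
    freqs = np.array([k * fs / L for k in range(K)])
    return freqs, psd
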