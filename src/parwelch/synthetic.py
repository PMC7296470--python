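"""Seeded generator of EEG-shaped test signals and middle-file datasets.

Emulates the dimensions of a standard scalp-EEG recording — 64 channels
sampled at 256 Hz, 1-second (256-sample) windows — so every stage of the
pipeline is testable without downloading data.  The signal model is a sum
of pure cosines plus white Gaussian noise; it deliberately has no 1/f
background or physiological band structure, which is sufficient to
exercise the estimator and scheduler but is not a realistic EEG
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .eeg_io import write_middle
from .errors import ConfigError
from .types import SignalChannel

__all__ = ["ToneSpec", "gen_channel", "gen_dataset"]

DEFAULT_N_CHANNELS = 64
DEFAULT_N_SAMPLES = 256
DEFAULT_FS = 256.0


@dataclass(frozen=True)
class ToneSpec:
    """One pure cosine component: amplitude * cos(2*pi*freq*t + phase)."""

    freq: float
    amplitude: float = 1.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.freq < 0:
            raise ConfigError(f"tone frequency must be >= 0, got {self.freq}")
        if self.amplitude < 0:
            raise ConfigError(f"tone amplitude must be >= 0, got {self.amplitude}")


def gen_channel(
    tones,
    noise_sd: float,
    n_samples: int = DEFAULT_N_SAMPLES,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    label: str = "ch00",
) -> SignalChannel:
    """Generate x[n] = sum of tones + N(0, noise_sd) white noise.

    The same seed always produces a bitwise-identical channel.  Tones
    above the Nyquist frequency fs/2 are rejected rather than silently
    aliased.
    """
    if n_samples < 1:
        raise ConfigError(f"n_samples must be >= 1, got {n_samples}")
    if noise_sd < 0:
        raise ConfigError(f"noise_sd must be >= 0, got {noise_sd}")
    n = np.arange(n_samples, dtype=np.float64)
    x = np.zeros(n_samples, dtype=np.float64)
    for tone in tones:
        if tone.freq > fs / 2:
            raise ConfigError(
                f"tone at {tone.freq} Hz exceeds the Nyquist frequency {fs / 2} Hz"
            )
        x += tone.amplitude * np.cos(2.0 * np.pi * tone.freq * n / fs + tone.phase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x += rng.normal(0.0, noise_sd, n_samples)
    return SignalChannel(label=label, samples=x, fs=fs)


def gen_dataset(
    n_files: int,
    out_dir,
    n_channels: int = DEFAULT_N_CHANNELS,
    n_samples: int = DEFAULT_N_SAMPLES,
    fs: float = DEFAULT_FS,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> list[Path]:
    """Write ``n_files`` middle files of synthetic EEG-shaped data.

    Each file's channels carry one deterministic alpha-band-range tone
    (8-13 Hz, cycling per channel) over white noise.  Per-file seeds are
    derived additively from the master seed (seed + file index) and
    recorded, with shapes, in a ``manifest.tsv`` alongside the files, so a
    dataset is byte-reproducible from its manifest.
    """
    if n_files < 1 or n_channels < 1 or n_samples < 1:
        raise ConfigError("n_files, n_channels and n_samples must all be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest_rows = []
    for f in range(n_files):
        file_seed = seed + f
        channels = []
        for m in range(n_channels):
            tone = ToneSpec(freq=8.0 + (m % 6), amplitude=2.0)
            channels.append(
                gen_channel(
                    [tone],
                    noise_sd=noise_sd,
                    n_samples=n_samples,
                    fs=fs,
                    seed=file_seed * 1009 + m,
                    label=f"ch{m:02d}",
                )
            )
        path = out_dir / f"synthetic_{f:04d}.txt"
        write_middle(fs, channels, path)
        paths.append(path)
        manifest_rows.append(
            f"{path.name}\t{file_seed}\t{n_channels}\t{n_samples}\t{fs:g}"
        )
    manifest = out_dir / "manifest.tsv"
    with manifest.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("file\tseed\tchannels\tsamples\tfs\n")
        fh.write("\n".join(manifest_rows) + "\n")
    return paths
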