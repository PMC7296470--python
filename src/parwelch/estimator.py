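"""scikit-learn-style transformer wrapping the Welch estimator.

``WelchPSD`` turns a (n_channels, n_samples) signal matrix into a
(n_channels, n_bins) PSD matrix, so spectral features plug directly into
sklearn pipelines and model selection.  It is stateless in the learning
sense: ``fit`` only validates the input shape against the segmentation
parameters and freezes the frequency axis.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .scheduler import parallel_welch
from .types import SignalChannel, WelchConfig
from .welch import frequency_axis, plan_segments

__all__ = ["WelchPSD"]


class WelchPSD(TransformerMixin, BaseEstimator):
    """Welch power-spectral-density features for multi-channel signals.

    Each input row is one channel of ``n_samples`` samples at ``fs`` Hz;
    each output row is that channel's PSD over ``n_bins_`` frequency bins.

    Parameters
    ----------
    fs : float, default=256.0
        Sampling rate in Hz.
    seg_len : int, default=64
        Segment length L in samples.
    n_overlap : int, default=32
        Overlap between consecutive segments, 0 <= n_overlap < seg_len.
    window_kind : {"hamming", "hann", "rectangular"}, default="hamming"
    window_convention : {"symmetric", "periodic"}, default="symmetric"
    scaling : {"density", "eq6"}, default="density"
        "density" yields units^2/Hz; "eq6" omits the 1/fs factor.
    sided : {"one", "two"}, default="one"
    detrend : {"none", "constant"}, default="none"
    backend : {"serial", "process", "message-passing"}, default="serial"
    n_workers : int, default=1

    Attributes
    ----------
    freqs_ : ndarray of shape (n_bins_,)
        Frequency axis in Hz.
    n_bins_ : int
    n_segments_ : int
        Segments per channel given the fitted input length.
    n_features_in_ : int

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal(size=(4, 256))
    >>> psd = WelchPSD(fs=256.0).fit_transform(X)
    >>> psd.shape
    (4, 33)
    """

    def __init__(
        self,
        fs: float = 256.0,
        seg_len: int = 64,
        n_overlap: int = 32,
        window_kind: str = "hamming",
        window_convention: str = "symmetric",
        scaling: str = "density",
        sided: str = "one",
        detrend: str = "none",
        backend: str = "serial",
        n_workers: int = 1,
    ):
        self.fs = fs
        self.seg_len = seg_len
        self.n_overlap = n_overlap
        self.window_kind = window_kind
        self.window_convention = window_convention
        self.scaling = scaling
        self.sided = sided
        self.detrend = detrend
        self.backend = backend
        self.n_workers = n_workers

    def _config(self) -> WelchConfig:
        return WelchConfig(
            seg_len=self.seg_len,
            n_overlap=self.n_overlap,
            window_kind=self.window_kind,
            window_convention=self.window_convention,
            scaling=self.scaling,
            sided=self.sided,
            detrend=self.detrend,
        )

    def fit(self, X, y=None):
        """Validate shapes and freeze the frequency axis."""
        X = check_array(X, dtype=np.float64)
        config = self._config()
        plan = plan_segments(X.shape[1], config)
        self.n_features_in_ = X.shape[1]
        self.n_segments_ = plan.n_segments
        self.freqs_ = frequency_axis(config.seg_len, self.fs, config.sided)
        self.n_bins_ = int(self.freqs_.size)
        return self

    def transform(self, X):
        """Compute one PSD row per channel row."""
        check_is_fitted(self, "freqs_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} samples per channel but the transformer "
                f"was fitted with {self.n_features_in_}"
            )
        config = self._config()
        out = np.empty((X.shape[0], self.n_bins_), dtype=np.float64)
        for m in range(X.shape[0]):
            channel = SignalChannel(label=f"ch{m:02d}", samples=X[m], fs=self.fs)
            result = parallel_welch(
                channel, config, backend=self.backend, n_workers=self.n_workers
            )
            out[m] = result.psd
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "freqs_")
        return np.asarray([f"psd_{f:g}hz" for f in self.freqs_], dtype=object)
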