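"""Serial Welch estimator: segmentation, windows, periodograms, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parwelch import (
    ConfigError,
    SignalChannel,
    WelchConfig,
    frequency_axis,
    make_window,
    plan_segments,
    segment_bounds,
    segment_periodogram,
    welch_psd,
)
from oracle import oracle_dft, oracle_welch, oracle_window


class TestPlanSegments:
    @pytest.mark.parametrize(
        "n, expected_ns, expected_tail",
        [
            (256, 7, 0),  # the canonical 1-second EEG window
            (64, 1, 0),  # exactly one segment
            (255, 6, 31),  # trailing remainder discarded
            (257, 7, 1),
        ],
    )
    def test_segment_count_and_tail(self, defaults, n, expected_ns, expected_tail):
        plan = plan_segments(n, defaults)
        assert plan.n_segments == expected_ns
        assert plan.discarded_tail == expected_tail
        # brute-force: Ns must be the count of i with i*step + L <= N
        brute = sum(1 for i in range(n) if i * defaults.step + defaults.seg_len <= n)
        assert plan.n_segments == brute

    def test_canonical_starts(self, defaults):
        plan = plan_segments(256, defaults)
        assert plan.starts == (0, 32, 64, 96, 128, 160, 192)

    def test_short_signal_rejected(self, defaults):
        with pytest.raises(ConfigError, match="N=63.*L=64"):
            plan_segments(63, defaults)

    @given(n=st.integers(64, 2000), overlap=st.integers(0, 63))
    @settings(max_examples=50, derandomize=True)
    def test_maximality_and_coverage(self, n, overlap):
        """Start indices step uniformly; the last segment fits; one more would not."""
        config = WelchConfig(n_overlap=overlap)
        plan = plan_segments(n, config)
        step = 64 - overlap
        assert plan.starts == tuple(i * step for i in range(plan.n_segments))
        assert plan.starts[-1] + 64 <= n
        assert plan.starts[-1] + step + 64 > n
        assert 0 <= plan.discarded_tail < step


class TestSegmentBounds:
    @pytest.mark.parametrize("i, expected", [(0, (0, 63)), (4, (128, 191)), (1, (32, 95))])
    def test_worked_example_ranges(self, defaults, i, expected):
        assert segment_bounds(i, defaults) == expected

    def test_first_segment_starts_at_zero(self):
        config = WelchConfig(seg_len=100, n_overlap=17)
        assert segment_bounds(0, config) == (0, 99)

    def test_negative_index_rejected(self, defaults):
        with pytest.raises(ConfigError):
            segment_bounds(-1, defaults)


class TestMakeWindow:
    @pytest.mark.parametrize("convention", ["symmetric", "periodic"])
    def test_hamming_endpoint(self, convention):
        w = make_window("hamming", convention, 64)
        assert w.coefficients[0] == pytest.approx(0.08, abs=1e-15)

    def test_rectangular_unit_power(self):
        w = make_window("rectangular", "symmetric", 64)
        assert np.all(w.coefficients == 1.0)
        assert w.power_norm == 1.0

    def test_symmetric_odd_center_is_one(self):
        w = make_window("hamming", "symmetric", 65)
        assert w.coefficients[32] == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("kind", ["hamming", "hann", "rectangular"])
    @pytest.mark.parametrize("convention", ["symmetric", "periodic"])
    def test_matches_cosine_formula_and_power_norm(self, kind, convention):
        w = make_window(kind, convention, 64)
        np.testing.assert_allclose(w.coefficients, oracle_window(kind, convention, 64), rtol=1e-14)
        assert w.power_norm == pytest.approx(np.mean(w.coefficients**2), rel=1e-15)
        assert np.all((w.coefficients >= 0) & (w.coefficients <= 1))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            make_window("blackman", "symmetric", 64)
        with pytest.raises(ConfigError):
            make_window("hamming", "dft-even", 64)


class TestFrequencyAxis:
    def test_one_sided_canonical(self):
        freqs = frequency_axis(64, 256.0, "one")
        assert freqs.size == 33
        np.testing.assert_array_equal(freqs, np.arange(33) * 4.0)

    def test_two_sided(self):
        freqs = frequency_axis(64, 256.0, "two")
        assert freqs.size == 64
        assert freqs[-1] == 252.0

    def test_nyquist_endpoint(self):
        np.testing.assert_array_equal(frequency_axis(2, 1.0, "one"), [0.0, 0.5])

    def test_odd_length_one_sided_rejected(self):
        with pytest.raises(ConfigError):
            frequency_axis(63, 256.0, "one")


def _two_sided_eq6(seg_len=64):
    return WelchConfig(
        seg_len=seg_len,
        n_overlap=0,
        window_kind="rectangular",
        scaling="eq6",
        sided="two",
    )


class TestSegmentPeriodogram:
    def test_constant_signal_concentrates_at_dc(self):
        c = 3.0
        L = 64
        config = _two_sided_eq6(L)
        channel = SignalChannel("dc", np.full(L, c), fs=256.0)
        plan = plan_segments(L, config)
        w = make_window("rectangular", "symmetric", L)
        p = segment_periodogram(channel, plan, 0, w, config)
        assert p.values[0] == pytest.approx(c**2 * L, rel=1e-12)
        np.testing.assert_allclose(p.values[1:], 0.0, atol=1e-9)

    def test_bin_centred_cosine_power(self):
        A, k0, L, fs = 2.0, 5, 64, 256.0
        config = _two_sided_eq6(L)
        n = np.arange(L)
        channel = SignalChannel("tone", A * np.cos(2 * np.pi * k0 * n / L), fs=fs)
        plan = plan_segments(L, config)
        w = make_window("rectangular", "symmetric", L)
        p = segment_periodogram(channel, plan, 0, w, config)
        assert p.values[k0] == pytest.approx(A**2 * L / 4, rel=1e-10)
        assert p.values[L - k0] == pytest.approx(A**2 * L / 4, rel=1e-10)

    def test_matches_direct_dft_oracle(self, make_channel):
        """Seeded Gaussian segment agrees with an O(L^2) summation DFT."""
        channel = make_channel(seed=7, n_samples=64)
        config = _two_sided_eq6(64)
        plan = plan_segments(64, config)
        w = make_window("rectangular", "symmetric", 64)
        p = segment_periodogram(channel, plan, 0, w, config)
        expected = np.abs(oracle_dft(channel.samples)) ** 2 / 64
        np.testing.assert_allclose(p.values, expected, rtol=1e-10)

    def test_out_of_range_index(self, defaults, make_channel):
        channel = make_channel(seed=0)
        plan = plan_segments(256, defaults)
        w = make_window("hamming", "symmetric", 64)
        with pytest.raises(ConfigError, match="7"):
            segment_periodogram(channel, plan, 7, w, defaults)


class TestWelchPsd:
    def test_single_segment_identity(self, make_channel):
        """With N = L the PSD is exactly that one segment's periodogram."""
        config = WelchConfig()
        channel = make_channel(seed=3, n_samples=64)
        result = welch_psd(channel, config)
        plan = plan_segments(64, config)
        w = make_window("hamming", "symmetric", 64)
        p = segment_periodogram(channel, plan, 0, w, config)
        np.testing.assert_array_equal(result.psd, p.values)
        assert result.n_segments_used == 1

    def test_canonical_channel_uses_seven_segments(self, make_channel, defaults):
        result = welch_psd(make_channel(seed=1, n_samples=256), defaults)
        assert result.n_segments_used == 7
        assert result.psd.size == 33

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_direct_summation_oracle(self, make_channel, seed):
        """Full pipeline agrees with the loop-based oracle on random channels."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(64, 1025))
        channel = make_channel(seed=seed, n_samples=n)
        result = welch_psd(channel, WelchConfig())
        freqs, expected = oracle_welch(channel.samples, 256.0, 64, 32)
        np.testing.assert_array_equal(result.freqs, freqs)
        np.testing.assert_allclose(result.psd, expected, rtol=1e-10)

    def test_matches_scipy_welch(self, make_channel):
        """Independent library cross-check with identical conventions."""
        import scipy.signal

        channel = make_channel(seed=11, n_samples=1024)
        result = welch_psd(channel, WelchConfig())
        w = make_window("hamming", "symmetric", 64).coefficients
        f, p = scipy.signal.welch(
            channel.samples, fs=256.0, window=w, noverlap=32, nfft=64, detrend=False
        )
        np.testing.assert_allclose(result.freqs, f, rtol=1e-12)
        np.testing.assert_allclose(result.psd, p, rtol=1e-12)

    def test_parseval_white_noise(self):
        """Integrated one-sided density recovers the signal's mean power."""
        rng = np.random.default_rng(42)
        x = rng.normal(0.0, 1.0, 65536)
        channel = SignalChannel("noise", x, fs=256.0)
        config = WelchConfig(n_overlap=0, window_kind="rectangular")
        result = welch_psd(channel, config)
        df = 256.0 / 64
        total = np.sum(result.psd) * df
        assert total == pytest.approx(np.mean(x**2), rel=0.05)

    def test_detrend_constant_removes_dc(self, make_channel):
        channel = SignalChannel("dc", np.full(256, 5.0) , fs=256.0)
        result = welch_psd(channel, WelchConfig(detrend="constant"))
        np.testing.assert_allclose(result.psd, 0.0, atol=1e-20)


class TestInvariants:
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(64, 512))
    @settings(max_examples=30, derandomize=True)
    def test_nonnegativity_and_mean_property(self, seed, n):
        """S(k) >= 0 and lies between the min and max segment periodogram."""
        rng = np.random.default_rng(seed)
        channel = SignalChannel("x", rng.normal(size=n), fs=256.0)
        config = WelchConfig()
        result = welch_psd(channel, config)
        assert np.all(result.psd >= 0)
        plan = plan_segments(n, config)
        w = make_window("hamming", "symmetric", 64)
        phis = np.array(
            [segment_periodogram(channel, plan, i, w, config).values
             for i in range(plan.n_segments)]
        )
        assert np.all(result.psd >= phis.min(axis=0) - 1e-15)
        assert np.all(result.psd <= phis.max(axis=0) + 1e-15)

    def test_density_is_eq6_over_fs(self, make_channel):
        """Bin-wise exact: density scaling divides the bare periodogram by fs."""
        channel = make_channel(seed=5, n_samples=512)
        dens = welch_psd(channel, WelchConfig(scaling="density"))
        bare = welch_psd(channel, WelchConfig(scaling="eq6"))
        np.testing.assert_array_equal(dens.psd, bare.psd / 256.0)

    def test_sidedness_power_conservation(self, make_channel):
        """Undoing the interior-bin doubling recovers the two-sided total."""
        channel = make_channel(seed=9, n_samples=512)
        one = welch_psd(channel, WelchConfig(sided="one"))
        two = welch_psd(channel, WelchConfig(sided="two"))
        undoubled = one.psd.copy()
        undoubled[1:-1] /= 2.0
        # two-sided bins k and L-k are conjugate-symmetric for real input
        assert np.sum(two.psd) == pytest.approx(
            np.sum(undoubled) + np.sum(undoubled[1:-1]), rel=1e-12
        )
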