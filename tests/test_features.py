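import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegconsensus.features import (
    band_bins,
    de_features,
    de_from_bandpassed,
    fft_features,
    make_eeg_image,
    morlet_cycles,
    wavelet_features,
)
from eegconsensus.montage import default_layout
from eegconsensus.preprocessing import BandDefinition, HANDCRAFTED_BANDS, IMAGE_BANDS

from conftest import make_epoch


def brute_force_dft(x: np.ndarray) -> np.ndarray:
    """O(N^2) reference DFT per channel (non-negative frequencies)."""
    n = x.shape[-1]
    s = np.arange(n)
    out = np.empty((x.shape[0], n // 2 + 1), dtype=complex)
    for t in range(n // 2 + 1):
        out[:, t] = (x * np.exp(-2j * np.pi * s * t / n)).sum(axis=-1)
    return out


class TestFFTFeatures:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(8, 750))
        ref = np.abs(brute_force_dft(x))
        for band in HANDCRAFTED_BANDS.values():
            idx = band_bins(band, 750, 250.0)
            got = fft_features(x, band, 250.0)
            np.testing.assert_allclose(
                got, ref[:, idx].ravel(), rtol=1e-10, atol=1e-8
            )

    def test_constant_signal_has_no_energy_above_dc(self):
        x = np.full((3, 750), 4.2)
        feats = fft_features(x, HANDCRAFTED_BANDS["theta"], 250.0)
        np.testing.assert_allclose(feats, 0.0, atol=1e-8)

    def test_pure_alpha_sinusoid_peaks_at_375(self):
        # 10 Hz over 750 samples at 250 Hz lands exactly in bin 30 with
        # magnitude N/2 = 375
        t = np.arange(750) / 250.0
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        feats = fft_features(x, HANDCRAFTED_BANDS["alpha"], 250.0)
        idx = band_bins(HANDCRAFTED_BANDS["alpha"], 750, 250.0)
        peak = np.argmax(feats)
        assert idx[peak] == 30
        assert feats[peak] == pytest.approx(375.0, rel=1e-9)

    def test_frequency_to_bin_mapping(self):
        # f Hz -> bin f * N / fs = 3 f for N=750, fs=250
        for f in (5, 13, 31):
            band = BandDefinition("point", f - 0.01, f + 0.01)
            assert list(band_bins(band, 750, 250.0)) == [3 * f]

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no DFT bins"):
            fft_features(np.zeros((2, 750)), BandDefinition("thin", 10.05, 10.2), 250.0)

    def test_length_is_channels_times_bins(self):
        x = np.random.default_rng(0).normal(size=(62, 750))
        band = HANDCRAFTED_BANDS["theta"]  # bins 15..21 -> 7 bins
        assert fft_features(x, band, 250.0).shape == (62 * 7,)


class TestDEFeatures:
    def test_unit_energy_closed_form(self):
        # P_n = 750 makes h_n = 1/2 log(2 pi e) exactly
        x = np.ones((1, 750))
        h = de_from_bandpassed(x)
        assert h[0] == pytest.approx(0.5 * np.log(2 * np.pi * np.e), abs=1e-12)

    def test_matches_independent_reimplementation(self):
        import math

        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 750))
        h = de_from_bandpassed(x)
        for c in range(6):
            p = sum(float(v) ** 2 for v in x[c])
            expected = 0.5 * math.log(p) + 0.5 * math.log(2 * math.pi * math.e / 750)
            assert h[c] == pytest.approx(expected, abs=1e-12)

    def test_doubling_amplitude_adds_log_two(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(3, 750))
        np.testing.assert_allclose(
            de_from_bandpassed(2 * x) - de_from_bandpassed(x), np.log(2), atol=1e-12
        )

    @given(st.floats(0.2, 5.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_sign_invariant_and_scale_equivariant(self, scale):
        x = np.random.default_rng(9).normal(size=(2, 750))
        base = de_from_bandpassed(x)
        np.testing.assert_allclose(de_from_bandpassed(-x), base, atol=1e-12)
        np.testing.assert_allclose(
            de_from_bandpassed(scale * x), base + np.log(scale), atol=1e-10
        )

    def test_wide_band_gaussian_matches_gaussian_entropy(self):
        """Monte-Carlo: for white Gaussian noise of variance sigma^2 the DE
        estimate converges on the Gaussian closed form 1/2 log(2 pi e sigma^2)
        when the band covers the full spectrum."""
        sigma = 1.7
        rng = np.random.default_rng(21)
        h = de_from_bandpassed(rng.normal(scale=sigma, size=(1000, 750)))
        target = 0.5 * np.log(2 * np.pi * np.e * sigma**2)
        se = h.std(ddof=1) / np.sqrt(len(h))
        assert abs(h.mean() - target) < 3 * se

    def test_zero_power_flagged(self):
        x = np.ones((2, 750))
        x[1] = 0.0
        with pytest.raises(ValueError, match="channel"):
            de_from_bandpassed(x)

    def test_band_pipeline_runs_on_epoch(self):
        epoch = make_epoch(np.random.default_rng(3).normal(size=(4, 1000)), pre=250)
        h = de_features(epoch, HANDCRAFTED_BANDS["gamma"])
        assert h.shape == (4,)
        assert np.isfinite(h).all()


class TestWaveletFeatures:
    def test_cycle_rule_matches_printed_anchors(self):
        assert morlet_cycles(2.0) == pytest.approx(3.5)
        assert morlet_cycles(60.0) == pytest.approx(18.0)
        # linear interpolation between the anchors
        assert morlet_cycles(31.0) == pytest.approx(3.5 + (18 - 3.5) * 29 / 58)

    def test_zero_signal_gives_zero_features(self):
        epoch = make_epoch(np.zeros((2, 1000)), pre=250)
        feats = wavelet_features(epoch, IMAGE_BANDS)
        assert feats.shape == (2 * len(IMAGE_BANDS),)
        np.testing.assert_allclose(feats, 0.0, atol=1e-12)

    def test_stationary_oscillation_removed_by_baseline(self):
        """A sinusoid present in both baseline and stimulus windows should
        survive baseline subtraction at a small fraction of the power of the
        same sinusoid gated to the stimulus window only."""
        t = np.arange(1000) / 250.0
        carrier = np.sin(2 * np.pi * 10.0 * t)
        stationary = make_epoch(np.tile(carrier, (2, 1)), pre=250)
        gated_sig = np.tile(carrier, (2, 1)).copy()
        gated_sig[:, :250] = 0.0
        gated = make_epoch(gated_sig, pre=250)
        bands = {"alpha": IMAGE_BANDS["alpha"]}
        f_stat = wavelet_features(stationary, bands)
        f_gated = wavelet_features(gated, bands)
        assert np.abs(f_stat).max() < 0.2 * np.abs(f_gated).max()

    def test_missing_pre_stimulus_rejected(self):
        epoch = make_epoch(np.zeros((2, 750)), pre=0)
        with pytest.raises(ValueError, match="pre-stimulus"):
            wavelet_features(epoch, IMAGE_BANDS)


class TestEEGImage:
    layout = default_layout(16)

    def _epoch_with_amplitudes(self, amps, freq=10.0):
        t = np.arange(750) / 250.0
        sig = np.outer(amps, np.sin(2 * np.pi * freq * t))
        return sig

    def test_constant_powers_give_constant_image_inside_hull(self):
        img = make_eeg_image(self._epoch_with_amplitudes(np.ones(16)), self.layout)
        assert img.shape == (32, 32, 3)
        alpha = img[:, :, 1]
        inside = alpha[alpha != 0.0]
        ref = (375.0) ** 2  # single-bin power of a unit 10 Hz sinusoid
        np.testing.assert_allclose(inside, ref, rtol=1e-6)

    def test_zero_signal_gives_zero_image(self):
        img = make_eeg_image(np.zeros((16, 750)), self.layout)
        np.testing.assert_array_equal(img, 0.0)

    def test_linear_field_reproduced_on_grid(self):
        """With channel powers linear in the projected 2D position, the
        piecewise-cubic interpolation reproduces the field exactly, so any
        grid node inside the electrode hull must carry the field value."""
        pts = self.layout.positions_2d
        field = 2.0 + 0.5 * pts[:, 0]  # linear in x
        amps = np.sqrt(field) / 375.0  # power = (amp * N/2)^2
        img = make_eeg_image(self._epoch_with_amplitudes(amps), self.layout)
        alpha = img[:, :, 1]
        radius = 1.05 * np.abs(pts).max()
        axis = np.linspace(-radius, radius, 32)
        gx, gy = np.meshgrid(axis, axis)
        inside = alpha != 0.0
        expected = (2.0 + 0.5 * gx) * (1.0 / 375.0**2) * 375.0**2
        np.testing.assert_allclose(alpha[inside], expected[inside], rtol=1e-6)

    def test_permutation_safe(self):
        rng = np.random.default_rng(2)
        sig = self._epoch_with_amplitudes(rng.uniform(0.5, 2.0, 16))
        perm = rng.permutation(16)
        img = make_eeg_image(sig, self.layout)
        img_perm = make_eeg_image(sig[perm], self.layout.reorder(perm))
        np.testing.assert_allclose(img, img_perm, atol=1e-9)

    def test_channel_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            make_eeg_image(np.zeros((10, 750)), self.layout)
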