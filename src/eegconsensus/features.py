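"""EEG encodings: FFT band features, differential entropy, Morlet wavelet
power, and topographic EEG images.

Differential entropy (DE).  For a Gaussian signal the differential entropy
has the closed form ``1/2 log(2 pi e sigma^2)`` (nats).  Estimating the
variance of a band-limited channel from the energy of its ``N``-sample
band-passed window, ``sigma^2 ~ P_n / N``, gives the per-channel, per-band
encoding used throughout the pipeline::

    h_n = 1/2 log(P_n) + 1/2 log(2 pi e / N),   P_n = sum_t |x~_t|^2,

with ``x~`` the band-passed signal and ``N = 750`` for the standard 3 s
window at 250 Hz.  Natural logarithms throughout.

The FFT encoding keeps the magnitudes of the DFT bins falling inside a band,
concatenated channel-major into one fixed-length vector; with a 750-sample
window at 250 Hz a frequency ``f`` lands in bin ``3 f``.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator

from .montage import MontageLayout
from .preprocessing import BandDefinition, IMAGE_BANDS, bandpass
from .synthetic import EEGEpoch

__all__ = [
    "fft_features",
    "band_bins",
    "band_power_fft",
    "de_features",
    "de_from_bandpassed",
    "morlet_cycles",
    "wavelet_features",
    "make_eeg_image",
]


def _window(epoch) -> np.ndarray:
    """Channels x samples analysis window from an epoch or a raw array."""
    if isinstance(epoch, EEGEpoch):
        return np.asarray(epoch.stimulus_window, dtype=float)
    return np.asarray(epoch, dtype=float)


def band_bins(band: BandDefinition, n_samples: int, sampling_rate: float) -> np.ndarray:
    """Indices of the non-negative DFT bins whose frequency lies in
    [band.low, band.high] (inclusive)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    idx = np.nonzero((freqs >= band.low) & (freqs <= band.high))[0]
    if idx.size == 0:
        raise ValueError(
            f"band {band.name} [{band.low}, {band.high}] Hz contains no DFT bins "
            f"for N={n_samples} at {sampling_rate} Hz"
        )
    return idx


def fft_features(epoch, band: BandDefinition, sampling_rate: float = 250.0) -> np.ndarray:
    """Magnitudes of in-band DFT coefficients, concatenated across channels.

    Length is ``n_channels * n_bins_in_band``.
    """
    x = _window(epoch)
    idx = band_bins(band, x.shape[-1], sampling_rate)
    coeffs = np.fft.rfft(x, axis=-1)
    return np.abs(coeffs[:, idx]).ravel()


def band_power_fft(epoch, band: BandDefinition, sampling_rate: float = 250.0) -> np.ndarray:
    """Per-channel spectral power: sum of squared in-band DFT magnitudes."""
    x = _window(epoch)
    idx = band_bins(band, x.shape[-1], sampling_rate)
    coeffs = np.fft.rfft(x, axis=-1)
    return (np.abs(coeffs[:, idx]) ** 2).sum(axis=-1)


def de_from_bandpassed(x_band: np.ndarray) -> np.ndarray:
    """DE per channel from an already band-passed channels x N window."""
    x_band = np.asarray(x_band, dtype=float)
    n = x_band.shape[-1]
    power = (x_band**2).sum(axis=-1)
    if np.any(power == 0):
        bad = np.nonzero(power == 0)[0]
        raise ValueError(
            f"differential entropy undefined: zero band power in channel(s) {bad.tolist()}"
        )
    return 0.5 * np.log(power) + 0.5 * np.log(2 * np.pi * np.e / n)


def de_features(
    epoch,
    band: BandDefinition,
    sampling_rate: float = 250.0,
    filter_order: int = 4,
) -> np.ndarray:
    """Differential-entropy encoding of one band: band-pass the analysis
    window, then apply the Gaussian closed form per channel (nats)."""
    x = _window(epoch)
    return de_from_bandpassed(bandpass(x, band, sampling_rate, order=filter_order))


# ---------------------------------------------------------------------------
# Morlet wavelet path
# ---------------------------------------------------------------------------

#: printed anchor points of the adaptive cycle rule
_CYCLE_ANCHORS = ((2.0, 3.5), (60.0, 18.0))


def morlet_cycles(freqs) -> np.ndarray:
    """Cycle count linear in frequency: 3.5 cycles at 2 Hz to 18 at 60 Hz."""
    (f0, c0), (f1, c1) = _CYCLE_ANCHORS
    return c0 + (c1 - c0) * (np.asarray(freqs, dtype=float) - f0) / (f1 - f0)


def wavelet_features(
    epoch: EEGEpoch,
    bands: dict[str, BandDefinition],
    decimate: int = 3,
    pad_seconds: float = 0.2,
    baseline_window: tuple[float, float] = (-0.9, -0.3),
    freq_step: float = 2.0,
) -> np.ndarray:
    """Morlet time-frequency power, baseline-corrected, band-averaged.

    The signal (including its pre-stimulus second) is decimated by
    ``decimate`` before the transform, zero-padded by ``pad_seconds`` on both
    sides, convolved with Morlet wavelets whose cycle count follows
    :func:`morlet_cycles`, and the mean power of the baseline window
    (seconds relative to stimulus onset) is subtracted per channel and
    frequency.  The stimulus-window power, averaged over time and over each
    band's frequencies, is concatenated across channels into one vector of
    length ``n_channels * len(bands)``.

    Note the decimated Nyquist frequency (sampling_rate / decimate / 2)
    bounds the analysable frequencies: with the default 250 Hz / 3 the gamma
    band is only covered up to ~40 Hz.
    """
    from mne.time_frequency import tfr_array_morlet

    if epoch.pre_stimulus_samples == 0:
        raise ValueError(
            "wavelet baseline correction needs the pre-stimulus segment; "
            "got an epoch with pre_stimulus_samples=0"
        )
    fs = epoch.sampling_rate / decimate
    x = np.asarray(epoch.signal, dtype=float)[:, ::decimate]
    pre = epoch.pre_stimulus_samples // decimate + (epoch.pre_stimulus_samples % decimate > 0)
    npad = int(round(pad_seconds * fs))
    xp = np.pad(x, ((0, 0), (npad, npad)))

    f_max = min(max(b.high for b in bands.values()), 0.95 * fs / 2)
    f_min = min(b.low for b in bands.values())
    freqs = np.arange(f_min, f_max + 1e-9, freq_step)
    power = tfr_array_morlet(
        xp[None], sfreq=fs, freqs=freqs, n_cycles=morlet_cycles(freqs),
        output="power", zero_mean=True,
    )[0]
    power = power[:, :, npad : npad + x.shape[1]]

    t = (np.arange(x.shape[1]) - pre) / fs
    base = (t >= baseline_window[0]) & (t <= baseline_window[1])
    if not base.any():
        raise ValueError("baseline window falls outside the pre-stimulus segment")
    power = power - power[:, :, base].mean(axis=-1, keepdims=True)

    stim = t >= 0
    out = []
    for band in bands.values():
        fmask = (freqs >= band.low) & (freqs <= min(band.high, f_max))
        if not fmask.any():
            raise ValueError(f"band {band.name} has no analysable wavelet frequencies")
        out.append(power[:, fmask][:, :, stim].mean(axis=(1, 2)))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# Topographic EEG images
# ---------------------------------------------------------------------------

def make_eeg_image(
    epoch,
    layout: MontageLayout,
    bands: dict[str, BandDefinition] | None = None,
    grid_size: int = 32,
    sampling_rate: float = 250.0,
    fill_value: float = 0.0,
) -> np.ndarray:
    """32 x 32 x 3 topographic band-power image (theta, alpha, beta planes).

    Per band, per channel, power is the sum of squared in-band FFT
    magnitudes; the scattered channel values are interpolated onto a square
    mesh covering the projected montage (Clough-Tocher piecewise-cubic
    scattered-data interpolation, ``fill_value`` outside the electrode hull).
    """
    bands = IMAGE_BANDS if bands is None else bands
    x = _window(epoch)
    if x.shape[0] != layout.n_channels:
        raise ValueError(
            f"epoch has {x.shape[0]} channels but layout has {layout.n_channels}"
        )
    pts = layout.positions_2d
    radius = 1.05 * np.abs(pts).max()
    axis = np.linspace(-radius, radius, grid_size)
    gx, gy = np.meshgrid(axis, axis)
    planes = []
    for band in bands.values():
        values = band_power_fft(x, band, sampling_rate)
        interp = CloughTocher2DInterpolator(pts, values, fill_value=fill_value)
        planes.append(interp(gx, gy))
    return np.stack(planes, axis=-1)
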