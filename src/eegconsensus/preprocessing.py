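"""Deterministic signal conditioning between raw epoch and feature encoders.

Two named band tables are kept because the two feature paths use slightly
different canonical limits: the hand-crafted path (FFT / differential entropy
/ wavelet) uses theta 5-7, alpha 8-13, beta 14-30, gamma 31-60 Hz, while the
topographic EEG-image path uses theta 4-7, alpha 8-13, beta 13-30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .synthetic import EEGEpoch

__all__ = [
    "BandDefinition",
    "HANDCRAFTED_BANDS",
    "IMAGE_BANDS",
    "normalize_channels",
    "extract_analysis_window",
    "bandpass",
    "downsample",
    "notch_filter",
    "baseline_correct",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got [{self.low}, {self.high}]")

    def validate_for(self, sampling_rate: float) -> None:
        if self.high > sampling_rate / 2:
            raise ValueError(
                f"band {self.name} upper edge {self.high} Hz exceeds the Nyquist "
                f"frequency {sampling_rate / 2} Hz"
            )


#: FFT / DE / wavelet path
HANDCRAFTED_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 5.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 14.0, 30.0),
    "gamma": BandDefinition("gamma", 31.0, 60.0),
}

#: topographic EEG-image path (three colour planes)
IMAGE_BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
}


def _normalize_array(x: np.ndarray) -> np.ndarray:
    """Linear per-channel scaling of [min, max] onto [-1, 1]; constant
    channels map to zeros rather than dividing by a zero range."""
    x = np.asarray(x, dtype=float)
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(x)
    np.divide(2 * (x - lo), span, out=out, where=span != 0)
    return out - (span != 0)


def normalize_channels(epoch: EEGEpoch | np.ndarray) -> EEGEpoch | np.ndarray:
    """Scale each channel's range of variability linearly into [-1, 1]."""
    if isinstance(epoch, EEGEpoch):
        return replace(epoch, signal=_normalize_array(epoch.signal))
    return _normalize_array(epoch)


def extract_analysis_window(epoch: EEGEpoch, n_samples: int = 750) -> EEGEpoch:
    """Return the ``n_samples``-long stimulus-on window as a new epoch.

    The pre-stimulus segment stays available on the input epoch (the wavelet
    baseline needs it); the returned epoch has ``pre_stimulus_samples = 0``.
    """
    total = epoch.signal.shape[1]
    needed = epoch.pre_stimulus_samples + n_samples
    if total < needed:
        raise ValueError(
            f"epoch too short: expected >= {needed} samples "
            f"({epoch.pre_stimulus_samples} pre-stimulus + {n_samples}), got {total}"
        )
    window = epoch.signal[:, epoch.pre_stimulus_samples : epoch.pre_stimulus_samples + n_samples]
    return replace(epoch, signal=window, pre_stimulus_samples=0)


def bandpass(
    x: np.ndarray,
    band: BandDefinition,
    sampling_rate: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Applied forward and backward (``sosfiltfilt``), so the effective
    attenuation is twice the design order's and the phase response is zero.
    """
    band.validate_for(sampling_rate)
    sos = sps.butter(
        order, [band.low, band.high], btype="bandpass", fs=sampling_rate, output="sos"
    )
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


# ---------------------------------------------------------------------------
# Recording-chain helpers for users with real (already epoched) data.  The
# synthetic generator emits clean 250 Hz epochs, so the pipeline skips these.
# ---------------------------------------------------------------------------

def downsample(x: np.ndarray, sampling_rate: float, target_rate: float = 250.0) -> np.ndarray:
    """Polyphase resampling to ``target_rate`` along the last axis."""
    from fractions import Fraction

    frac = Fraction(target_rate / sampling_rate).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator, axis=-1)


def notch_filter(x: np.ndarray, sampling_rate: float, freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch (power-line removal) along the last axis."""
    b, a = sps.iirnotch(freq, q, fs=sampling_rate)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float), axis=-1)


def baseline_correct(x: np.ndarray, n_baseline: int) -> np.ndarray:
    """Subtract the per-channel mean of the first ``n_baseline`` samples."""
    x = np.asarray(x, dtype=float)
    return x - x[..., :n_baseline].mean(axis=-1, keepdims=True)
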