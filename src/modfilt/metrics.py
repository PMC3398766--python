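"""Acoustic property measurements for validating modulation filtering.

These are the quantitative stand-ins for the design claims made about the
two low-pass presets: temporal low-pass filtering should flatten the
envelope while preserving the long-term power spectrum, and spectral
low-pass filtering should blur harmonic structure while preserving the
temporal envelope.  Each function measures one side of those claims on a
pair of waveforms (typically input vs filtered output).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import butter, filtfilt, hilbert, welch

from .spectrogram import Waveform, stft_log_spectrogram

__all__ = [
    "temporal_envelope",
    "envelope_modulation_amplitude",
    "envelope_correlation",
    "power_spectrum_correlation",
    "harmonic_contrast",
    "log_spectrogram_correlation",
]

#: envelope smoothing cutoff, Hz — wide enough for the slow (< ~3 Hz)
#: envelopes of the harmonic fixtures, narrow enough to exclude
#: reconstruction phase noise
ENVELOPE_CUTOFF_HZ = 10.0


def temporal_envelope(wave: Waveform, cutoff: float = ENVELOPE_CUTOFF_HZ) -> np.ndarray:
    """Hilbert magnitude envelope, low-pass smoothed at ``cutoff`` Hz."""
    env = np.abs(hilbert(wave.samples))
    b, a = butter(4, cutoff / (wave.rate / 2))
    return filtfilt(b, a, env)


def envelope_modulation_amplitude(
    wave: Waveform, mod_freq: float, cutoff: float = 30.0
) -> float:
    """Amplitude of the envelope component at ``mod_freq`` Hz.

    The mean-removed smoothed envelope is Fourier-analysed and the
    magnitude at the bin nearest ``mod_freq`` returned (normalised by
    length, so comparable across equal-duration signals).
    """
    env = temporal_envelope(wave, cutoff=cutoff)
    env = env - env.mean()
    spectrum = np.abs(np.fft.rfft(env)) / env.size
    freqs = np.fft.rfftfreq(env.size, d=1 / wave.rate)
    return float(spectrum[np.argmin(np.abs(freqs - mod_freq))])


def envelope_correlation(a: Waveform, b: Waveform) -> float:
    """Pearson correlation of the two smoothed temporal envelopes."""
    return float(np.corrcoef(temporal_envelope(a), temporal_envelope(b))[0, 1])


def power_spectrum_correlation(
    a: Waveform,
    b: Waveform,
    band: tuple[float, float] = (100.0, 7000.0),
    nperseg: int = 2048,
) -> float:
    """Correlation of the long-term log power spectra within ``band``."""
    fa, pa = welch(a.samples, fs=a.rate, nperseg=nperseg)
    fb, pb = welch(b.samples, fs=b.rate, nperseg=nperseg)
    lo, hi = band
    hi = min(hi, 0.95 * a.rate / 2)
    sel = (fa > lo) & (fa < hi)
    return float(np.corrcoef(np.log(pa[sel]), np.log(pb[sel]))[0, 1])


def harmonic_contrast(
    wave: Waveform, f0: float, n_harmonics: int = 8, edge_frames: int = 100
) -> float:
    """Mean peak-to-valley log-amplitude contrast of the harmonic stack.

    Measured on the time-averaged log-spectrogram: mean level at the first
    ``n_harmonics`` harmonic frequencies minus mean level at the midpoints
    between them.  Near zero for a sound without harmonic ripple.
    """
    spec = stft_log_spectrogram(wave)
    n_harmonics = min(n_harmonics, int((0.45 * wave.rate) / f0))
    profile = spec.values[:, edge_frames:-edge_frames].mean(axis=1)
    peaks, valleys = [], []
    for h in range(1, n_harmonics + 1):
        peaks.append(profile[np.argmin(np.abs(spec.freqs - h * f0))])
        valleys.append(profile[np.argmin(np.abs(spec.freqs - (h + 0.5) * f0))])
    return float(np.mean(peaks) - np.mean(valleys))


def log_spectrogram_correlation(a: Waveform, b: Waveform) -> float:
    """Correlation of the two floored log-spectrograms, cell by cell."""
    sa = stft_log_spectrogram(a)
    sb = stft_log_spectrogram(b)
    n = min(sa.values.shape[1], sb.values.shape[1])
    return float(
        np.corrcoef(sa.values[:, :n].ravel(), sb.values[:, :n].ravel())[0, 1]
    )
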