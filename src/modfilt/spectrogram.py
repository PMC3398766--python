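"""Gaussian-window log-spectrogram analysis and iterative inversion.

This module implements the two ends of the modulation-filtering pipeline:
the forward time-frequency transform (a short-time Fourier transform with a
Gaussian window, expressed as a floored log-amplitude spectrogram) and the
recursive spectrogram-inversion algorithm (alternating-projection phase
retrieval in the style of Griffin & Lim) that turns a — possibly modified —
magnitude spectrogram back into a waveform.

Log amplitudes are natural-log throughout; decibels appear only at I/O
boundaries.  The dynamic-range floor is carried explicitly (``floor_value``)
so that exponentiation is exact at the floor and silence round-trips cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import gaussian

__all__ = [
    "Waveform",
    "SpectrogramParams",
    "LogSpectrogram",
    "stft_log_spectrogram",
    "invert_log_spectrogram",
    "control_filter",
]

# amplitude reference used when a signal is pure silence (max amplitude 0)
_SILENCE_REF = 1e-12


@dataclass(frozen=True)
class Waveform:
    """Mono audio: a finite sample vector and its sample rate in Hz."""

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("waveform must be a non-empty 1-D sample vector")
        if not np.all(np.isfinite(samples)):
            raise ValueError("waveform samples must be finite")
        if not (self.rate > 0):
            raise ValueError(f"sample rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class SpectrogramParams:
    """Analysis parameters for the Gaussian-window STFT.

    window_sd
        Standard deviation of the Gaussian analysis window, seconds.  The
        window support is truncated at +/- 3 sd.
    hop
        Frame step, seconds.  Must not exceed the 6-sd window support.
    fft_pad_factor
        Zero-padding factor applied on top of the next power of two above
        the window length.
    floor_db
        Dynamic range below the spectrogram maximum retained before
        clamping to the floor, in dB.
    """

    window_sd: float = 0.002
    hop: float = 0.001
    fft_pad_factor: int = 2
    floor_db: float = 80.0

    def __post_init__(self):
        if not (self.window_sd > 0 and self.hop > 0):
            raise ValueError("window_sd and hop must be positive")
        if self.hop > 6 * self.window_sd:
            raise ValueError("hop must not exceed the 6-sd window support")
        if not (isinstance(self.fft_pad_factor, int) and self.fft_pad_factor >= 1):
            raise ValueError("fft_pad_factor must be a positive integer")
        if not (self.floor_db > 0):
            raise ValueError("floor_db must be positive")

    def window_length(self, rate: float) -> int:
        """Odd sample count covering +/- 3 sd of the Gaussian window."""
        n = int(round(6 * self.window_sd * rate))
        return max(3, n | 1)

    def hop_samples(self, rate: float) -> int:
        return max(1, int(round(self.hop * rate)))

    def n_fft(self, rate: float) -> int:
        n_win = self.window_length(rate)
        return self.fft_pad_factor * (1 << math.ceil(math.log2(n_win)))


@dataclass(frozen=True)
class LogSpectrogram:
    """Floored natural-log magnitude spectrogram with axis calibrations.

    ``values`` has shape (n_freqs, n_frames); ``freqs`` are bin centres in Hz
    and ``times`` frame centres in seconds, both strictly increasing.  The
    originating waveform length (``n_samples``) is kept so inversion can
    return a signal of exactly the analysed duration.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    params: SpectrogramParams
    rate: float
    floor_value: float
    n_samples: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("spectrogram values must be 2-D")
        if v.shape != (len(self.freqs), len(self.times)):
            raise ValueError("axis calibrations do not match value matrix")
        object.__setattr__(self, "values", v)

    @property
    def hop_seconds(self) -> float:
        return self.params.hop_samples(self.rate) / self.rate

    @property
    def freq_spacing(self) -> float:
        """Frequency-bin spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])

    def magnitudes(self) -> np.ndarray:
        """Linear-amplitude spectrogram (exact exp of the floored log)."""
        return np.exp(self.values)

    def with_values(self, values: np.ndarray) -> "LogSpectrogram":
        return replace(self, values=np.asarray(values, dtype=np.float64))


def _make_sft(params: SpectrogramParams, rate: float) -> ShortTimeFFT:
    n_win = params.window_length(rate)
    win = gaussian(n_win, std=params.window_sd * rate, sym=True)
    return ShortTimeFFT(
        win,
        hop=params.hop_samples(rate),
        fs=rate,
        mfft=params.n_fft(rate),
        fft_mode="onesided",
    )


def stft_log_spectrogram(
    wave: Waveform, params: SpectrogramParams | None = None
) -> LogSpectrogram:
    """Gaussian-window STFT converted to a floored natural-log spectrogram.

    The floor sits ``floor_db`` below the spectrogram maximum:
    ``floor_value = ln(max) - floor_db * ln(10) / 20``.  Pure silence is
    floored against a tiny fixed amplitude reference so every cell equals
    the floor.
    """
    params = params or SpectrogramParams()
    if params.window_length(wave.rate) > wave.samples.size:
        raise ValueError(
            "analysis window is longer than the signal "
            f"({params.window_length(wave.rate)} > {wave.samples.size} samples)"
        )
    sft = _make_sft(params, wave.rate)
    S = sft.stft(wave.samples)
    amp = np.abs(S)
    amp_max = float(amp.max())
    if amp_max <= 0.0:
        amp_max = _SILENCE_REF
    floor_value = math.log(amp_max) - params.floor_db * math.log(10.0) / 20.0
    values = np.log(np.maximum(amp, math.exp(floor_value)))
    times = sft.t(wave.samples.size)
    return LogSpectrogram(
        values=values,
        freqs=np.asarray(sft.f, dtype=np.float64),
        times=np.asarray(times, dtype=np.float64),
        params=params,
        rate=wave.rate,
        floor_value=floor_value,
        n_samples=wave.samples.size,
    )


def invert_log_spectrogram(
    spec: LogSpectrogram,
    init_phase: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
    seed: int | None = 0,
    full_output: bool = False,
):
    """Recover a waveform whose spectrogram magnitude matches ``spec``.

    Alternating projections between the set of consistent spectrograms
    (least-squares inverse STFT followed by re-analysis) and the set of
    spectrograms with the target magnitude (magnitude replacement, phase
    kept).  Iteration stops when the relative Frobenius magnitude error
    drops below ``tol`` or after ``max_iter`` iterations.

    Parameters
    ----------
    init_phase
        Optional phase matrix (radians) matching ``spec.values``; when
        omitted, phases are drawn uniformly from [-pi, pi) using ``seed``.
    full_output
        When true, also return the per-iteration error trace.

    Returns
    -------
    (Waveform, achieved_error) or (Waveform, achieved_error, error_trace)
    """
    if not np.all(np.isfinite(spec.values)):
        raise ValueError("spectrogram contains non-finite values")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")

    target = spec.magnitudes()
    if init_phase is None:
        rng = np.random.default_rng(seed)
        phase = rng.uniform(-np.pi, np.pi, size=target.shape)
    else:
        phase = np.asarray(init_phase, dtype=np.float64)
        if phase.shape != target.shape:
            raise ValueError("init_phase shape does not match spectrogram")

    sft = _make_sft(spec.params, spec.rate)
    norm = float(np.linalg.norm(target))
    if norm == 0.0:  # degenerate: nothing to match
        norm = 1.0

    S = target * np.exp(1j * phase)
    trace: list[float] = []
    x = sft.istft(S, k1=spec.n_samples)
    for _ in range(max_iter):
        S_cons = sft.stft(x)
        err = float(np.linalg.norm(np.abs(S_cons) - target) / norm)
        trace.append(err)
        if err < tol:
            break
        S = target * np.exp(1j * np.angle(S_cons))
        x = sft.istft(S, k1=spec.n_samples)

    wave = Waveform(samples=x, rate=spec.rate)
    if full_output:
        return wave, trace[-1], np.asarray(trace)
    return wave, trace[-1]


def control_filter(
    wave: Waveform,
    params: SpectrogramParams | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
    seed: int | None = 0,
    match_rms: bool = True,
) -> Waveform:
    """Analysis/inversion round trip with no modulation filtering.

    Used to subject unfiltered stimuli to the same reconstruction losses as
    modulation-filtered ones, so conditions differ only in their modulation
    content.  Output duration equals the input duration exactly.
    """
    spec = stft_log_spectrogram(wave, params)
    out, _ = invert_log_spectrogram(spec, max_iter=max_iter, tol=tol, seed=seed)
    if match_rms and out.rms > 0:
        scale = wave.rms / out.rms
        out = Waveform(samples=out.samples * scale, rate=out.rate)
    return out
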