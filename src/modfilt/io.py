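"""WAV file I/O (PCM16 and float32, mono) with resampling on read."""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .spectrogram import Waveform

__all__ = ["read_wav", "write_wav", "resample"]

DEFAULT_ANALYSIS_RATE = 44100.0


def read_wav(path, rate: float | None = None, mixdown: bool = True) -> Waveform:
    """Read a WAV file as a float64 mono waveform in [-1, 1].

    Multi-channel files are averaged to mono (set ``mixdown=False`` to
    refuse them instead).  When ``rate`` is given, the signal is resampled
    to it with a polyphase filter.
    """
    fs, data = wavfile.read(str(path))
    if data.ndim == 2:
        if not mixdown:
            raise ValueError(f"{path} is not mono")
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    wave = Waveform(samples=data, rate=float(fs))
    if rate is not None and rate != wave.rate:
        wave = resample(wave, rate)
    return wave


def resample(wave: Waveform, rate: float) -> Waveform:
    frac = Fraction(rate / wave.rate).limit_denominator(1000)
    out = resample_poly(wave.samples, frac.numerator, frac.denominator)
    return Waveform(samples=out, rate=wave.rate * frac.numerator / frac.denominator)


def write_wav(path, wave: Waveform, dtype: str = "float32") -> None:
    """Write mono WAV as float32 or PCM16."""
    path = Path(path)
    if dtype == "float32":
        wavfile.write(str(path), int(round(wave.rate)), wave.samples.astype(np.float32))
    elif dtype == "pcm16":
        peak = max(1.0, float(np.max(np.abs(wave.samples))))
        scaled = np.clip(wave.samples / peak, -1.0, 1.0)
        wavfile.write(
            str(path), int(round(wave.rate)), (scaled * 32767).astype(np.int16)
        )
    else:
        raise ValueError("dtype must be 'float32' or 'pcm16'")
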