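"""Modulation power spectrum (MPS) computation, masking and filtering.

The MPS of a sound is the amplitude of the 2-D Fourier transform of its
log-spectrogram.  Its axes are temporal modulation (Hz, how fast the
envelope fluctuates) and spectral modulation (cycles/kHz, how densely
energy ripples across frequency — a harmonic stack with fundamental f0
ripples at roughly 1000/f0 cycles/kHz).  Low-pass filtering in this domain
removes cues to sound identity while preserving spectrotemporal complexity:
zeroing spectral modulations above 0.5 cycles/kHz blurs harmonic structure
but keeps the temporal envelope (the ``animal`` preset), and zeroing
temporal modulations above 4 Hz flattens the envelope but keeps the overall
power spectrum (the ``tool`` preset).

The full sound-to-sound pipeline is: log-spectrogram -> 2-D FFT -> zero the
selected modulation amplitudes -> inverse 2-D FFT -> iterative spectrogram
inversion back to a waveform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .spectrogram import (
    LogSpectrogram,
    SpectrogramParams,
    Waveform,
    invert_log_spectrogram,
    stft_log_spectrogram,
)

__all__ = [
    "ModulationSpectrum",
    "FilterSpec",
    "ModulationMask",
    "ANIMAL_PRESET",
    "TOOL_PRESET",
    "compute_mps",
    "make_mask",
    "apply_mask",
    "invert_mps",
    "mps_filter_sound",
]

#: relative tolerance on the imaginary residual when inverting an MPS
HERMITIAN_RTOL = 1e-8


@dataclass(frozen=True)
class ModulationSpectrum:
    """Centred 2-D Fourier transform of a log-spectrogram.

    ``amplitude`` and ``phase`` are aligned to ``wf_axis`` (spectral
    modulation, cycles/kHz, rows) and ``wt_axis`` (temporal modulation, Hz,
    columns); both axes are fftshift-ordered and contain 0.  ``source``
    retains the originating spectrogram (with its values) so the inverse
    transform can restore axis calibrations, floor and signal length.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    wf_axis: np.ndarray
    wt_axis: np.ndarray
    source: LogSpectrogram

    def __post_init__(self):
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if self.amplitude.shape != (len(self.wf_axis), len(self.wt_axis)):
            raise ValueError("axes do not match amplitude matrix")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")

    @property
    def complex_values(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)

    @property
    def power(self) -> float:
        """Total squared modulation amplitude."""
        return float(np.sum(self.amplitude**2))


@dataclass(frozen=True)
class FilterSpec:
    """A low-pass modulation filter: which axis, and the cutoff.

    ``lowpass_spectral`` keeps |spectral modulation| <= cutoff (cycles/kHz);
    ``lowpass_temporal`` keeps |temporal modulation| <= cutoff (Hz);
    ``none`` keeps everything.
    """

    mode: str = "none"
    cutoff: float | None = None

    _MODES = ("lowpass_spectral", "lowpass_temporal", "none")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")
        if self.mode != "none" and not (self.cutoff and self.cutoff > 0):
            raise ValueError("cutoff must be positive for a low-pass filter")


#: vocalisation identity rides on spectral modulation: low-pass at 0.5 cycles/kHz
ANIMAL_PRESET = FilterSpec(mode="lowpass_spectral", cutoff=0.5)
#: tool/action identity rides on temporal modulation: low-pass at 4 Hz
TOOL_PRESET = FilterSpec(mode="lowpass_temporal", cutoff=4.0)

PRESETS = {"animal": ANIMAL_PRESET, "tool": TOOL_PRESET, "none": FilterSpec()}


@dataclass(frozen=True)
class ModulationMask:
    """Binary (or tapered) keep-mask aligned to an MPS grid."""

    keep: np.ndarray
    wf_axis: np.ndarray
    wt_axis: np.ndarray

    def __post_init__(self):
        if self.keep.shape != (len(self.wf_axis), len(self.wt_axis)):
            raise ValueError("mask shape does not match axes")


def compute_mps(spec: LogSpectrogram) -> ModulationSpectrum:
    """2-D FFT of the log-spectrogram, centred with DC in the middle.

    The temporal-modulation axis spans +/- 1/(2*hop) Hz; the spectral-
    modulation axis is derived from the frequency-bin spacing and expressed
    in cycles/kHz (cycles per kHz of spectrogram frequency axis).
    """
    if spec.values.shape[0] < 2 or spec.values.shape[1] < 2:
        raise ValueError("spectrogram must have at least 2 rows and 2 columns")
    F = np.fft.fftshift(np.fft.fft2(spec.values))
    wf = np.fft.fftshift(np.fft.fftfreq(spec.values.shape[0], d=spec.freq_spacing / 1000.0))
    wt = np.fft.fftshift(np.fft.fftfreq(spec.values.shape[1], d=spec.hop_seconds))
    return ModulationSpectrum(
        amplitude=np.abs(F),
        phase=np.angle(F),
        wf_axis=wf,
        wt_axis=wt,
        source=spec,
    )


def make_mask(
    filt: FilterSpec,
    wf_axis: np.ndarray,
    wt_axis: np.ndarray,
    edge_width: float = 0.0,
) -> ModulationMask:
    """Build the keep-mask for a low-pass modulation filter.

    The mask depends only on |modulation frequency|, so it is Hermitian-
    symmetric by construction and always keeps DC.  A cutoff at or beyond
    the axis range filters nothing; that is flagged with a warning and the
    all-keep mask is returned.  ``edge_width`` > 0 replaces the hard edge
    with a raised-cosine taper of that width (same units as the cutoff);
    the default is a hard edge, matching a filter that literally zeroes
    amplitudes beyond the cutoff.
    """
    wf = np.asarray(wf_axis, dtype=np.float64)
    wt = np.asarray(wt_axis, dtype=np.float64)
    keep = np.ones((wf.size, wt.size))
    if filt.mode != "none":
        if filt.mode == "lowpass_spectral":
            axis, along_rows = wf, True
        else:
            axis, along_rows = wt, False
        if filt.cutoff >= np.max(np.abs(axis)):
            warnings.warn(
                f"cutoff {filt.cutoff} exceeds the modulation axis range "
                f"(max |{np.max(np.abs(axis)):.3g}|); mask keeps everything",
                stacklevel=2,
            )
            return ModulationMask(keep=keep, wf_axis=wf, wt_axis=wt)
        profile = _lowpass_profile(np.abs(axis), filt.cutoff, edge_width)
        keep = profile[:, None] * keep if along_rows else keep * profile[None, :]
    return ModulationMask(keep=keep, wf_axis=wf, wt_axis=wt)


def _lowpass_profile(abs_freq: np.ndarray, cutoff: float, edge_width: float) -> np.ndarray:
    if edge_width <= 0:
        return (abs_freq <= cutoff).astype(np.float64)
    ramp = (abs_freq - cutoff) / edge_width
    profile = 0.5 * (1 + np.cos(np.pi * np.clip(ramp, 0.0, 1.0)))
    profile[abs_freq <= cutoff] = 1.0
    return profile


def apply_mask(mps: ModulationSpectrum, mask: ModulationMask) -> ModulationSpectrum:
    """Zero (or attenuate) modulation amplitudes outside the mask.

    Phase is preserved wherever any amplitude is kept; the operation is a
    projection (idempotent for a binary mask) and preserves Hermitian
    symmetry because the mask is symmetric in |modulation frequency|.
    """
    if mask.keep.shape != mps.amplitude.shape:
        raise ValueError("mask shape does not match modulation spectrum")
    return replace(mps, amplitude=mps.amplitude * mask.keep)


def invert_mps(mps: ModulationSpectrum, rtol: float = HERMITIAN_RTOL) -> LogSpectrogram:
    """Inverse 2-D FFT back to a log-spectrogram.

    The input must be Hermitian-symmetric to within ``rtol`` (true of any
    MPS of a real spectrogram whose amplitudes were masked symmetrically);
    the imaginary residual is checked against that tolerance and discarded.
    The output inherits the source spectrogram's axes and floor.
    """
    V = np.fft.ifft2(np.fft.ifftshift(mps.complex_values))
    scale = max(float(np.max(np.abs(V.real))), 1e-300)
    resid = float(np.max(np.abs(V.imag))) / scale
    if resid > rtol:
        raise ValueError(
            f"modulation spectrum is not Hermitian-symmetric "
            f"(relative imaginary residual {resid:.2e} > {rtol:.2e})"
        )
    values = np.maximum(V.real, mps.source.floor_value)
    return mps.source.with_values(values)


def mps_filter_sound(
    wave: Waveform,
    filt: FilterSpec,
    params: SpectrogramParams | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
    seed: int | None = 0,
    match_rms: bool = True,
    edge_width: float = 0.0,
) -> Waveform:
    """Full sound-to-sound modulation filter.

    Composition of the five pipeline steps: log-spectrogram, 2-D FFT,
    amplitude masking, inverse 2-D FFT, and iterative spectrogram inversion
    (seeded random initial phase).  Output duration equals the input
    duration; by default the output is rescaled to the input RMS so that
    filtered and raw stimuli are level-matched.
    """
    spec = stft_log_spectrogram(wave, params)
    mps = compute_mps(spec)
    mask = make_mask(filt, mps.wf_axis, mps.wt_axis, edge_width=edge_width)
    filtered_spec = invert_mps(apply_mask(mps, mask))
    out, _ = invert_log_spectrogram(filtered_spec, max_iter=max_iter, tol=tol, seed=seed)
    if match_rms and out.rms > 0:
        out = Waveform(samples=out.samples * (wave.rms / out.rms), rate=out.rate)
    return out
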