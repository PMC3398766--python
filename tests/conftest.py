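"""Shared fixtures: synthetic fixture sounds and their filtered versions.

The modulation-filter pipeline (STFT -> 2-D FFT -> mask -> inverse FFT ->
iterative inversion) costs a few seconds per 2 s sound, so filtered
waveforms are computed once per session and shared between the module
tests and the acceptance suite.
"""

import numpy as np
import pytest

import modfilt as mf
from modfilt.synth import SynthSpec, synth

RATE = 16000.0


@pytest.fixture(scope="session")
def rate():
    return RATE


@pytest.fixture(scope="session")
def am_noise_wave():
    """Tool-like fixture: shaped noise with an 8 Hz sinusoidal envelope."""
    return synth(SynthSpec(kind="am_noise", am_rate=8.0, duration=2.0, seed=3), RATE)


@pytest.fixture(scope="session")
def harmonic_wave():
    """Animal-like fixture: harmonic stack on f0 = 500 Hz, slow envelope."""
    return synth(SynthSpec(kind="harmonic_voc", f0=500.0, duration=2.0, seed=4), RATE)


@pytest.fixture(scope="session")
def tool_filtered(am_noise_wave):
    """The AM-noise fixture through the 4 Hz temporal low-pass preset."""
    return mf.mps_filter_sound(am_noise_wave, mf.TOOL_PRESET, seed=11)


@pytest.fixture(scope="session")
def animal_filtered(harmonic_wave):
    """The harmonic fixture through the 0.5 cycles/kHz spectral low-pass preset."""
    return mf.mps_filter_sound(harmonic_wave, mf.ANIMAL_PRESET, seed=12)


@pytest.fixture(scope="session")
def control_filtered(harmonic_wave):
    """The harmonic fixture through the analysis/inversion round trip only."""
    return mf.control_filter(harmonic_wave, seed=13)


@pytest.fixture(scope="session")
def toy_trial_sets():
    """Rendered meaningful/meaningless trial sets from a 8-sound inventory."""
    inventory = mf.make_inventory(4, seed=5, rate=RATE)
    return mf.build_trial_sets(inventory, render_audio=True, max_iter=30)


@pytest.fixture(scope="session")
def flood_fill_oracle():
    """Brute-force connected-component labelling (BFS flood fill).

    Independent of scipy.ndimage: returns the sorted list of component
    sizes of a boolean 3-D grid under 6/18/26 connectivity.
    """

    def components(mask, connectivity):
        offsets = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    n_nonzero = sum(1 for d in (dx, dy, dz) if d)
                    if n_nonzero == 0:
                        continue
                    if connectivity == 6 and n_nonzero > 1:
                        continue
                    if connectivity == 18 and n_nonzero > 2:
                        continue
                    offsets.append((dx, dy, dz))
        mask = np.asarray(mask, dtype=bool)
        seen = np.zeros_like(mask)
        sizes = []
        for start in np.argwhere(mask):
            start = tuple(start)
            if seen[start]:
                continue
            stack, size = [start], 0
            seen[start] = True
            while stack:
                v = stack.pop()
                size += 1
                for off in offsets:
                    w = tuple(np.add(v, off))
                    if any(c < 0 or c >= s for c, s in zip(w, mask.shape)):
                        continue
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
            sizes.append(size)
        return sorted(sizes)

    return components
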