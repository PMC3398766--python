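"""Trial and session construction for the 2x2 factorial listening design.

Stimulus sequences are built from a sound inventory of two semantic
categories (animal vocalisations, tool/action sounds).  Each trial
concatenates 2 s excerpts from four different sources of one category into
an 8 s sequence.  A "meaningful" set of 32 trials (16 animal + 16 tool)
uses every inventory sound exactly once; a matched "meaningless" set
contains, trial for trial, the same sources passed through the
category-appropriate low-pass modulation filter.  A session presents the
four sound conditions (16 trials each) plus 8 silence trials per run, 72
trials per run over two runs (144 experimental trials), in a seeded random
order that is fixed across subjects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectrogram import SpectrogramParams, Waveform
from . import modulation

__all__ = [
    "CONDITIONS",
    "InventoryEntry",
    "SoundInventory",
    "Trial",
    "SessionDesign",
    "excerpt",
    "build_trial",
    "build_trial_sets",
    "build_session",
    "load_manifest",
]

#: canonical condition order used throughout (and by contrast vectors)
CONDITIONS = ("mful_a", "mful_t", "mless_a", "mless_t", "silence")

CATEGORIES = ("animal", "tool")

_TRIAL_SOURCES = 4
_EXCERPT_SECONDS = 2.0
_RAMP_SECONDS = 0.010


@dataclass(frozen=True)
class InventoryEntry:
    source_id: str
    category: str
    waveform: Waveform | None = None
    path: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")

    def load(self, rate: float | None = None) -> Waveform:
        if self.waveform is not None:
            return self.waveform
        from .io import read_wav

        return read_wav(self.path, rate=rate)


@dataclass(frozen=True)
class SoundInventory:
    """Ordered collection of category-labelled sounds with unique ids."""

    entries: tuple

    def __post_init__(self):
        entries = tuple(self.entries)
        ids = [e.source_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("source_ids must be unique")
        object.__setattr__(self, "entries", entries)

    def by_category(self, category: str) -> list:
        return [e for e in self.entries if e.category == category]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Trial:
    """One 8 s stimulus sequence (or a silence trial).

    ``waveform`` may be None for design-level trials whose audio has not
    been rendered; silence trials never carry audio.
    """

    condition: str
    source_ids: tuple = ()
    category: str | None = None
    waveform: Waveform | None = None

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.condition == "silence":
            if self.source_ids:
                raise ValueError("silence trials carry no sources")
        else:
            if len(self.source_ids) != _TRIAL_SOURCES:
                raise ValueError("sound trials comprise exactly 4 sources")
            if len(set(self.source_ids)) != _TRIAL_SOURCES:
                raise ValueError("the 4 sound sources must be different")


@dataclass(frozen=True)
class SessionDesign:
    """Two ordered runs of 72 trials each plus the seed that ordered them."""

    runs: tuple
    seed: int

    def condition_counts(self, run_index: int) -> dict:
        counts = {c: 0 for c in CONDITIONS}
        for trial in self.runs[run_index]:
            counts[trial.condition] += 1
        return counts

    @property
    def n_experimental_trials(self) -> int:
        return sum(len(run) for run in self.runs)


def excerpt(wave: Waveform, duration: float = _EXCERPT_SECONDS) -> Waveform:
    """Cut the most energetic contiguous window of ``duration`` seconds.

    The window maximising short-term energy is selected by exhaustive
    cumulative-energy scan (a proxy for the original curation step of
    keeping the characteristic part of each recording), then 10 ms
    raised-cosine onset/offset ramps are applied.
    """
    n_out = int(round(duration * wave.rate))
    n = wave.samples.size
    if n < n_out:
        raise ValueError(
            f"input ({n / wave.rate:.3f} s) shorter than requested excerpt "
            f"({duration:.3f} s)"
        )
    if n == n_out:
        start = 0
    else:
        energy = np.concatenate([[0.0], np.cumsum(wave.samples**2)])
        window_energy = energy[n_out:] - energy[: n - n_out + 1]
        start = int(np.argmax(window_energy))
    out = wave.samples[start : start + n_out].copy()
    return Waveform(samples=_apply_ramps(out, wave.rate), rate=wave.rate)


def _apply_ramps(x: np.ndarray, rate: float) -> np.ndarray:
    ramp = int(round(_RAMP_SECONDS * rate))
    if ramp > 1 and 2 * ramp <= x.size:
        fade = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        x[:ramp] *= fade
        x[-ramp:] *= fade[::-1]
    return x


def build_trial(
    sounds: list,
    category: str,
    condition: str,
    source_ids: list | None = None,
) -> Trial:
    """Concatenate four 2 s excerpts of one category into an 8 s trial.

    ``sounds`` may be InventoryEntry objects (ids and category checked
    against the entries) or Waveforms with ``source_ids`` given explicitly.
    Excerpts already carry 10 ms raised-cosine edge ramps, so butt-joining
    them is click-free and keeps the trial at exactly 4 x 2 s.
    """
    if len(sounds) != _TRIAL_SOURCES:
        raise ValueError("a trial requires exactly 4 sounds")
    if isinstance(sounds[0], InventoryEntry):
        cats = {e.category for e in sounds}
        if cats != {category}:
            raise ValueError(f"all sources must be category {category!r}, got {cats}")
        source_ids = [e.source_id for e in sounds]
        waves = [e.load() for e in sounds]
    else:
        if source_ids is None or len(source_ids) != _TRIAL_SOURCES:
            raise ValueError("source_ids required when passing raw waveforms")
        waves = list(sounds)
    rates = {w.rate for w in waves}
    if len(rates) != 1:
        raise ValueError("all sounds in a trial must share one sample rate")
    samples = np.concatenate([w.samples for w in waves])
    return Trial(
        condition=condition,
        source_ids=tuple(source_ids),
        category=category,
        waveform=Waveform(samples=samples, rate=rates.pop()),
    )


def build_trial_sets(
    inventory: SoundInventory,
    params: SpectrogramParams | None = None,
    render_audio: bool = False,
    seed: int | None = None,
    max_iter: int = 50,
    tol: float = 1e-3,
    presets: dict | None = None,
):
    """Build the matched meaningful / meaningless trial sets.

    Every inventory sound is used exactly once across the meaningful
    trials; meaningless trial i contains modulation-filtered versions
    (category preset: spectral low-pass for animals, temporal low-pass for
    tools) of exactly the sources of meaningful trial i.  Grouping of
    sources into trials follows inventory order, or a seeded shuffle within
    category when ``seed`` is given.

    With ``render_audio=False`` (default) the trials are design-level
    (waveform None); rendering excerpts, filtering every sound and
    concatenating is substantially slower and opt-in.

    Returns (meaningful, meaningless): two equal-length trial lists,
    animal trials first.
    """
    presets = presets or {
        "animal": modulation.ANIMAL_PRESET,
        "tool": modulation.TOOL_PRESET,
    }
    rng = np.random.default_rng(seed) if seed is not None else None
    meaningful, meaningless = [], []
    for category, mful_cond, mless_cond in (
        ("animal", "mful_a", "mless_a"),
        ("tool", "mful_t", "mless_t"),
    ):
        entries = inventory.by_category(category)
        if not entries or len(entries) % _TRIAL_SOURCES:
            raise ValueError(
                f"{category} inventory size {len(entries)} is not divisible by 4"
            )
        order = list(range(len(entries)))
        if rng is not None:
            rng.shuffle(order)
        for g in range(len(entries) // _TRIAL_SOURCES):
            group = [entries[j] for j in order[4 * g : 4 * g + 4]]
            ids = tuple(e.source_id for e in group)
            if render_audio:
                raw = [excerpt(e.load()) for e in group]
                filtered = [
                    _apply_ramps(
                        modulation.mps_filter_sound(
                            w, presets[category], params=params,
                            max_iter=max_iter, tol=tol,
                            seed=_render_seed(seed, ids[k]),
                        ).samples,
                        w.rate,
                    )
                    for k, w in enumerate(raw)
                ]
                filtered = [Waveform(samples=s, rate=raw[0].rate) for s in filtered]
                meaningful.append(
                    build_trial(raw, category, mful_cond, source_ids=ids)
                )
                meaningless.append(
                    build_trial(filtered, category, mless_cond, source_ids=ids)
                )
            else:
                meaningful.append(
                    Trial(condition=mful_cond, source_ids=ids, category=category)
                )
                meaningless.append(
                    Trial(condition=mless_cond, source_ids=ids, category=category)
                )
    return meaningful, meaningless


def _render_seed(seed: int | None, source_id: str) -> int:
    base = 0 if seed is None else int(seed)
    return (base * 1000003 + (hash(source_id) & 0x7FFFFFFF)) % (2**31)


def build_session(
    trial_sets,
    n_silence_per_run: int = 8,
    seed: int = 0,
) -> SessionDesign:
    """Order the trials into two runs of a fixed seeded random order.

    Each run presents the complete meaningful + meaningless trial sets plus
    ``n_silence_per_run`` silence trials, shuffled by ``seed`` (the same
    order for every subject, a different order per run).
    """
    meaningful, meaningless = trial_sets
    if not meaningful or len(meaningful) != len(meaningless):
        raise ValueError("meaningful and meaningless trial sets must match")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(2):
        trials = list(meaningful) + list(meaningless) + [
            Trial(condition="silence") for _ in range(n_silence_per_run)
        ]
        order = rng.permutation(len(trials))
        runs.append(tuple(trials[i] for i in order))
    return SessionDesign(runs=tuple(runs), seed=seed)


def load_manifest(path: str | Path) -> SoundInventory:
    """Read a sound inventory manifest: CSV of source_id, category, path."""
    path = Path(path)
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            wav = row["path"]
            if not Path(wav).is_absolute():
                wav = str(path.parent / wav)
            entries.append(
                InventoryEntry(
                    source_id=row["source_id"], category=row["category"], path=wav
                )
            )
    return SoundInventory(entries=tuple(entries))
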