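# Methods

## Modulation filtering

The pipeline operates on the natural-log magnitude spectrogram of a mono
waveform. Decibels appear only at I/O boundaries; internally one log
convention is used throughout.

**Spectrogram.** Gaussian-window STFT (window support truncated at ±3 sd,
odd length; `scipy.signal.ShortTimeFFT`). Defaults: window sd 2 ms, hop
1 ms, FFT padding factor 2, floor 80 dB below the spectrogram maximum.
These values resolve the modulation ranges the filters act on: at a 2 ms
window the frequency resolution (~80 Hz sd) separates harmonics of
vocal-range fundamentals (f₀ ≥ 250 Hz), i.e. spectral modulations up to
several cycles/kHz; a 1 ms hop puts the temporal-modulation Nyquist at
500 Hz, far above the 4 Hz cutoff; a 2 s analysis window gives 0.5 Hz
temporal-modulation resolution. The floor is clamped, and the floor value
carried on the object so `exp()` is exact at the floor and silence
round-trips to silence; pure silence is floored against a fixed 1e-12
amplitude reference.

**MPS.** Centred 2-D FFT of the log-spectrogram. The temporal axis is in
Hz (from the hop), the spectral axis in cycles/kHz (from the
frequency-bin spacing divided by 1000; the internal unit conversion from
cycles/Hz is exactly that factor). Amplitude/phase are stored separately;
Hermitian symmetry of the transform of a real matrix is relied on and
checked (relative imaginary residual tolerance 1e-8 on inversion — a
numerical, not scientific, tolerance).

**Masks.** Low-pass masks are hard binary by default, matching a filter
that literally zeroes amplitudes beyond the cutoff; a raised-cosine edge
(`edge_width`) exists but defaults off. Masks depend only on the absolute
modulation frequency, so they are Hermitian-symmetric by construction and
always keep DC — overall level survives filtering. A cutoff at or beyond
the axis range degenerates to the all-keep mask with a warning rather
than an error.

**Inversion.** Griffin–Lim-style alternating projections: least-squares
inverse STFT (dual-window synthesis) followed by re-analysis and
magnitude replacement. Defaults max_iter 50, tol 1e-3 relative Frobenius
magnitude error, initial phase uniform random from a seed. The projection
distance is non-increasing across iterations (tested). The originating
sample count is carried on the spectrogram so reconstruction returns
exactly the analysed duration.

**Level matching.** `mps_filter_sound` rescales the output to the input
RMS by default (`match_rms`), so filtered and raw stimuli are presented
at matched level; disable to study raw reconstruction gain.

## Stimulus construction

Excerpts are the contiguous 2 s window of maximal energy (cumulative-sum
scan) — a deterministic proxy for the human judgement of keeping the
characteristic part of a recording; the selection strategy is the one
genuinely open design choice here and is isolated in `excerpt`. Excerpts
get 10 ms raised-cosine onset/offset ramps. Trials butt-join four ramped
excerpts: because each joint is already faded on both sides this is
click-free while keeping the trial at exactly 4 × 2 s (an overlapped
crossfade would shorten it by 30 ms and break the duration invariant).

Trial sets partition each category's inventory into groups of four in
manifest order (or a seeded shuffle); each group yields one meaningful
trial and one matched meaningless trial whose four sources are the same
recordings passed through the category preset (spectral low-pass for
animal, temporal low-pass for tool). Every inventory sound is used
exactly once across the meaningful set. Waveform rendering is opt-in
(`render_audio`): the design level (labels, source assignments, orders)
is cheap, while filtering every sound costs seconds per sound.

A session presents the complete 32+32 trial set plus 8 silence trials in
each of two runs (72 per run, 144 experimental trials); the order is a
seeded permutation, fixed across subjects, drawn independently per run.

## Synthetic fixtures

`harmonic_voc` plants spectral modulation at 1000/f₀ cycles/kHz (harmonic
stack, 1/h amplitude roll-off, 5 Hz vibrato at ±1 % f₀, 2 Hz amplitude
contour of depth 0.4); `am_noise` plants temporal modulation at
`am_rate` (sinusoidal envelope of depth 0.9 on band-limited noise with a
fixed smooth spectral tilt, so the long-term spectrum has structure that
a correlation can measure); `click_train` is a transient alternative.
Inventory generation jitters f₀ over 250–700 Hz and envelope rates over
6–12 Hz per seed.

What these fixtures do *not* emulate: the within-category acoustic
diversity, nonstationarity and recording noise of natural sounds.
Passing tests therefore demonstrate that the filters act on modulation
content as specified — not that filtered natural recordings are
perceptually meaningless; that judgement requires listeners.

## Measurements

Temporal envelopes are Hilbert magnitudes smoothed at 10 Hz — wide enough
for the fixtures' sub-3 Hz envelope content, narrow enough to exclude
reconstruction phase noise. Envelope modulation depth is the rFFT
magnitude of the mean-removed envelope at the nearest bin. Long-term
spectra are Welch log-PSDs correlated over 100 Hz–7 kHz (clipped at 95 %
of Nyquist). Harmonic contrast is the mean log-amplitude difference
between the first eight harmonic frequencies and the midpoints between
them, on the time-averaged spectrogram excluding 100 edge frames.

## Behavioural statistics

The matching task is 6-AFC, so chance is 1/6. Above-chance performance
uses the exact one-tailed upper-tail binomial probability
P(X ≥ k | n, 1/6) at α = 0.05 (the question is directional). Both the
pooled rule (48 trials) and the per-category rule (24 trials) are
provided; on the published patient table the pooled rule yields 6/9
above-chance patients and the per-category rule reproduces the printed
chance-level flags exactly, so the two conventions are indistinguishable
on these data. The paired animal-tool comparison is a Student-t interval
on the differences (n−1 df). Values are reported at full precision and
rounded to 1 dp only at the reporting boundary. Control-group raw scores
are not published; their summary statistics are carried as constants, so
control-side analyses beyond the printed means (e.g. the bootstrap-vs-t
question for their CI) are out of reach.

## Map statistics

Group comparison is a voxel-wise two-sample t with unequal variances and
Welch–Satterthwaite degrees of freedom, returned as a df map; the p→t
cluster-forming threshold is evaluated voxel-wise against that df map.
Cluster formation uses `scipy.ndimage.label`; connectivity defaults to 18
(faces+edges, a common convention) and is configurable (6/26). Extent
correction by random-field theory is not implemented; a permutation
max-extent null (`cluster_extent_null`) serves synthetic experiments
instead.

Voxel categorisation is a pure function of the sign of the control
group's *signed forward effect* — the most literal reading of "direction
of activation": magenta where the control effect is negative (the group
difference is plausibly controls activating in the reverse contrast),
cyan where positive (plausibly patient over-activation in the forward
contrast), and exact zeros labelled indeterminate rather than silently
coloured. Foci are user-supplied mm coordinates (JSON config) mapped to
the nearest voxel through the affine; they are configuration, not
package constants, since the canonical six-focus set derives from prior
work in another stereotactic convention.

The synthetic map generator produces i.i.d. Gaussian subject maps with
spherical additive effects on an MNI-like centred diagonal affine.
Problem sizes used by the test suite and the reproduction script —
22³ ≈ 10⁴ voxels for null calibration (10 subjects per group), 24³ with
groups of 9 and 22 for planted-effect recovery — were chosen as the
smallest grids at which the calibration check (5 % ± 2 %) is stable.

## Known limitations

* Griffin–Lim inversion converges to a local magnitude-consistent
  solution; reconstruction quality depends on window overlap (the 2 ms /
  1 ms defaults give dense overlap and spectrogram correlations > 0.95).
* Binary masks introduce ringing at the modulation cutoff; the optional
  raised-cosine edge trades ringing for transition width.
* Filtering operates on the log-magnitude spectrogram; linear-domain
  marginals (envelope, spectrum) are preserved approximately, which is
  what the correlation-based properties quantify.
* The session randomiser reproduces orders internally per seed; the
  original experiment's presentation order is not recoverable.
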