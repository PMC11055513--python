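# Methods

This note documents the models, defaults and numerical choices behind
`itdeeg`, and what the synthetic-data tests do and do not establish about
real recordings.

## Stimulus synthesis

**SAM tones.** A sinusoidally amplitude-modulated tone is
`m(t) · sin(2π f_c t)` with the raised-cosine modulator
`m(t) = ½(1 − cos 2π f_m t)` (100% depth, unit peak). The −cos phase puts a
modulator trough at t = 0 and at every integer multiple of the modulation
period; because every default (f_m, segment length) pair makes
`f_m × 2 s` an integer, the nominal segment boundaries coincide exactly
with envelope troughs. Interaural switches are applied at the trough sample
nearest the nominal boundary, so the transition itself carries no monaural
transient; segment annotations keep the nominal boundaries.

* *Fine-structure ITD*: during T2 the lead ear's carrier phase is advanced
  by the IPD (default π/2); the envelope is identical in both ears
  throughout. IPDs outside (−π, π] are rejected.
* *Envelope ITD*: the lead ear's modulator is advanced in phase by the ITD
  (default 500 µs) while the carrier stays interaurally identical — a
  modulator phase shift, not a whole-waveform delay, so no fine-structure
  cue is introduced. ITDs of at least half a modulation period are rejected
  as ambiguous.
* The right ear leads by default (`lead_ear`); the choice affects sign
  only.

**Filtered clicks.** Single-sample positive impulses at the pulse rate are
band-pass filtered to 3000–5000 Hz with a 4th-order Butterworth applied
forward–backward. Zero-phase filtering keeps the dichotic delay purely a
pulse-timing offset, and makes the −6 dB amplitude points of the effective
response (|H|²) fall exactly at the corner frequencies, i.e. a passband
centered at 4 kHz. During T2 the lagging ear's pulses are delayed by the
IPTD (default 500 µs). The click sequence is T1, T2, T4 — there is no
return-to-diotic segment, hence no inward-change (ACC2) event.

**Masking noise** (clicks only; the SAM experiments deliberately carry
none): per ear an independent white realization (seeds `seed`, `seed+1`)
is shaped in the frequency domain — flat to 200 Hz, −3 dB/octave in power
above, zeroed above 1 kHz — then passed through a causal 5th-order 1-kHz
Butterworth low-pass and gated with 50-ms raised-cosine ramps. Its RMS sits
35 dB below the stimulus level, mirroring a 75 dB SPL stimulus with
40 dB SPL noise.

**Levels and ramps.** Calibration to SPL is hardware-bound, so levels are
digital: RMS over the stimulation part is set to `level_dbfs`
(default −20 dBFS), with the click/noise difference preserved. Onset and
offset of the stimulation part get 20-ms raised-cosine ramps (the ramp
duration is configurable).

**Verification operators.** Envelope ITD is the parabolic-refined peak lag
of the cross-correlated Hilbert envelopes; carrier IPD is the phase of the
cross-spectrum at f_c over an integer number of carrier cycles; modulation
rate is the largest non-DC peak of the envelope amplitude spectrum;
broadband ITD cross-correlates the raw waveforms. Windows shorter than
5 modulation (or carrier) periods raise an unreliable-estimate error.
The noise-slope estimator aggregates a Welch PSD into third-octave bands
whose edges lie inside the fit range and regresses band power (dB) on
log₂(center): log-spaced bands weight each octave equally, so the estimate
is not dominated by the low-pass corner at the top of the range (measured:
3.14 dB/octave over 200–1000 Hz against the 3 dB/octave design target).
Passband edges use a moving-maximum envelope of the magnitude spectrum
(width 400 Hz, wider than any default harmonic spacing) and interpolate the
−6 dB crossings; the moving maximum widens both edges symmetrically and
leaves the band center unbiased.

## Synthetic EEG

The generative model is deliberately phenomenological — it produces
recordings whose *analysis-level* structure matches the paradigm, not a
biophysical simulation:

```
r_c(t) = −gain_c · s(t) + noise_c(t)          (per channel, µV)
```

`s(t)` is the evoked source expressed at Cz against the 4-channel average;
the sign encodes the polarity inversion of the vertex response at
mastoid/inion sites, so re-referencing recovers +s(t) on the virtual-Cz
trace with unit gain at the default `channel_gains = (1, 1, 1, 1)`.

* **Transients**: each of onset / ACC1 / ACC2 / offset contributes a sum of
  three signed Gaussians (P1, N1, P2) with per-event latencies and
  amplitudes defaulting to the fine-structure experiment's group means
  (e.g. onset P1/N1/P2 = 1.684/−3.324/3.946 µV at 42/114/211 ms); widths
  default to 15/20/30 ms SD, chosen so each peak sits comfortably inside
  its detection window while remaining smooth. Gaussians are truncated at
  ±4 SD. Whole-complex latency jitter per trial defaults to 3 ms SD —
  enough to be realistic, small against the peak widths.
* **Steady state**: a cosine at the modulation rate, amplitude default
  0.187 µV, present only during stimulation. Optional desynchronization
  multiplies it by `1 − exp(−(t − t_event)/τ)` after each transient
  (τ = 0.3 s default) — a qualitative emulation of the post-transient
  suppression seen in time-frequency maps, not a quantitative model.
* **Noise**: white (10 µV SD per channel) plus 1/f pink (10 µV SD,
  exponent 1), independent per channel; optional mains line. These defaults
  make single-trial peaks invisible but 60-trial averages clean.
* **Artifacts**: designated trials receive a 250-µV square pulse on all
  channels, guaranteed to trip the ±200 µV rejection.
* 60 trials per condition, 0.5-s inter-trial gap, seeded and fully
  deterministic; the configuration and the clean source trace are embedded
  in the recording as ground truth.

What passing tests show: the extraction chain recovers known parameters
under realistic noise at the study's trial count. What they do not show:
robustness to real-world nonstationarities (drifting electrode impedance,
alpha bursts, ocular artifacts with non-square morphology, inter-subject
topography differences) — none of these are modeled.

## Preprocessing

Fixed order, each step logged: segment (−0.2 s pre-stimulus to the end of
the silence) → 0.1–1000 Hz 2nd-order Butterworth → baseline (mean of the
final 1 s, which lies after stimulus offset) → ±200 µV whole-trial
rejection on all recording channels → re-reference to the 4-channel
average with a virtual-Cz trace = −(channel mean) → average over surviving
trials. Filtering happens after segmentation; the pre-stimulus interval and
the silent tail absorb edge transients.

Numerical choices:

* Both Butterworth filters are applied forward–backward so group delay
  cannot shift peak latencies; the effective order doubles (the stopband
  tests assert |H|² against the closed form, with bilinear prewarping).
* At simulation rates where the nominal 1000-Hz corner reaches Nyquist
  (e.g. the 1-kHz rate used throughout the tests, mirroring the paradigm's
  own minimum-rate recommendation) the band-pass degrades to the 0.1-Hz
  high-pass alone.
* Re-referencing is idempotent: a second application is a no-op once the
  virtual-Cz trace exists.
* Rejection uses strict inequality (|v| > 200 µV) and masks whole trials;
  zero surviving trials raise an explicit error.

A consequence of the 0.1-Hz high-pass worth knowing: an 8.2-s epoch has its
fundamental at 0.12 Hz, which a 2nd-order zero-phase high-pass attenuates
by ~30%. Whole-epoch comparison of the chain output against a raw injected
trace therefore shows ~5% RMS deviation *by design* (drift removal). The
fidelity measure used in the tests compares each event-template window with
its mean removed; residual distortion is then 0.1–0.3%, asserted < 2%.

## Peak picking

P1 = global maximum in 10–85 ms, N1 = global minimum in 85–160 ms,
P2 = global maximum in 160–300 ms after each event, on the virtual-Cz trace
of the 0.1–30 Hz filtered average. Global (not first-local) extrema at the
extremal sample, no sub-sample interpolation — the behavior of an automatic
classifier on densely sampled data. Window-edge extrema are flagged. N1
amplitude keeps its signed (negative) value; N1P2 = P2 − N1 is therefore
positive. A noise-floor reference distribution is built by applying the
same picking to windows anchored at random times inside the silent T4
segment; change responses with amplitudes in that distribution are what the
paradigm calls "at the noise floor".

## ASSR

Rectangular-window single-sided DFT amplitude of the condition-averaged
trace (phase-locked response), mean removed, normalized so a window-spanning
sinusoid of amplitude A yields A at its bin. 2-s segment windows put every
default rate (40/80/160/320 Hz) exactly on a bin (resolution 0.5 Hz); the
whole-presentation window has 0.125 Hz resolution. No significance
statistic is attached — amplitudes only. For *recovery* of an injected
amplitude the stimulation-only window (T123/T12) is the right choice: the
component spans that window exactly, whereas a whole-presentation window
includes the silence and scales the bin by stimulation/total (6/8) — a
geometric fact, not an estimator defect.

## Time-frequency analysis

Complex Morlet kernel `exp(2iπft)·exp(−t²/2σ²)`, σ = n/(2πf), n = 6,
sampled on t = −1…1 s. The raw formula has no normalization; kernels are
scaled by 2/Σ(Gaussian) before convolution so a unit sinusoid at f gives a
unit-height ridge, making magnitudes comparable across frequency (labelled
arbitrary units; an L2 normalization was considered and rejected because it
does not yield an interpretable ridge height). Edges are reflect-padded and
the outer 3σ(f) band is flagged edge-contaminated. The frequency resolution
follows the Gaussian response `exp(−2π²σ(f)²(f−f0)²)`, SD ≈ f/n, which the
tests assert within 10%. Default grid: 2–80 Hz in 1-Hz steps.

## Statistics

Descriptive summaries (mean/median/SD/n) plus two-sided paired t-tests for
every level pair of a factor, with the Bonferroni multiplier equal to the
number of pairs — except that two-level factors receive no correction.
Zero-variance difference pairs are flagged degenerate and reported with
p = 1. A full repeated-measures GLM with sphericity correction is
deliberately out of scope; the pairwise tests cover the reported pairwise
conclusions. Deposited per-participant tables are consumed through a
configurable column mapping.

## Problem sizes in the test suite

Simulated recovery studies run at a 1-kHz simulation rate (the paradigm's
recommended clinical minimum): 200 datasets of 60 trials for the
peak-recovery benchmarks; 60–600 datasets for steady-state amplitude
recovery depending on the amplitude (smaller amplitudes need more data —
the 1-nV tolerance at 0.02 µV sits at the statistical limit of the study
conditions, see the test's docstring); 60 datasets for the
change-response-absence comparison (two-sample KS at α = 0.01). All
simulations are seeded; reported example numbers are actual outputs.

## Known limitations

* The synthetic EEG is a signal-plus-noise model with per-channel gains; no
  volume conduction, no realistic topography, no cochlear-implant
  stimulation artifacts.
* EDF files can be imported (via mne) but not exported; recordings
  serialize to npz + JSON.
* The steady-state desynchronization model (exponential recovery gate) is
  illustrative; its parameters are not fitted to data.
* Stimulus levels are digital (dBFS); playback calibration is out of
  scope.
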