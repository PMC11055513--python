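"""Binaural EEG stimulus synthesis.

Three stimulus families probe interaural-time-difference (ITD) sensitivity:

* ``ITDFS_SAM`` — sinusoidally amplitude-modulated (SAM) tones whose *carrier*
  acquires an interaural phase difference (IPD) during the dichotic segment,
  i.e. an ITD carried by the temporal fine structure.
* ``ITDENV_SAM`` — high-carrier SAM tones whose *envelope* is shifted between
  the ears (ITD_ENV) while the carrier stays interaurally in phase.
* ``IPTD_CLICKS`` — band-pass filtered click trains (3–5 kHz) whose pulse
  timing differs between the ears (IPTD), mimicking bilateral cochlear-implant
  stimulation; presented in uncorrelated low-pass masking noise.

Each presentation follows a fixed segment sequence: T1 diotic, T2 dichotic,
T3 return-to-diotic (SAM only) and T4 silence, 2 s each by default.  The
interaural switch is applied at the envelope trough nearest the nominal
segment boundary so that the change itself carries no monaural onset cue.

The module also provides measurement operators (envelope ITD, carrier IPD,
modulation rate, broadband ITD, spectral slope, passband edges) used for
verification of generated waveforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "Experiment",
    "SequenceLayout",
    "StimulusSpec",
    "StereoSignal",
    "make_stimulus",
    "make_sam_itdfs",
    "make_sam_itdenv",
    "make_filtered_clicks",
    "make_masking_noise",
    "measure_envelope_itd",
    "measure_carrier_ipd",
    "measure_modulation_rate",
    "measure_broadband_itd",
    "spectral_slope_db_per_octave",
    "passband_edges",
    "write_wav",
    "read_wav",
    "UnreliableEstimateError",
]

#: band limits of the filtered click trains, Hz
CLICK_BAND_HZ = (3000.0, 5000.0)
#: Butterworth order of the click band-pass (applied forward-backward)
CLICK_FILTER_ORDER = 4


class UnreliableEstimateError(ValueError):
    """Raised when a measurement window is too short for a stable estimate."""


class Experiment(str, Enum):
    ITDFS_SAM = "itdfs_sam"
    ITDENV_SAM = "itdenv_sam"
    IPTD_CLICKS = "iptd_clicks"


@dataclass(frozen=True)
class SequenceLayout:
    """Segment durations of one stimulus presentation, seconds.

    T1 = diotic, T2 = dichotic, T3 = return to diotic (0 for click trains),
    T4 = silence.
    """

    t1_s: float = 2.0
    t2_s: float = 2.0
    t3_s: float = 2.0
    t4_s: float = 2.0

    @property
    def total_s(self) -> float:
        return self.t1_s + self.t2_s + self.t3_s + self.t4_s

    @property
    def stim_s(self) -> float:
        """Duration of the stimulation part (everything before the silence)."""
        return self.t1_s + self.t2_s + self.t3_s

    @classmethod
    def for_experiment(cls, experiment: Experiment) -> "SequenceLayout":
        if experiment is Experiment.IPTD_CLICKS:
            return cls(2.0, 2.0, 0.0, 2.0)
        return cls(2.0, 2.0, 2.0, 2.0)

    def annotations(self) -> list[tuple[str, float, float]]:
        out = []
        t = 0.0
        for label, dur in (("T1", self.t1_s), ("T2", self.t2_s),
                           ("T3", self.t3_s), ("T4", self.t4_s)):
            if dur > 0:
                out.append((label, t, t + dur))
                t += dur
        return out


@dataclass
class StimulusSpec:
    """Full parameterization of one EEG stimulus presentation.

    Exactly one of ``ipd`` / ``itd_env_us`` / ``iptd_us`` is active, matching
    ``experiment``.  ``f_m`` is the modulation frequency for SAM tones and the
    pulse rate (pps) for click trains (alias :attr:`pulse_rate`).
    """

    experiment: Experiment = Experiment.ITDFS_SAM
    f_c: float = 400.0
    f_m: float = 40.0
    ipd: float | None = None           # carrier IPD in T2, radians (ITDFS)
    itd_env_us: float | None = None    # envelope ITD in T2, µs (ITDENV)
    iptd_us: float | None = None       # pulse-timing ITD in T2, µs (clicks)
    layout: SequenceLayout | None = None
    fs: float = 20000.0
    level_dbfs: float = -20.0          # digital RMS level re full scale
    lead_ear: str = "right"
    ramp_ms: float = 20.0
    seed: int | None = None            # used only where noise is involved

    def __post_init__(self) -> None:
        self.experiment = Experiment(self.experiment)
        if self.layout is None:
            self.layout = SequenceLayout.for_experiment(self.experiment)
        if self.lead_ear not in ("left", "right"):
            raise ValueError("lead_ear must be 'left' or 'right'")
        active = {
            Experiment.ITDFS_SAM: self.ipd,
            Experiment.ITDENV_SAM: self.itd_env_us,
            Experiment.IPTD_CLICKS: self.iptd_us,
        }
        for exp, value in active.items():
            if self.experiment is not exp and value is not None:
                raise ValueError(
                    f"{exp.value} parameter set but experiment is "
                    f"{self.experiment.value}"
                )
        if self.experiment is Experiment.ITDFS_SAM:
            if self.ipd is None:
                self.ipd = math.pi / 2
            if not (-math.pi < self.ipd <= math.pi):
                raise ValueError("ipd must lie in (-pi, pi]")
            if self.fs <= 2 * self.f_c:
                raise ValueError("fs must exceed twice the carrier frequency")
        elif self.experiment is Experiment.ITDENV_SAM:
            if self.itd_env_us is None:
                self.itd_env_us = 500.0
            if abs(self.itd_env_us) * 1e-6 >= 0.5 / self.f_m:
                raise ValueError(
                    "envelope ITD of at least half a modulation period is "
                    "ambiguous"
                )
            if self.fs <= 2 * self.f_c:
                raise ValueError("fs must exceed twice the carrier frequency")
        else:
            if self.iptd_us is None:
                self.iptd_us = 500.0
            if self.f_m > 1000:
                raise ValueError("pulse rate above 1000 pps not supported")
            if self.iptd_us * 1e-6 >= 1.0 / self.f_m:
                raise ValueError("IPTD must be below the inter-pulse interval")

    # click trains reuse f_m as pulses/s
    @property
    def pulse_rate(self) -> float:
        return self.f_m

    def to_dict(self) -> dict:
        d = asdict(self)
        d["experiment"] = self.experiment.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        d = dict(d)
        layout = d.get("layout")
        if isinstance(layout, dict):
            d["layout"] = SequenceLayout(**layout)
        return cls(**d)


@dataclass
class StereoSignal:
    """Two-channel sampled waveform (full scale ±1) with segment annotations."""

    left: np.ndarray
    right: np.ndarray
    fs: float
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("channel lengths differ")

    @property
    def duration_s(self) -> float:
        return len(self.left) / self.fs

    @property
    def n_samples(self) -> int:
        return len(self.left)

    def window(self, label_or_window) -> tuple[float, float]:
        """Resolve a segment label (e.g. ``"T2"``) or (start, end) pair."""
        if isinstance(label_or_window, str):
            for label, start, end in self.annotations:
                if label == label_or_window:
                    return (start, end)
            raise KeyError(f"no annotation {label_or_window!r}")
        start, end = label_or_window
        return float(start), float(end)

    def slice(self, label_or_window) -> tuple[np.ndarray, np.ndarray]:
        start, end = self.window(label_or_window)
        i0, i1 = int(round(start * self.fs)), int(round(end * self.fs))
        return self.left[i0:i1], self.right[i0:i1]


# ---------------------------------------------------------------------------
# synthesis helpers

def _raised_cos_modulator(t: np.ndarray, f_m: float, shift_s: float = 0.0) -> np.ndarray:
    """Unit-peak raised-cosine AM modulator with a trough at t = shift_s."""
    return 0.5 * (1.0 - np.cos(2 * np.pi * f_m * (t - shift_s)))


def _trough_index(modulator: np.ndarray, nominal_idx: int, fs: float, f_m: float) -> int:
    """Sample index of the modulator trough nearest a nominal boundary."""
    half = int(round(0.5 * fs / f_m)) + 1
    lo = max(0, nominal_idx - half)
    hi = min(len(modulator), nominal_idx + half + 1)
    return lo + int(np.argmin(modulator[lo:hi]))


def _apply_ramps(x: np.ndarray, fs: float, ramp_ms: float, stim_end_idx: int) -> None:
    """In-place raised-cosine onset ramp and offset ramp ending at stim_end_idx."""
    n = int(round(ramp_ms * 1e-3 * fs))
    if n <= 1:
        return
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n) / n))
    x[:n] *= ramp
    x[stim_end_idx - n:stim_end_idx] *= ramp[::-1]


def _scale_rms(channels: list[np.ndarray], level_dbfs: float, upto_idx: int) -> None:
    """Scale both channels jointly so stimulation-part RMS hits level_dbfs."""
    rms = np.sqrt(np.mean(np.concatenate([c[:upto_idx] for c in channels]) ** 2))
    if rms > 0:
        g = 10 ** (level_dbfs / 20) / rms
        for c in channels:
            c *= g


def make_sam_itdfs(spec: StimulusSpec) -> StereoSignal:
    """SAM tone with a carrier IPD (fine-structure ITD) during T2.

    The envelope is identical in both ears throughout; only the carrier phase
    of the lead ear changes, and both phase transitions happen at the
    envelope trough nearest the nominal segment boundary.
    """
    if spec.experiment is not Experiment.ITDFS_SAM:
        raise ValueError("spec.experiment must be ITDFS_SAM")
    lay = spec.layout
    fs = spec.fs
    n_stim = int(round(lay.stim_s * fs))
    n_total = int(round(lay.total_s * fs))
    t = np.arange(n_stim) / fs
    env = _raised_cos_modulator(t, spec.f_m)

    i_on = _trough_index(env, int(round(lay.t1_s * fs)), fs, spec.f_m)
    i_off = _trough_index(env, int(round((lay.t1_s + lay.t2_s) * fs)), fs, spec.f_m)

    phase = np.zeros(n_stim)
    phase[i_on:i_off] = spec.ipd
    base = 2 * np.pi * spec.f_c * t
    lead = env * np.sin(base + phase)
    lag = env * np.sin(base)

    left, right = (lag, lead) if spec.lead_ear == "right" else (lead, lag)
    left = np.concatenate([left, np.zeros(n_total - n_stim)])
    right = np.concatenate([right, np.zeros(n_total - n_stim)])
    for ch in (left, right):
        _apply_ramps(ch, fs, spec.ramp_ms, n_stim)
    _scale_rms([left, right], spec.level_dbfs, n_stim)
    return StereoSignal(left, right, fs, lay.annotations())


def make_sam_itdenv(spec: StimulusSpec) -> StereoSignal:
    """SAM tone whose envelope leads in one ear during T2 (envelope ITD).

    The modulator of the lead ear is advanced by ``itd_env_us`` while the
    carrier remains interaurally in phase; realized as a modulator phase
    shift (not a whole-waveform delay) so no fine-structure cue is added.
    """
    if spec.experiment is not Experiment.ITDENV_SAM:
        raise ValueError("spec.experiment must be ITDENV_SAM")
    lay = spec.layout
    fs = spec.fs
    itd_s = spec.itd_env_us * 1e-6
    n_stim = int(round(lay.stim_s * fs))
    n_total = int(round(lay.total_s * fs))
    t = np.arange(n_stim) / fs
    env0 = _raised_cos_modulator(t, spec.f_m)

    i_on = _trough_index(env0, int(round(lay.t1_s * fs)), fs, spec.f_m)
    i_off = _trough_index(env0, int(round((lay.t1_s + lay.t2_s) * fs)), fs, spec.f_m)

    env_lead = env0.copy()
    # advanced modulator: env(t + ITD)
    env_lead[i_on:i_off] = _raised_cos_modulator(t[i_on:i_off] + itd_s, spec.f_m)
    carrier = np.sin(2 * np.pi * spec.f_c * t)
    lead = env_lead * carrier
    lag = env0 * carrier

    left, right = (lag, lead) if spec.lead_ear == "right" else (lead, lag)
    left = np.concatenate([left, np.zeros(n_total - n_stim)])
    right = np.concatenate([right, np.zeros(n_total - n_stim)])
    for ch in (left, right):
        _apply_ramps(ch, fs, spec.ramp_ms, n_stim)
    _scale_rms([left, right], spec.level_dbfs, n_stim)
    return StereoSignal(left, right, fs, lay.annotations())


def make_filtered_clicks(spec: StimulusSpec) -> StereoSignal:
    """Band-pass filtered click train with a pulse-timing ITD during T2.

    Unit impulses at ``pulse_rate`` are band-pass filtered to 3–5 kHz with a
    zero-phase Butterworth filter; in T2 the lagging ear's pulses are delayed
    by ``iptd_us`` so the lead ear leads.  Sequence: T1 diotic, T2 dichotic,
    T4 silence (no return-to-diotic segment for click trains).
    """
    if spec.experiment is not Experiment.IPTD_CLICKS:
        raise ValueError("spec.experiment must be IPTD_CLICKS")
    lay = spec.layout
    fs = spec.fs
    rate = spec.pulse_rate
    iptd_s = spec.iptd_us * 1e-6
    n_stim = int(round(lay.stim_s * fs))
    n_total = int(round(lay.total_s * fs))
    t1_end = lay.t1_s

    def pulse_train(delay_in_t2: float) -> np.ndarray:
        x = np.zeros(n_stim)
        k = 0
        while True:
            tp = k / rate
            if tp >= lay.stim_s:
                break
            if tp >= t1_end:
                tp += delay_in_t2
            idx = int(round(tp * fs))
            if idx < n_stim:
                x[idx] = 1.0
            k += 1
        return x

    lead = pulse_train(0.0)
    lag = pulse_train(iptd_s)
    sos = sps.butter(CLICK_FILTER_ORDER, CLICK_BAND_HZ, btype="bandpass", fs=fs,
                     output="sos")
    lead = sps.sosfiltfilt(sos, lead)
    lag = sps.sosfiltfilt(sos, lag)

    peak = max(np.abs(lead).max(), np.abs(lag).max())
    lead /= peak
    lag /= peak

    left, right = (lag, lead) if spec.lead_ear == "right" else (lead, lag)
    left = np.concatenate([left, np.zeros(n_total - n_stim)])
    right = np.concatenate([right, np.zeros(n_total - n_stim)])
    for ch in (left, right):
        _apply_ramps(ch, fs, spec.ramp_ms, n_stim)
    _scale_rms([left, right], spec.level_dbfs, n_stim)
    return StereoSignal(left, right, fs, lay.annotations())


def make_stimulus(spec: StimulusSpec) -> StereoSignal:
    """Dispatch to the family-specific generator."""
    return {
        Experiment.ITDFS_SAM: make_sam_itdfs,
        Experiment.ITDENV_SAM: make_sam_itdenv,
        Experiment.IPTD_CLICKS: make_filtered_clicks,
    }[spec.experiment](spec)


def make_masking_noise(duration_s: float, fs: float = 20000.0, seed: int = 0,
                       relative_level_db: float = -35.0,
                       ref_level_dbfs: float = -20.0,
                       gate_ms: float = 50.0) -> StereoSignal:
    """Low-pass masking noise, uncorrelated between ears.

    Spectrum is flat up to 200 Hz and falls 3 dB/octave above; components
    above 1 kHz are zeroed and a 5th-order low-pass at 1 kHz is applied, then
    50-ms raised-cosine gates.  RMS is set ``relative_level_db`` below the
    reference stimulus level (clicks at 75 dB SPL vs noise at 40 dB SPL gives
    the default −35 dB).  Ears use seeds ``seed`` and ``seed + 1``.
    """
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(freqs)
    above = freqs > 200.0
    shape[above] = (freqs[above] / 200.0) ** -0.5   # −3 dB/octave in power
    shape[freqs > 1000.0] = 0.0
    sos = sps.butter(5, 1000.0, btype="lowpass", fs=fs, output="sos")

    chans = []
    for s in (seed, seed + 1):
        rng = np.random.default_rng(s)
        x = rng.standard_normal(n)
        x = np.fft.irfft(np.fft.rfft(x) * shape, n)
        x = sps.sosfilt(sos, x)
        ng = int(round(gate_ms * 1e-3 * fs))
        gate = 0.5 * (1 - np.cos(np.pi * np.arange(ng) / ng))
        x[:ng] *= gate
        x[-ng:] *= gate[::-1]
        x *= 10 ** ((ref_level_dbfs + relative_level_db) / 20) / np.sqrt(np.mean(x ** 2))
        chans.append(x)
    return StereoSignal(chans[0], chans[1], fs, [("noise", 0.0, duration_s)])


# ---------------------------------------------------------------------------
# measurement operators

def _xcorr_lag_us(a: np.ndarray, b: np.ndarray, fs: float,
                  refine: bool = True) -> float:
    """Lag (µs) by which ``a`` leads ``b``, from the cross-correlation peak.

    A positive scipy correlation lag means ``a`` is *delayed* relative to
    ``b``, so the lead is the negated peak lag.
    """
    a = a - a.mean()
    b = b - b.mean()
    c = sps.correlate(a, b, mode="full")
    lags = sps.correlation_lags(len(a), len(b), mode="full")
    k = int(np.argmax(c))
    lag = float(lags[k])
    if refine and 0 < k < len(c) - 1:
        y0, y1, y2 = c[k - 1], c[k], c[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag += 0.5 * (y0 - y2) / denom
    return -lag / fs * 1e6


def measure_envelope_itd(sig: StereoSignal, window, f_m: float | None = None) -> float:
    """Envelope ITD in µs (positive: right ear leads), via Hilbert envelopes.

    Cross-correlation of the two channels' Hilbert envelopes with parabolic
    sub-sample refinement of the peak.
    """
    start, end = sig.window(window)
    if f_m is not None and (end - start) < 5.0 / f_m:
        raise UnreliableEstimateError("window shorter than 5 modulation periods")
    left, right = sig.slice(window)
    env_l = np.abs(sps.hilbert(left))
    env_r = np.abs(sps.hilbert(right))
    return _xcorr_lag_us(env_r, env_l, sig.fs)


def measure_broadband_itd(sig: StereoSignal, window) -> float:
    """Broadband interaural lag in µs (positive: right leads), raw waveforms."""
    left, right = sig.slice(window)
    return _xcorr_lag_us(right, left, sig.fs)


def measure_carrier_ipd(sig: StereoSignal, f_c: float, window) -> float:
    """Interaural phase difference (rad) of the carrier component at ``f_c``.

    Phase of the cross-spectrum at ``f_c`` over an integer number of carrier
    cycles; positive means the right ear's carrier phase leads.
    """
    left, right = sig.slice(window)
    n_cycles = int(np.floor(len(left) / sig.fs * f_c))
    if n_cycles < 5:
        raise UnreliableEstimateError("window shorter than 5 carrier cycles")
    n = int(round(n_cycles / f_c * sig.fs))
    t = np.arange(n) / sig.fs
    probe = np.exp(-2j * np.pi * f_c * t)
    zl = np.sum(left[:n] * probe)
    zr = np.sum(right[:n] * probe)
    return float(np.angle(zr * np.conj(zl)))


def measure_modulation_rate(sig: StereoSignal, window, f_min: float = 2.0) -> float:
    """Dominant non-DC frequency (Hz) of the Hilbert envelope spectrum."""
    left, _ = sig.slice(window)
    env = np.abs(sps.hilbert(left))
    env = env - env.mean()
    spec = np.abs(np.fft.rfft(env))
    freqs = np.fft.rfftfreq(len(env), 1 / sig.fs)
    mask = freqs >= f_min
    return float(freqs[mask][np.argmax(spec[mask])])


def spectral_slope_db_per_octave(x: np.ndarray, fs: float, f_lo: float = 200.0,
                                 f_hi: float = 1000.0,
                                 bands_per_octave: int = 3) -> float:
    """Spectral slope in dB/octave over [f_lo, f_hi] from log-spaced band powers.

    Welch PSD aggregated into fractional-octave bands whose edges lie within
    [f_lo, f_hi]; band power in dB regressed on log2(center frequency).
    """
    f, pxx = sps.welch(x, fs=fs, nperseg=min(len(x), 8192))
    centers = []
    levels = []
    k = 0
    while True:
        fc = f_lo * 2 ** (k / bands_per_octave)
        lo = fc * 2 ** (-0.5 / bands_per_octave)
        hi = fc * 2 ** (0.5 / bands_per_octave)
        if hi > f_hi:
            break
        m = (f >= lo) & (f < hi)
        if m.sum() >= 2:
            centers.append(fc)
            levels.append(10 * np.log10(np.mean(pxx[m])))
        k += 1
    if len(centers) < 3:
        raise ValueError("too few bands for a slope estimate")
    slope, _ = np.polyfit(np.log2(centers), levels, 1)
    return float(slope)


def passband_edges(x: np.ndarray, fs: float, rel_db: float = -6.0,
                   smooth_hz: float = 400.0) -> tuple[float, float]:
    """Frequencies of the ``rel_db`` points around the spectral peak.

    The magnitude spectrum is envelope-smoothed with a moving maximum of
    width ``smooth_hz`` (bridging harmonic line spacing), and the first
    crossings of ``peak + rel_db`` dB below/above the peak are returned with
    linear interpolation.
    """
    mag = np.abs(np.fft.rfft(x - np.mean(x)))
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    width = max(1, int(round(smooth_hz / (freqs[1] - freqs[0]))))
    from scipy.ndimage import maximum_filter1d
    smooth = maximum_filter1d(mag, size=width)
    db = 20 * np.log10(np.maximum(smooth, 1e-300))
    ipk = int(np.argmax(db))
    target = db[ipk] + rel_db

    def cross(indices) -> float:
        prev = ipk
        for i in indices:
            if db[i] < target:
                f0, f1 = freqs[i], freqs[prev]
                d0, d1 = db[i], db[prev]
                return float(f0 + (target - d0) / (d1 - d0) * (f1 - f0))
            prev = i
        raise ValueError("no crossing found")

    lo = cross(range(ipk - 1, -1, -1))
    hi = cross(range(ipk + 1, len(db)))
    return lo, hi


# ---------------------------------------------------------------------------
# WAV + sidecar I/O

def write_wav(path, sig: StereoSignal, spec: StimulusSpec | None = None) -> None:
    """Write a float32 stereo WAV plus a JSON sidecar with spec/annotations."""
    path = Path(path)
    data = np.stack([sig.left, sig.right], axis=1).astype(np.float32)
    wavfile.write(path, int(sig.fs), data)
    sidecar = {
        "fs": sig.fs,
        "annotations": [list(a) for a in sig.annotations],
        "spec": spec.to_dict() if spec is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_wav(path) -> tuple[StereoSignal, StimulusSpec | None]:
    """Read a stereo WAV written by :func:`write_wav` (sidecar optional)."""
    path = Path(path)
    fs, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("expected a stereo WAV")
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    annotations: list[tuple[str, float, float]] = []
    spec = None
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        annotations = [tuple(a) for a in meta.get("annotations", [])]
        if meta.get("spec"):
            spec = StimulusSpec.from_dict(meta["spec"])
    sig = StereoSignal(data[:, 0].astype(float), data[:, 1].astype(float),
                       float(fs), annotations)
    return sig, spec
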