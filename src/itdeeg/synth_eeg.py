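"""Synthetic EEG recordings with known ground truth.

Generates continuous multi-channel recordings that emulate the study
conditions of the evoked-potential paradigm: event-locked P1-N1-P2
deflections at stimulus onset, the outward ITD change (ACC1), the inward
change (ACC2, SAM experiments only) and stimulus offset; an additive
steady-state response (ASSR) at the modulation rate during stimulation;
pink + white background noise at tens of µV; a four-channel clinical
montage (two mastoids, inion, below-inion) recorded against Cz; and
optional high-amplitude artifact epochs.

The generative model per channel is

    r_c(t) = -gain_c * s(t) + noise_c(t)

where ``s(t)`` is the evoked source expressed at Cz against the average of
the four recording channels.  The sign models the polarity inversion of the
auditory vertex response at mastoid/inion sites, so that re-referencing the
simulated channels and forming the virtual-Cz trace recovers ``+s(t)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .stimuli import Experiment, StimulusSpec

__all__ = [
    "EVENT_TYPES",
    "CaepTemplateParams",
    "NoiseModel",
    "ArtifactModel",
    "SynthRecordingConfig",
    "EEGRecording",
    "caep_template",
    "simulate_recording",
    "DEFAULT_CHANNELS",
]

EVENT_TYPES = ("onset", "acc1", "acc2", "offset")

#: clinical 4-channel montage (Cz is the physical reference)
DEFAULT_CHANNELS = ("M_left_62", "M_right_56", "Inion_49", "BelowInion_59")

# group-mean P1/N1/P2 latencies (ms) and amplitudes (µV) for
# onset / ACC1 / ACC2 / offset in the fine-structure-ITD experiment;
# used as the default injected template.
_DEF_LAT = {
    "p1": {"onset": 42.0, "acc1": 46.0, "acc2": 57.0, "offset": 27.0},
    "n1": {"onset": 114.0, "acc1": 132.0, "acc2": 137.0, "offset": 95.0},
    "p2": {"onset": 211.0, "acc1": 227.0, "acc2": 240.0, "offset": 213.0},
}
_DEF_AMP = {
    "p1": {"onset": 1.684, "acc1": 1.405, "acc2": 1.005, "offset": 0.248},
    "n1": {"onset": -3.324, "acc1": -1.299, "acc2": -1.019, "offset": -2.146},
    "p2": {"onset": 3.946, "acc1": 2.128, "acc2": 1.862, "offset": 2.379},
}
#: Gaussian SDs of the three deflections, ms
_DEF_WIDTH = {"p1": 15.0, "n1": 20.0, "p2": 30.0}


@dataclass
class CaepTemplateParams:
    """P1-N1-P2 template parameters per event type.

    ``latencies_ms[peak][event]`` / ``amplitudes_uV[peak][event]`` for
    ``peak`` in p1/n1/p2 and ``event`` in onset/acc1/acc2/offset.  Each peak
    is a signed Gaussian of SD ``peak_width_ms[peak]``; N1 amplitudes are
    negative.  ``latency_jitter_sd_ms`` shifts the whole complex per trial.
    """

    latencies_ms: dict = field(default_factory=lambda: copy.deepcopy(_DEF_LAT))
    amplitudes_uV: dict = field(default_factory=lambda: copy.deepcopy(_DEF_AMP))
    peak_width_ms: dict = field(default_factory=lambda: dict(_DEF_WIDTH))
    latency_jitter_sd_ms: float = 3.0

    def scaled(self, k: float) -> "CaepTemplateParams":
        out = copy.deepcopy(self)
        for peak in out.amplitudes_uV:
            for ev in out.amplitudes_uV[peak]:
                out.amplitudes_uV[peak][ev] *= k
        return out


@dataclass
class NoiseModel:
    """Background noise: white + 1/f^exponent components, optional mains line."""

    white_sd_uV: float = 10.0
    pink_sd_uV: float = 10.0
    pink_exponent: float = 1.0
    line_freq_hz: float | None = None
    line_amp_uV: float = 0.0


@dataclass
class ArtifactModel:
    """Square-pulse artifacts injected into ``n_epochs`` whole trials."""

    n_epochs: int = 0
    amplitude_uV: float = 250.0
    duration_s: float = 0.05


@dataclass
class SynthRecordingConfig:
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    n_trials: int = 60
    inter_trial_gap_s: float = 0.5
    caep: CaepTemplateParams = field(default_factory=CaepTemplateParams)
    assr_amp_uV: float = 0.187
    assr_phase_rad: float = 0.0
    assr_reset: bool = False
    assr_reset_tau_s: float = 0.3
    noise: NoiseModel = field(default_factory=NoiseModel)
    artifact: ArtifactModel = field(default_factory=ArtifactModel)
    channel_labels: tuple = DEFAULT_CHANNELS
    channel_gains: tuple = (1.0, 1.0, 1.0, 1.0)
    fs: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.artifact.n_epochs > self.n_trials:
            raise ValueError("more artifact epochs than trials")
        if len(self.channel_gains) != len(self.channel_labels):
            raise ValueError("one gain per channel required")


@dataclass
class EEGRecording:
    """Continuous multi-channel recording in µV with event markers."""

    data: np.ndarray          # (n_channels, n_samples)
    fs: float
    channel_labels: tuple
    events: list              # [(onset_s, condition_id), ...] strictly increasing
    ground_truth: SynthRecordingConfig | None = None
    artifact_trials: tuple = ()
    clean_signal: np.ndarray | None = None   # noise-free virtual-Cz source

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("events must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def caep_template(params: CaepTemplateParams, event: str, fs: float,
                  duration_s: float = 0.5) -> np.ndarray:
    """Evoked template for one event type: sum of three signed Gaussians (µV).

    Each Gaussian contributes only within ±4 SD of its latency.
    """
    if event not in EVENT_TYPES:
        raise ValueError(f"unknown event type {event!r}")
    n = int(round(duration_s * fs))
    t_ms = np.arange(n) / fs * 1e3
    out = np.zeros(n)
    for peak in ("p1", "n1", "p2"):
        lat = params.latencies_ms[peak][event]
        amp = params.amplitudes_uV[peak][event]
        sd = params.peak_width_ms[peak]
        if sd <= 0:
            raise ValueError("peak widths must be positive")
        g = amp * np.exp(-0.5 * ((t_ms - lat) / sd) ** 2)
        g[np.abs(t_ms - lat) > 4 * sd] = 0.0
        out += g
    return out


def event_offsets_s(spec: StimulusSpec) -> dict:
    """Event times within a trial, seconds from stimulus onset."""
    lay = spec.layout
    out = {"onset": 0.0, "acc1": lay.t1_s}
    if lay.t3_s > 0:
        out["acc2"] = lay.t1_s + lay.t2_s
    out["offset"] = lay.stim_s
    return out


def _pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float,
                exponent: float) -> np.ndarray:
    """1/f^exponent (power) noise scaled to the requested SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def simulate_recording(config: SynthRecordingConfig) -> EEGRecording:
    """Render a continuous recording from the generative model.

    Trials are laid out back to back with ``inter_trial_gap_s`` between the
    end of one presentation and the next onset, with 1-s padding at both
    ends.  Designated artifact trials get a square pulse on every channel.
    """
    spec = config.stimulus
    lay = spec.layout
    fs = config.fs
    trial_period = lay.total_s + config.inter_trial_gap_s
    if config.inter_trial_gap_s < 0:
        raise ValueError("trials overlap: negative inter-trial gap")
    pad = 1.0
    total_s = 2 * pad + config.n_trials * trial_period
    n = int(round(total_s * fs))
    t_onsets = pad + np.arange(config.n_trials) * trial_period

    rng = np.random.default_rng(config.seed)
    ev_offsets = event_offsets_s(spec)
    stim_len = int(round(lay.stim_s * fs))

    s = np.zeros(n)
    for i, t0 in enumerate(t_onsets):
        i0 = int(round(t0 * fs))
        # transient complexes, jittered per trial and event
        for ev, dt in ev_offsets.items():
            jitter = rng.normal(0.0, config.caep.latency_jitter_sd_ms) * 1e-3 \
                if config.caep.latency_jitter_sd_ms > 0 else 0.0
            tpl = caep_template(config.caep, ev, fs)
            j0 = i0 + int(round((dt + jitter) * fs))
            j1 = min(j0 + len(tpl), n)
            s[j0:j1] += tpl[: j1 - j0]
        # steady-state component during stimulation only
        if config.assr_amp_uV != 0.0:
            tt = np.arange(stim_len) / fs
            assr = config.assr_amp_uV * np.cos(
                2 * np.pi * spec.f_m * tt + config.assr_phase_rad)
            if config.assr_reset:
                gate = np.ones(stim_len)
                for dt in ev_offsets.values():
                    if dt >= lay.stim_s:
                        continue
                    k0 = int(round(dt * fs))
                    rel = tt[k0:] - tt[k0]
                    gate[k0:] = 1.0 - np.exp(-rel / config.assr_reset_tau_s)
                assr = assr * gate
            s[i0:i0 + stim_len] += assr

    n_ch = len(config.channel_labels)
    data = np.empty((n_ch, n), dtype=float)
    for c in range(n_ch):
        noise = np.zeros(n)
        if config.noise.pink_sd_uV > 0:
            noise += _pink_noise(rng, n, fs, config.noise.pink_sd_uV,
                                 config.noise.pink_exponent)
        if config.noise.white_sd_uV > 0:
            noise += rng.standard_normal(n) * config.noise.white_sd_uV
        if config.noise.line_freq_hz:
            tt = np.arange(n) / fs
            noise += config.noise.line_amp_uV * np.sin(
                2 * np.pi * config.noise.line_freq_hz * tt + rng.uniform(0, 2 * np.pi))
        data[c] = -config.channel_gains[c] * s + noise

    artifact_trials: tuple = ()
    if config.artifact.n_epochs > 0:
        chosen = rng.choice(config.n_trials, size=config.artifact.n_epochs,
                            replace=False)
        artifact_trials = tuple(sorted(int(i) for i in chosen))
        dur = int(round(config.artifact.duration_s * fs))
        for i in artifact_trials:
            j0 = int(round((t_onsets[i] + 0.5) * fs))
            data[:, j0:j0 + dur] += config.artifact.amplitude_uV

    events = [(float(t0), 0) for t0 in t_onsets]
    return EEGRecording(data=data, fs=fs, channel_labels=config.channel_labels,
                        events=events, ground_truth=config,
                        artifact_trials=artifact_trials, clean_signal=s)
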