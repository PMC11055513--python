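"""Preprocessing chain: continuous recording -> averaged evoked response.

Fixed pipeline order (each step logged in the provenance of the result):

    segment -> bandpass (0.1-1000 Hz) -> baseline -> reject -> rereference
    -> average

Filtering is applied after segmentation; edge transients are absorbed by the
200-ms pre-stimulus interval and the 1-s post-offset tail.  Both Butterworth
filters are applied forward-backward (zero phase) so peak latencies are not
shifted by group delay; the effective order doubles, which is recorded in
the provenance.  Baseline is the mean of the final 1 s of the epoch (after
stimulus offset); artifact rejection masks whole trials exceeding ±200 µV on
any recording channel; re-referencing subtracts the average of the four
clinical channels and emits a virtual-Cz trace (the physical Cz reference
expressed against that average), which is the default analysis trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .synth_eeg import EEGRecording

__all__ = [
    "Epochs",
    "Evoked",
    "segment",
    "bandpass",
    "bandpass_sos",
    "baseline_correct",
    "reject_artifacts",
    "rereference",
    "average",
    "resample",
    "run_pipeline",
    "VIRTUAL_CZ",
]

log = logging.getLogger(__name__)

VIRTUAL_CZ = "virtual_Cz"

#: broadband analysis filter corners, Hz
BROADBAND = (0.1, 1000.0)
#: artifact rejection threshold, µV
REJECT_UV = 200.0


@dataclass
class Epochs:
    """Segmented trials (trial x channel x time) for one condition, µV."""

    data: np.ndarray
    fs: float
    channel_labels: tuple
    t0_offset_s: float = -0.2
    condition: object = None
    keep_mask: np.ndarray | None = None
    reject_reasons: dict = field(default_factory=dict)
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.keep_mask is None:
            self.keep_mask = np.ones(self.data.shape[0], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.data.shape[2]) / self.fs

    def copy_with(self, **kw) -> "Epochs":
        return replace(self, **kw)


@dataclass
class Evoked:
    """Trial-averaged response (channel x time), µV."""

    data: np.ndarray
    fs: float
    channel_labels: tuple
    t0_offset_s: float = -0.2
    condition: object = None
    n_trials_used: int = 0
    provenance: list = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.data.shape[1]) / self.fs

    def trace(self, channel: str = VIRTUAL_CZ) -> np.ndarray:
        return self.data[self.channel_labels.index(channel)]

    def copy_with(self, **kw) -> "Evoked":
        return replace(self, **kw)


def segment(rec: EEGRecording, window_s: float | None = None,
            pre_s: float = 0.2) -> Epochs:
    """Cut one epoch per event: [-pre_s, window_s - pre_s] around each onset.

    ``window_s`` defaults to pre_s + the stimulus layout total (8.2 s for the
    SAM experiments, 6.2 s for clicks) when the recording carries ground
    truth.  Events too close to the recording edge are dropped and logged.
    """
    if window_s is None:
        if rec.ground_truth is None:
            raise ValueError("window_s required for recordings without ground truth")
        window_s = pre_s + rec.ground_truth.stimulus.layout.total_s
    n_samp = int(round(window_s * rec.fs))
    n_pre = int(round(pre_s * rec.fs))
    rows = []
    dropped = 0
    for t0, _cond in rec.events:
        i0 = int(round(t0 * rec.fs)) - n_pre
        if i0 < 0 or i0 + n_samp > rec.n_samples:
            dropped += 1
            continue
        rows.append(rec.data[:, i0:i0 + n_samp])
    if dropped:
        log.warning("segment: dropped %d event(s) at the recording edge", dropped)
    if not rows:
        raise ValueError("no events fit inside the recording")
    cond = rec.ground_truth.stimulus if rec.ground_truth is not None else None
    return Epochs(data=np.stack(rows), fs=rec.fs,
                  channel_labels=tuple(rec.channel_labels),
                  t0_offset_s=-pre_s, condition=cond,
                  provenance=[f"segment(window={window_s}, pre={pre_s}, "
                              f"dropped={dropped})"])


def bandpass_sos(fs: float, lo: float = BROADBAND[0], hi: float = BROADBAND[1],
                 order: int = 2):
    """Butterworth SOS for [lo, hi]; degrades to a high-pass when hi >= Nyquist.

    At low sampling rates (e.g. the 1-kHz simulation rate) the nominal 1-kHz
    upper corner exceeds Nyquist and only the high-pass corner applies.
    """
    if lo <= 0:
        raise ValueError("low corner must be positive")
    if hi <= lo:
        raise ValueError("invalid corner ordering")
    if hi >= 0.49 * fs:
        return sps.butter(order, lo, btype="highpass", fs=fs, output="sos")
    return sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")


def bandpass(x, fs: float, lo: float = BROADBAND[0], hi: float = BROADBAND[1],
             order: int = 2, axis: int = -1):
    """Zero-phase Butterworth band-pass of arrays or Epochs/Evoked containers."""
    sos = bandpass_sos(fs, lo, hi, order)
    if isinstance(x, (Epochs, Evoked)):
        out = sps.sosfiltfilt(sos, x.data, axis=-1)
        return x.copy_with(data=out, provenance=x.provenance +
                           [f"bandpass({lo}-{hi} Hz, order {order}, zero-phase)"])
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=axis)


def baseline_correct(epochs: Epochs, baseline_s: float = 1.0) -> Epochs:
    """Subtract the per-trial, per-channel mean of the last ``baseline_s`` s.

    The paradigm puts the final second of every epoch after stimulus offset
    (inside the silent T4 window), so this is a post-offset baseline.
    """
    n_base = int(round(baseline_s * epochs.fs))
    if n_base > epochs.data.shape[2]:
        raise ValueError("epoch shorter than the baseline window")
    base = epochs.data[:, :, -n_base:].mean(axis=2, keepdims=True)
    return epochs.copy_with(data=epochs.data - base,
                            provenance=epochs.provenance +
                            [f"baseline(last {baseline_s} s)"])


def reject_artifacts(epochs: Epochs, threshold_uV: float = REJECT_UV) -> Epochs:
    """Mask trials with any sample exceeding ±threshold on any channel."""
    if threshold_uV <= 0:
        raise ValueError("threshold must be positive")
    bad = np.any(np.abs(epochs.data) > threshold_uV, axis=(1, 2))
    mask = epochs.keep_mask & ~bad
    reasons = dict(epochs.reject_reasons)
    for i in np.nonzero(bad)[0]:
        reasons[int(i)] = f"amplitude > {threshold_uV} uV"
    n_rej = int(bad.sum())
    if n_rej:
        log.info("reject_artifacts: masked %d trial(s)", n_rej)
    return epochs.copy_with(keep_mask=mask, reject_reasons=reasons,
                            provenance=epochs.provenance +
                            [f"reject(±{threshold_uV} µV, {n_rej} masked)"])


def rereference(epochs: Epochs) -> Epochs:
    """Re-reference to the average of the recording channels; add virtual Cz.

    Each channel becomes ``channel − mean(channels)`` and an extra trace
    ``virtual_Cz = −mean(channels)`` is appended: the physical Cz reference
    expressed against the 4-channel average.  Idempotent on the original
    channels (virtual Cz is not re-added if already present).
    """
    labels = epochs.channel_labels
    if VIRTUAL_CZ in labels:
        # already re-referenced: the physical channels are mean-free and the
        # virtual Cz is fixed, so applying the step again is a no-op
        return epochs
    phys = epochs.data
    base_labels = labels
    mean = phys.mean(axis=1, keepdims=True)
    reref = phys - mean
    out = np.concatenate([reref, -mean], axis=1)
    return epochs.copy_with(data=out,
                            channel_labels=base_labels + (VIRTUAL_CZ,),
                            provenance=epochs.provenance +
                            ["rereference(4-channel average + virtual Cz)"])


def average(epochs: Epochs) -> Evoked:
    """Mean over surviving trials."""
    if epochs.n_kept == 0:
        raise ValueError("no surviving trials to average")
    data = epochs.data[epochs.keep_mask].mean(axis=0)
    return Evoked(data=data, fs=epochs.fs, channel_labels=epochs.channel_labels,
                  t0_offset_s=epochs.t0_offset_s, condition=epochs.condition,
                  n_trials_used=epochs.n_kept,
                  provenance=epochs.provenance + [f"average({epochs.n_kept} trials)"])


def resample(x, fs: float, target_fs: float, axis: int = -1):
    """Polyphase resampling with anti-alias filtering (downsampling only)."""
    if target_fs > fs:
        raise ValueError("target_fs must not exceed fs")
    frac = Fraction(target_fs / fs).limit_denominator(10000)
    if isinstance(x, Evoked):
        data = sps.resample_poly(x.data, frac.numerator, frac.denominator, axis=-1)
        return x.copy_with(data=data, fs=fs * frac.numerator / frac.denominator,
                           provenance=x.provenance + [f"resample({target_fs} Hz)"])
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                             frac.denominator, axis=axis)


def run_pipeline(rec: EEGRecording, window_s: float | None = None,
                 pre_s: float = 0.2, lo: float = BROADBAND[0],
                 hi: float = BROADBAND[1],
                 reject_uV: float = REJECT_UV) -> Evoked:
    """Full chain: segment, broadband filter, baseline, reject, rereference,
    average.  Returns the evoked response with the virtual-Cz analysis trace.
    """
    ep = segment(rec, window_s=window_s, pre_s=pre_s)
    ep = bandpass(ep, ep.fs, lo=lo, hi=hi)
    ep = baseline_correct(ep)
    ep = reject_artifacts(ep, threshold_uV=reject_uV)
    ep = rereference(ep)
    return average(ep)
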