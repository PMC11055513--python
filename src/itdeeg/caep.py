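"""Cortical evoked potential (P1-N1-P2) extraction.

Peaks are picked from the 0.1–30 Hz filtered average response inside fixed
post-event windows — 10–85 ms (P1, maximum), 85–160 ms (N1, minimum),
160–300 ms (P2, maximum) — for each of the four event types: stimulus
onset, the outward ITD change (ACC1), the inward change (ACC2) and the
stimulus offset.  Amplitudes are the signed trace values in µV (N1 is
negative); the primary transient measure is the N1P2 amplitude, P2 − N1.
Extrema are global within their window, taken at the extremal sample with
no sub-sample interpolation; window-edge hits are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Evoked, bandpass, VIRTUAL_CZ
from .stimuli import SequenceLayout

__all__ = [
    "PEAK_WINDOWS_MS",
    "Peak",
    "PeakSet",
    "lowpass_caep",
    "event_times",
    "pick_peaks",
    "n1p2",
    "noise_floor_n1p2",
]

#: fixed post-event detection windows, ms
PEAK_WINDOWS_MS = {"p1": (10.0, 85.0), "n1": (85.0, 160.0), "p2": (160.0, 300.0)}

#: CAEP analysis filter corners, Hz
CAEP_BAND = (0.1, 30.0)


@dataclass
class Peak:
    amp_uV: float
    lat_ms: float
    edge: bool = False      # extremum sits on a window boundary sample
    sub_noise: bool = False


@dataclass
class PeakSet:
    """P1/N1/P2 per event type, with the derived N1P2 amplitude."""

    peaks: dict = field(default_factory=dict)   # event -> {"p1": Peak, ...}

    def __getitem__(self, event: str) -> dict:
        return self.peaks[event]

    @property
    def events(self) -> tuple:
        return tuple(self.peaks)

    def n1p2_uV(self, event: str) -> float:
        p = self.peaks[event]
        return p["p2"].amp_uV - p["n1"].amp_uV


def lowpass_caep(evoked: Evoked, lo: float = CAEP_BAND[0],
                 hi: float = CAEP_BAND[1], order: int = 2) -> Evoked:
    """0.1–30 Hz zero-phase Butterworth band-pass of the averaged response."""
    return bandpass(evoked, evoked.fs, lo=lo, hi=hi, order=order)


def event_times(layout: SequenceLayout) -> dict:
    """Start times of onset / ACC1 / ACC2 / offset, seconds from onset.

    ACC2 is absent when the layout has no return-to-diotic segment
    (t3 = 0, click trains).
    """
    out = {"onset": 0.0, "acc1": layout.t1_s}
    if layout.t3_s > 0:
        out["acc2"] = layout.t1_s + layout.t2_s
    out["offset"] = layout.stim_s
    return out


def _pick_window(trace: np.ndarray, times_s: np.ndarray, t_event: float,
                 win_ms: tuple[float, float], mode: str) -> Peak:
    lo_s = t_event + win_ms[0] * 1e-3
    hi_s = t_event + win_ms[1] * 1e-3
    m = (times_s >= lo_s) & (times_s <= hi_s)
    idx = np.nonzero(m)[0]
    if len(idx) == 0:
        raise ValueError(f"peak window [{lo_s}, {hi_s}] s outside the epoch")
    seg = trace[idx]
    k = int(np.argmax(seg)) if mode == "max" else int(np.argmin(seg))
    i = idx[k]
    lat_ms = (times_s[i] - t_event) * 1e3
    return Peak(amp_uV=float(trace[i]), lat_ms=float(lat_ms),
                edge=(k == 0 or k == len(seg) - 1))


def pick_peaks(evoked: Evoked, layout: SequenceLayout | None = None,
               channel: str = VIRTUAL_CZ,
               noise_sd_uV: float | None = None) -> PeakSet:
    """Pick P1/N1/P2 for every event type on the analysis trace.

    ``layout`` defaults to the evoked's condition layout.  If
    ``noise_sd_uV`` is given, peaks with |amplitude| below twice that value
    are flagged ``sub_noise``.
    """
    if layout is None:
        if evoked.condition is None or evoked.condition.layout is None:
            raise ValueError("layout required")
        layout = evoked.condition.layout
    trace = evoked.trace(channel)
    times = evoked.times
    out = PeakSet()
    for ev, t_ev in event_times(layout).items():
        picks = {}
        for peak, (mode) in (("p1", "max"), ("n1", "min"), ("p2", "max")):
            pk = _pick_window(trace, times, t_ev, PEAK_WINDOWS_MS[peak], mode)
            if noise_sd_uV is not None and abs(pk.amp_uV) < 2 * noise_sd_uV:
                pk.sub_noise = True
            picks[peak] = pk
        out.peaks[ev] = picks
    return out


def n1p2(peaks: PeakSet, event: str = "onset") -> float:
    """N1P2 amplitude, µV: P2 peak amplitude minus N1 peak amplitude."""
    return peaks.n1p2_uV(event)


def noise_floor_n1p2(evoked: Evoked, layout: SequenceLayout,
                     rng: np.random.Generator, n_windows: int = 20,
                     channel: str = VIRTUAL_CZ) -> np.ndarray:
    """Noise-floor distribution of 'picked' N1P2 from the silent T4 window.

    Applies the same min/max picking to windows anchored at random pseudo
    event times inside the silence, providing the reference distribution
    against which sub-noise ACC peaks can be judged.
    """
    trace = evoked.trace(channel)
    times = evoked.times
    t4_start = layout.stim_s
    t_max = layout.total_s - 0.310   # pseudo event + P2 window must fit
    if t_max <= t4_start:
        raise ValueError("silent window too short for noise-floor sampling")
    vals = np.empty(n_windows)
    for i in range(n_windows):
        t_ev = rng.uniform(t4_start, t_max)
        n1 = _pick_window(trace, times, t_ev, PEAK_WINDOWS_MS["n1"], "min")
        p2 = _pick_window(trace, times, t_ev, PEAK_WINDOWS_MS["p2"], "max")
        vals[i] = p2.amp_uV - n1.amp_uV
    return vals
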