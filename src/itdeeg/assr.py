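"""Auditory steady-state response (ASSR) extraction.

ASSRs are quantified as the single-sided discrete Fourier amplitude of the
condition-averaged (phase-locked) broadband response within a rectangular
analysis window: the diotic (T1), dichotic (T2), return-to-diotic (T3) and
silent (T4) segments, or the whole presentation (T1234 / T124).  The
spectrum is normalized so that a sinusoid of amplitude A µV spanning the
window yields A at its bin; with 2-s windows every default modulation rate
(40/80/160/320 Hz) falls exactly on a bin.  The ASSR value is the amplitude
at the bin nearest the modulation rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import Evoked, VIRTUAL_CZ
from .stimuli import SequenceLayout

__all__ = [
    "ASSRResult",
    "window_for_label",
    "amplitude_spectrum",
    "assr_at",
]


@dataclass
class ASSRResult:
    label: str
    freqs: np.ndarray          # Hz
    amplitude: np.ndarray      # µV per bin, single-sided
    resolution_hz: float

    def assr_uV(self, f_m: float) -> float:
        return assr_at(self, f_m)


def window_for_label(layout: SequenceLayout, label: str) -> tuple[float, float]:
    """(start, end) seconds from stimulus onset for an analysis window label.

    T1234/T124 denote the whole presentation (stimulation plus silence).
    """
    t1, t2, t3 = layout.t1_s, layout.t2_s, layout.t3_s
    table = {
        "T1": (0.0, t1),
        "T2": (t1, t1 + t2),
        "T4": (layout.stim_s, layout.total_s),
        "T1234": (0.0, layout.total_s),
        "T124": (0.0, layout.total_s),
        # stimulation-only window: a steady-state component present
        # throughout stimulation spans this window exactly, so its bin
        # amplitude equals the physiological amplitude with no duty-cycle
        # dilution (T1234 spans the silence too and scales by stim/total).
        "T123": (0.0, layout.stim_s),
        "T12": (0.0, layout.stim_s),
    }
    if t3 > 0:
        table["T3"] = (t1 + t2, t1 + t2 + t3)
    if label not in table:
        raise KeyError(f"window label {label!r} not available for this layout")
    return table[label]


def amplitude_spectrum(evoked: Evoked, window, channel: str = VIRTUAL_CZ,
                       min_duration_s: float | None = None) -> ASSRResult:
    """Rectangular-window DFT amplitude spectrum of the averaged trace.

    ``window`` is a T-label or a (start, end) pair in seconds from stimulus
    onset.  The mean is removed before the transform; amplitudes are
    single-sided (2|X|/N).  Frequency resolution is 1 / window duration.
    """
    if isinstance(window, str):
        label = window
        if evoked.condition is None:
            raise ValueError("labelled window requires condition metadata")
        start, end = window_for_label(evoked.condition.layout, window)
    else:
        label = f"{window[0]:g}-{window[1]:g}s"
        start, end = window
    if min_duration_s is not None and (end - start) < min_duration_s:
        raise ValueError("analysis window too short")
    times = evoked.times
    i0 = int(np.searchsorted(times, start - 1e-9))
    i1 = i0 + int(round((end - start) * evoked.fs))
    x = evoked.trace(channel)[i0:i1]
    if len(x) < 2:
        raise ValueError("analysis window outside the epoch")
    x = x - x.mean()
    n = len(x)
    amp = np.abs(np.fft.rfft(x)) * 2.0 / n
    amp[0] /= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1 / evoked.fs)
    return ASSRResult(label=label, freqs=freqs, amplitude=amp,
                      resolution_hz=evoked.fs / n)


def assr_at(result: ASSRResult, f_m: float) -> float:
    """Amplitude (µV) at the bin nearest ``f_m``; warns if f_m is off-bin."""
    if f_m < 0 or f_m > result.freqs[-1]:
        raise ValueError("modulation rate outside the frequency grid")
    k = int(np.argmin(np.abs(result.freqs - f_m)))
    if abs(result.freqs[k] - f_m) > result.resolution_hz / 10:
        warnings.warn(
            f"modulation rate {f_m} Hz is {abs(result.freqs[k]-f_m):.3g} Hz "
            "away from the nearest bin; amplitude suffers leakage",
            stacklevel=2)
    return float(result.amplitude[k])
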