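"""Complex Morlet wavelet time-frequency analysis.

The kernel at analysis frequency f is

    w(t) = exp(2*i*pi*f*t) * exp(-t**2 / (2*sigma**2)),   sigma = n / (2*pi*f)

sampled on t = -1 : 1/fs : 1, with n the number of cycles (default 6).  The
scalogram is the magnitude of the convolution of the averaged response with
the kernel at each grid frequency.  Kernels are amplitude-normalized (scaled
by 2 / sum of the Gaussian envelope) so that a unit-amplitude sinusoid at f
produces a unit-height ridge; magnitudes are therefore comparable across
frequencies and labelled arbitrary units.  Edges use reflect padding and the
outer 3*sigma(f) band is flagged as edge-contaminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["MorletParams", "Scalogram", "morlet_kernel", "scalogram", "sigma_s"]


def sigma_s(f: float, n: float = 6.0) -> float:
    """Gaussian width (s) of the Morlet kernel at frequency f."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return n / (2 * np.pi * f)


@dataclass
class MorletParams:
    n: float = 6.0                       # cycles
    f_grid: np.ndarray = field(default_factory=lambda: np.arange(2.0, 81.0, 1.0))
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 cycles")
        self.f_grid = np.asarray(self.f_grid, dtype=float)
        if np.any(self.f_grid <= 0):
            raise ValueError("frequencies must be positive")


@dataclass
class Scalogram:
    magnitude: np.ndarray        # (freq, time), arbitrary units, >= 0
    f_grid: np.ndarray
    times: np.ndarray            # aligned to the input trace's time axis
    params: MorletParams
    edge_mask: np.ndarray | None = None   # True where edge-contaminated


def morlet_kernel(f: float, n: float = 6.0, fs: float = 1000.0) -> np.ndarray:
    """Complex Morlet kernel on t = -1 : 1/fs : 1 (length 2*fs + 1 samples)."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    if fs <= 2 * f:
        raise ValueError("fs too low for this analysis frequency")
    t = np.arange(-round(fs), round(fs) + 1) / fs
    sig = sigma_s(f, n)
    return np.exp(2j * np.pi * f * t) * np.exp(-t ** 2 / (2 * sig ** 2))


def scalogram(trace: np.ndarray, params: MorletParams,
              times: np.ndarray | None = None) -> Scalogram:
    """Morlet scalogram of a 1-D trace (typically the averaged response)."""
    trace = np.asarray(trace, dtype=float)
    fs = params.fs
    n_t = len(trace)
    kernel_len = 2 * int(round(fs)) + 1
    if n_t < kernel_len // 2:
        raise ValueError("trace shorter than the kernel support")
    if times is None:
        times = np.arange(n_t) / fs
    pad = kernel_len // 2
    padded = np.pad(trace, pad, mode="reflect")
    mag = np.empty((len(params.f_grid), n_t))
    edge = np.zeros((len(params.f_grid), n_t), dtype=bool)
    t_k = np.arange(-round(fs), round(fs) + 1) / fs
    for i, f in enumerate(params.f_grid):
        gauss = np.exp(-t_k ** 2 / (2 * sigma_s(f, params.n) ** 2))
        # amplitude normalization: unit sinusoid at f -> unit ridge
        k = np.exp(2j * np.pi * f * t_k) * gauss * (2.0 / gauss.sum())
        conv = sps.fftconvolve(padded, k, mode="same")[pad:pad + n_t]
        mag[i] = np.abs(conv)
        n_edge = min(n_t, int(np.ceil(3 * sigma_s(f, params.n) * fs)))
        if n_edge > 0:
            edge[i, :n_edge] = True
            edge[i, n_t - n_edge:] = True
    return Scalogram(magnitude=mag, f_grid=params.f_grid, times=np.asarray(times),
                     params=params, edge_mask=edge)
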