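"""Canonical hemodynamic response kernels.

Shared by the forward simulator and the GLM design-matrix builder so that
channel-selection regressors match the generative model by construction.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma

#: length of the sampled HRF kernel in seconds (response has decayed by then)
HRF_DURATION_S = 32.0

#: length of the sampled initial-dip kernel in seconds
DIP_DURATION_S = 4.0


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma impulse response, unit peak amplitude.

    ``h(t) = g(t; peak) - ratio * g(t; undershoot)`` with unit-scale gamma
    densities, rescaled so that ``max h = 1``. Peaks near ``peak_s`` and
    undershoots near ``undershoot_s``.
    """
    t = np.asarray(t, dtype=float)
    h = _gamma.pdf(t, peak_s) - undershoot_ratio * _gamma.pdf(t, undershoot_s)
    h[t < 0] = 0.0
    m = h.max()
    if m > 0:
        h = h / m
    return h


def initial_dip(t: np.ndarray, peak_s: float = 1.0, shape: float = 3.0) -> np.ndarray:
    """Early-oxygen-consumption transient, unit peak, maximum near ``peak_s``.

    A single gamma density whose mode is placed at ``peak_s``; essentially
    contained within the first two seconds after onset.
    """
    t = np.asarray(t, dtype=float)
    scale = peak_s / (shape - 1.0)
    g = _gamma.pdf(t, shape, scale=scale)
    g[t < 0] = 0.0
    m = g.max()
    if m > 0:
        g = g / m
    return g


def hrf_kernel(fs: float, task_s: float) -> np.ndarray:
    """Boxcar of ``task_s`` seconds convolved with the double-gamma HRF.

    Sampled at ``fs``; unit peak amplitude. This is the single-trial
    hemodynamic waveform used both to synthesize sessions and to build
    regressors.
    """
    n = int(np.round((HRF_DURATION_S + task_s) * fs))
    t = np.arange(n) / fs
    h = double_gamma_hrf(t)
    box = (t < task_s).astype(float)
    k = np.convolve(box, h)[:n] / fs
    m = np.abs(k).max()
    if m > 0:
        k = k / m
    return k


def dip_kernel(fs: float) -> np.ndarray:
    """Sampled unit-peak initial-dip waveform at rate ``fs``."""
    n = int(np.round(DIP_DURATION_S * fs))
    t = np.arange(n) / fs
    return initial_dip(t)
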