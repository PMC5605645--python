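"""Orthogonal discrete wavelet decomposition (approximation branch).

Implements the analysis cascade directly: half-point symmetric boundary
extension, convolution with the scaling (low-pass) decomposition filter,
and dyadic downsampling, so that an input of length n yields
floor((n + L - 1) / 2) coefficients per level for filter length L.
"""

from __future__ import annotations

import numpy as np

# Scaling (low-pass) decomposition filters of orthonormal wavelets,
# ordered as applied in convolution. Each sums to sqrt(2) and has unit
# energy (asserted in the test suite).
DEC_LO = {
    "sym4": np.array([
        -0.07576571478927333, -0.02963552764599851, 0.49761866763201545,
        0.8037387518059161, 0.29785779560527736, -0.09921954357684722,
        -0.012603967262037833, 0.0322231006040427,
    ]),
    "db4": np.array([
        -0.010597401784997278, 0.032883011666982945, 0.030841381835986965,
        -0.18703481171888114, -0.02798376941698385, 0.6308807679295904,
        0.7148465705525415, 0.23037781330885523,
    ]),
}


def quadrature_mirror(dec_lo: np.ndarray) -> np.ndarray:
    """High-pass analysis filter paired with a low-pass analysis filter."""
    L = len(dec_lo)
    return np.array([(-1) ** k * dec_lo[L - 1 - k] for k in range(L)])


def _symmetric_extend(x: np.ndarray, pad: int) -> np.ndarray:
    """Half-point symmetric extension: ... x1 x0 | x0 x1 ... xn-1 | xn-1 ..."""
    if pad > len(x):
        # repeat reflection for very short signals
        reps = int(np.ceil(pad / len(x)))
        tile = np.concatenate([x[::-1], x] * reps)
        left = tile[-pad:] if pad else x[:0]
        right = np.concatenate([x, x[::-1]] * reps)[len(x):len(x) + pad]
        return np.concatenate([left, x, right])
    left = x[pad - 1::-1]
    right = x[:-pad - 1:-1]
    return np.concatenate([left, x, right])


def dwt_step(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """One analysis level for one filter branch."""
    L = len(filt)
    if len(x) < L:
        raise ValueError(f"signal length {len(x)} shorter than filter length {L}")
    ext = _symmetric_extend(np.asarray(x, float), L - 1)
    full = np.convolve(ext, filt, mode="valid")  # length len(x) + L - 1
    return full[1::2]


def approx_length(n: int, levels: int, filter_length: int = 8) -> int:
    """Final approximation length after ``levels`` analysis steps."""
    for _ in range(levels):
        n = (n + filter_length - 1) // 2
    return n


def dwt_approx(signal: np.ndarray, levels: int = 4, wavelet: str = "sym4") -> np.ndarray:
    """Final-level approximation coefficients of the analysis cascade."""
    if wavelet not in DEC_LO:
        raise ValueError(f"unsupported wavelet {wavelet!r}; available: {sorted(DEC_LO)}")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    a = np.asarray(signal, float)
    if a.ndim != 1:
        raise ValueError("dwt_approx expects a 1-D signal")
    lo = DEC_LO[wavelet]
    for _ in range(levels):
        a = dwt_step(a, lo)
    return a
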