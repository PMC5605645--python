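"""Raw-session conditioning: re-referencing, filtering, hemoglobin
conversion, motion correction, epoching and baseline subtraction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.interpolate import LSQUnivariateSpline
from scipy.ndimage import uniform_filter1d

from . import constants as C
from .synthetic import EventList, RawSession


@dataclass
class HbSeries:
    """Continuous ΔHbO/ΔHbR concentration changes (µmol/L)."""

    hbo: np.ndarray  # samples × channels
    hbr: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have the same shape")
        if not (np.isfinite(self.hbo).all() and np.isfinite(self.hbr).all()):
            raise ValueError("hemoglobin series contain non-finite values")


@dataclass
class EpochSet:
    """Onset-locked, baseline-corrected trials."""

    data: np.ndarray  # trials × samples × channels
    fs: float
    window_s: tuple[float, float]
    labels: np.ndarray
    baseline_window_s: tuple[float, float]
    modality: str  # "EEG" | "HbO" | "HbR"
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels length must equal trial count")
        if self.data.shape[2] != len(self.channel_names):
            raise ValueError("channel_names length must equal channel count")

    @property
    def times_s(self) -> np.ndarray:
        """Onset-relative sample times."""
        start = self.window_s[0]
        return start + np.arange(self.data.shape[1]) / self.fs

    def crop(self, start_s: float, end_s: float) -> "EpochSet":
        """Sub-window [start_s, end_s) of every trial: exactly
        floor((end - start) * fs) samples starting at the first sample at
        or after ``start_s``."""
        t = self.times_s
        n_keep = int(np.floor((end_s - start_s) * self.fs + 1e-9))
        first = int(np.searchsorted(t, start_s - 1e-9))
        if n_keep < 1 or first + n_keep > len(t):
            raise ValueError("crop window outside epoch")
        sl = slice(first, first + n_keep)
        return EpochSet(self.data[:, sl, :], self.fs, (start_s, end_s),
                        self.labels, self.baseline_window_s, self.modality,
                        self.channel_names)

    def channel(self, name: str) -> np.ndarray:
        """trials × samples slice for one named channel."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch set") from None
        return self.data[:, :, i]


@dataclass
class HbEpochs:
    hbo: EpochSet
    hbr: EpochSet


def rereference_eeg(eeg: np.ndarray, mastoids: np.ndarray) -> np.ndarray:
    """Subtract the mastoid average from every channel, sample-wise."""
    eeg = np.asarray(eeg, float)
    mastoids = np.asarray(mastoids, float)
    if eeg.shape[0] != mastoids.shape[0]:
        raise ValueError("eeg and mastoid sample counts differ")
    return eeg - mastoids.mean(axis=1, keepdims=True)


def resample_eeg(eeg: np.ndarray, fs_in: float = 500.0, fs_out: float = 250.0) -> np.ndarray:
    """Anti-aliased integer-factor decimation along axis 0."""
    ratio = fs_in / fs_out
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(f"fs_in/fs_out must be an integer, got {ratio}")
    if factor == 1:
        return np.asarray(eeg, float).copy()
    y = sps.decimate(np.asarray(eeg, float), factor, ftype="fir", axis=0, zero_phase=True)
    n_out = int(np.floor(eeg.shape[0] * fs_out / fs_in))
    return y[:n_out]


def bandpass(x: np.ndarray, fs: float, low_hz: float, high_hz: float,
             order: int, zero_phase: bool = True) -> np.ndarray:
    """Butterworth band-pass along axis 0. Zero-phase by default."""
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz outside (0, {nyq}) Hz")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    x = np.asarray(x, float)
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def mbll(intensity_760: np.ndarray, intensity_850: np.ndarray,
         sd_distance_cm: float, fs: Optional[float] = None,
         dpf_760: float = C.DPF_760, dpf_850: float = C.DPF_850,
         reference_s: Optional[float] = C.MBLL_REFERENCE_S) -> HbSeries:
    """Invert the modified Beer-Lambert law.

    ΔOD_λ(t) = −log10(I_λ(t) / I_λ,ref) with the reference intensity taken
    as the mean over the first ``reference_s`` seconds (first sample when
    ``fs`` or ``reference_s`` is None). The 2×2 extinction system is solved
    per sample:

        [ΔHbO, ΔHbR]ᵀ = E⁻¹ · [ΔOD_760/(d·DPF_760), ΔOD_850/(d·DPF_850)]ᵀ

    Returns concentrations in µmol/L.
    """
    i760 = np.asarray(intensity_760, float)
    i850 = np.asarray(intensity_850, float)
    if np.any(i760 <= 0) or np.any(i850 <= 0):
        raise ValueError("optical intensities must be strictly positive")
    if sd_distance_cm <= 0:
        raise ValueError("sd_distance_cm must be > 0")
    if fs is not None and reference_s is not None:
        n_ref = max(1, int(np.round(reference_s * fs)))
    else:
        n_ref = 1
    ref760 = i760[:n_ref].mean(axis=0)
    ref850 = i850[:n_ref].mean(axis=0)
    od = np.stack([-np.log10(i760 / ref760) / (sd_distance_cm * dpf_760),
                   -np.log10(i850 / ref850) / (sd_distance_cm * dpf_850)], axis=-1)
    if abs(np.linalg.det(C.EXTINCTION)) < 1e-12:
        raise ValueError("extinction matrix is singular")
    conc = np.linalg.solve(C.EXTINCTION, od[..., None])[..., 0] / C.MICROMOLAR_TO_MOLAR
    fs_out = fs if fs is not None else 0.0
    return HbSeries(hbo=conc[..., 0], hbr=conc[..., 1], fs=fs_out)


def _moving_std(x: np.ndarray, n_win: int) -> np.ndarray:
    m = uniform_filter1d(x, n_win, mode="nearest")
    m2 = uniform_filter1d(x * x, n_win, mode="nearest")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def spline_motion_correct(x: np.ndarray, fs: float,
                          detection_window_s: float = C.MOTION_STD_WINDOW_S,
                          threshold_k: float = C.MOTION_STD_K) -> np.ndarray:
    """Moving-std artifact detection with cubic-spline removal.

    Samples whose moving standard deviation exceeds ``threshold_k`` times
    its median are grouped into segments; a cubic spline fitted through the
    segment is subtracted and the segment mean re-aligned to the preceding
    clean data. Clean signals pass through unchanged.
    """
    x = np.asarray(x, float)
    if x.ndim == 1:
        return _spline_correct_1d(x, fs, detection_window_s, threshold_k)
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        out[:, c] = _spline_correct_1d(x[:, c], fs, detection_window_s, threshold_k)
    return out


def _spline_correct_1d(x: np.ndarray, fs: float, win_s: float, k: float) -> np.ndarray:
    n = len(x)
    n_win = int(np.round(win_s * fs))
    if n_win > n:
        raise ValueError("detection window longer than signal")
    n_win = max(n_win, 2)
    mstd = _moving_std(x, n_win)
    med = np.median(mstd)
    if med == 0:
        return x.copy()
    bad = mstd > k * med
    if not bad.any():
        return x.copy()
    # pad detections by half a window so segment edges are included
    pad = n_win // 2
    bad = uniform_filter1d(bad.astype(float), 2 * pad + 1, mode="nearest") > 0
    out = x.copy()
    idx = np.flatnonzero(bad)
    splits = np.flatnonzero(np.diff(idx) > 1)
    segments = [(seg[0], seg[-1] + 1) for seg in np.split(idx, splits + 1)]
    # merge segments separated by a short gap: a step artifact is detected
    # only at its edges and the plateau between them must be included.
    # Plateaus longer than ~4 windows are not bridged.
    merged = [segments[0]]
    for a, b in segments[1:]:
        pa, pb = merged[-1]
        if a - pb < 4 * n_win:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))
    for a, b in merged:
        t = np.arange(a, b, dtype=float)
        if b - a >= 8:
            # interior knots every ~0.25 s capture the artifact trajectory
            step = max(int(np.round(0.25 * fs)), 2)
            knots = t[step:-step:step]
            if len(knots):
                spline = LSQUnivariateSpline(t, x[a:b], knots, k=3)
            else:
                spline = np.poly1d(np.polyfit(t, x[a:b], 3))
        else:
            spline = np.poly1d(np.polyfit(t, x[a:b], min(3, b - a - 1)))
        resid = x[a:b] - spline(t)
        if resid.std() > k * med:
            # spline rings on hard discontinuities; fall back to full
            # interpolation (segment carries no residual signal)
            resid = np.zeros_like(resid)
        # re-align: ramp from the preceding clean level to the following one
        # so both junctions stay continuous
        pre = out[max(0, a - n_win):a]
        post = x[b:min(n, b + n_win)]
        lo = pre.mean() if len(pre) else (post.mean() if len(post) else 0.0)
        hi = post.mean() if len(post) else lo
        ramp = np.linspace(lo, hi, b - a)
        out[a:b] = resid - resid.mean() + ramp
    return out


def epoch(x: np.ndarray, fs: float, events: EventList,
          window_s: tuple[float, float], baseline_window_s: tuple[float, float],
          modality: str = "EEG", channel_names: Optional[list[str]] = None) -> EpochSet:
    """Extract half-open [start, end) onset-locked windows and subtract the
    per-trial, per-channel baseline mean."""
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    start_s, end_s = window_s
    n_samp = int(np.floor((end_s - start_s) * fs + 1e-9))
    n = x.shape[0]
    trials = []
    for onset in events.onsets_s:
        i0 = int(np.round((onset + start_s) * fs))
        if i0 < 0 or i0 + n_samp > n:
            raise ValueError(f"event at {onset} s: window extends past the recording")
        trials.append(x[i0:i0 + n_samp])
    data = np.stack(trials)
    t_rel = start_s + np.arange(n_samp) / fs
    b0, b1 = baseline_window_s
    bmask = (t_rel >= b0 - 1e-9) & (t_rel < b1 - 1e-9)
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    data = data - data[:, bmask, :].mean(axis=1, keepdims=True)
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(data.shape[2])]
    return EpochSet(data=data, fs=fs, window_s=window_s, labels=events.labels,
                    baseline_window_s=baseline_window_s, modality=modality,
                    channel_names=channel_names)


# ---------------------------------------------------------------------------
# modality pipelines

def preprocess_eeg(session: RawSession, fs_out: float = C.EEG_FS_OUT,
                   band_hz: tuple[float, float] = C.EEG_BAND_HZ,
                   order: int = C.EEG_FILTER_ORDER,
                   window_s: tuple[float, float] = C.EEG_EPOCH_WINDOW_S,
                   baseline_s: tuple[float, float] = C.EEG_BASELINE_WINDOW_S,
                   zero_phase: bool = True,
                   filter_before_downsample: bool = False) -> EpochSet:
    """Re-reference → downsample → band-pass → epoch + baseline-correct."""
    x = rereference_eeg(session.eeg, session.mastoids)
    if filter_before_downsample:
        x = bandpass(x, session.fs_eeg, *band_hz, order, zero_phase=zero_phase)
        x = resample_eeg(x, session.fs_eeg, fs_out)
    else:
        x = resample_eeg(x, session.fs_eeg, fs_out)
        x = bandpass(x, fs_out, *band_hz, order, zero_phase=zero_phase)
    return epoch(x, fs_out, session.events, window_s, baseline_s,
                 modality="EEG", channel_names=session.eeg_names)


def preprocess_fnirs(session: RawSession,
                     band_hz: tuple[float, float] = C.FNIRS_BAND_HZ,
                     order: int = C.FNIRS_FILTER_ORDER,
                     window_s: tuple[float, float] = C.FNIRS_EPOCH_WINDOW_S,
                     baseline_s: tuple[float, float] = C.FNIRS_BASELINE_WINDOW_S,
                     motion_window_s: float = C.MOTION_STD_WINDOW_S,
                     motion_k: float = C.MOTION_STD_K,
                     zero_phase: bool = True) -> tuple[HbSeries, HbEpochs]:
    """MBLL → band-pass → spline motion correction → epoch.

    Returns both the continuous corrected series (GLM input) and the
    baseline-corrected epochs (feature input).
    """
    hb = mbll(session.fnirs_intensity[:, :, 0], session.fnirs_intensity[:, :, 1],
              session.montage.sd_distance_cm, fs=session.fs_fnirs)
    fs = session.fs_fnirs
    hbo = bandpass(hb.hbo, fs, *band_hz, order, zero_phase=zero_phase)
    hbr = bandpass(hb.hbr, fs, *band_hz, order, zero_phase=zero_phase)
    hbo = spline_motion_correct(hbo, fs, motion_window_s, motion_k)
    hbr = spline_motion_correct(hbr, fs, motion_window_s, motion_k)
    series = HbSeries(hbo=hbo, hbr=hbr, fs=fs)
    names = [f"ch{c.id:02d}" for c in session.montage.fnirs_channels]
    epochs = HbEpochs(
        hbo=epoch(hbo, fs, session.events, window_s, baseline_s, "HbO", names),
        hbr=epoch(hbr, fs, session.events, window_s, baseline_s, "HbR", names),
    )
    return series, epochs
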