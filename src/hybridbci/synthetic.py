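"""Seeded synthetic EEG-fNIRS sessions.

Generates raw sessions with the block paradigm the downstream pipeline
assumes: alternating rest/task trials of left- and right-hand movement,
lateralized class-locked effects, physiological noise, and dual-wavelength
optical intensities produced by a forward modified Beer-Lambert model so
that the preprocessing stage can invert them exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import hrf
from .constants import (
    EXTINCTION,
    DPF_760,
    DPF_850,
    MICROMOLAR_TO_MOLAR,
)

# Ratios tying HbR to the HbO effect waveforms. The dip is negative in HbO
# and positive (roughly half depth) in HbR; the main response washes out HbR.
HBR_HRF_RATIO = -1.0 / 3.0
HBR_DIP_RATIO = 0.5

LEFT_EEG = [
    ("FFT7h", -6.0, 3.0), ("FFC5h", -4.0, 3.0), ("FFC3h", -2.0, 3.0),
    ("FTT7h", -6.0, 1.0), ("FCC5h", -4.0, 1.0), ("FCC3h", -2.0, 1.0),
    ("CCP5h", -4.0, -1.0), ("CCP3h", -2.0, -1.0),
]
RIGHT_EEG = [(n.replace("7", "8").replace("5", "6").replace("3", "4"), -x, y)
             for n, x, y in LEFT_EEG]

_GRID_X = [-6.5, -5.0, -3.5, -2.0]
_GRID_Y = [3.5, 2.0, 0.5, -1.0, -2.5]


class MontageError(ValueError):
    pass


@dataclass(frozen=True)
class Electrode:
    name: str
    x: float
    y: float
    hemisphere: str


@dataclass(frozen=True)
class FnirsChannel:
    id: int
    source_id: str
    detector_id: str
    x: float
    y: float
    hemisphere: str


@dataclass
class Montage:
    """Electrode/optode geometry with hemisphere labels."""

    eeg_electrodes: list[Electrode]
    fnirs_channels: list[FnirsChannel]
    sd_distance_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.sd_distance_cm <= 0:
            raise MontageError("sd_distance_cm must be > 0")
        for e in self.eeg_electrodes:
            if e.hemisphere not in ("left", "right"):
                raise MontageError(f"electrode {e.name}: bad hemisphere {e.hemisphere!r}")
        for c in self.fnirs_channels:
            if c.hemisphere not in ("left", "right"):
                raise MontageError(f"channel {c.id}: bad hemisphere {c.hemisphere!r}")

    def channel(self, channel_id: int) -> FnirsChannel:
        for c in self.fnirs_channels:
            if c.id == channel_id:
                return c
        raise MontageError(f"no fNIRS channel with id {channel_id}")

    def channels_in(self, hemisphere: str) -> list[FnirsChannel]:
        return [c for c in self.fnirs_channels if c.hemisphere == hemisphere]

    def nearest_electrode(self, x: float, y: float) -> Electrode:
        """Nearest EEG electrode to a point; ties broken by name."""
        return min(self.eeg_electrodes,
                   key=lambda e: (np.hypot(e.x - x, e.y - y), e.name))

    def to_dict(self) -> dict:
        return {
            "sd_distance_cm": self.sd_distance_cm,
            "eeg_electrodes": [asdict(e) for e in self.eeg_electrodes],
            "fnirs_channels": [asdict(c) for c in self.fnirs_channels],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(
            eeg_electrodes=[Electrode(**e) for e in d["eeg_electrodes"]],
            fnirs_channels=[FnirsChannel(**c) for c in d["fnirs_channels"]],
            sd_distance_cm=d["sd_distance_cm"],
        )


def default_montage(n_fnirs: int = 34, sd_distance_cm: float = 3.0) -> Montage:
    """Idealized symmetric grid: 8 EEG electrodes and n/2 fNIRS channels per
    hemisphere, electrodes interleaved among channel midpoints."""
    if n_fnirs % 2 != 0:
        raise MontageError("n_fnirs must be even (split across hemispheres)")
    per_hemi = n_fnirs // 2
    grid = [(x, y) for y in _GRID_Y for x in _GRID_X]
    if per_hemi > len(grid):
        raise MontageError(f"montage grid supports at most {len(grid)} channels per hemisphere")
    electrodes = [Electrode(n, x, y, "left") for n, x, y in LEFT_EEG]
    electrodes += [Electrode(n, x, y, "right") for n, x, y in RIGHT_EEG]
    channels = []
    for i, (x, y) in enumerate(grid[:per_hemi]):
        channels.append(FnirsChannel(i + 1, f"S{i + 1}", f"D{i + 1}", x, y, "left"))
    for i, (x, y) in enumerate(grid[:per_hemi]):
        cid = per_hemi + i + 1
        channels.append(FnirsChannel(cid, f"S{cid}", f"D{cid}", -x, y, "right"))
    return Montage(electrodes, channels, sd_distance_cm)


@dataclass
class EventList:
    """Trial onsets, durations and class labels."""

    onsets_s: np.ndarray
    durations_s: np.ndarray
    labels: np.ndarray  # array of "left" / "right"

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.onsets_s) == len(self.durations_s) == len(self.labels)):
            raise ValueError("event columns must have equal length")
        if len(self.onsets_s) and np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        bad = set(self.labels) - {"left", "right"}
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.onsets_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset": self.onsets_s, "duration": self.durations_s,
                             "label": self.labels})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventList":
        return cls(df["onset"].to_numpy(float), df["duration"].to_numpy(float),
                   df["label"].to_numpy(object))


@dataclass
class SimConfig:
    """Parameters of one synthetic session.

    Setting ``eeg_effect_amp = dip_amp = hrf_peak_amp = 0`` defines the null
    model: left and right trial ensembles then differ only by noise.
    """

    n_trials_per_class: int = 25
    rest_s: float = 20.0
    task_s: float = 5.0
    # recording continues past the last task offset so late-trial epochs fit
    post_s: float = 16.0
    fs_eeg: float = 500.0
    fs_fnirs: float = 7.81
    n_eeg: int = 16
    n_fnirs: int = 34
    eeg_effect_amp: float = 10.0     # µV, contralateral early transient
    eeg_transient_center_s: float = 0.4
    eeg_transient_width_s: float = 0.15
    dip_amp: float = 0.4             # µmol/L, initial-dip depth in HbO
    hrf_peak_amp: float = 1.2        # µmol/L, main HbO response peak
    eeg_noise: float = 10.0          # µV white
    eeg_drift: float = 5.0           # µV slow common-mode
    fnirs_noise: float = 0.08        # µmol/L white
    drift_amp: float = 0.3           # µmol/L very-low-frequency drift
    mayer_amp: float = 0.2           # µmol/L at ~0.1 Hz
    resp_amp: float = 0.15           # µmol/L at ~0.25 Hz
    cardiac_amp: float = 0.2         # µmol/L at ~0.8 Hz
    motion_spike_rate: float = 0.5   # events per minute
    motion_spike_amp: float = 3.0    # µmol/L
    baseline_intensity: float = 1.0  # arbitrary units
    target_channels: dict = field(default_factory=lambda: {"left": 12, "right": 29})
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rest_s", "task_s", "fs_eeg", "fs_fnirs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("eeg_effect_amp", "dip_amp", "hrf_peak_amp", "eeg_noise",
                     "fnirs_noise", "drift_amp", "mayer_amp", "resp_amp",
                     "cardiac_amp", "motion_spike_rate", "motion_spike_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if set(self.target_channels) != {"left", "right"}:
            raise ValueError("target_channels must have keys 'left' and 'right'")

    @property
    def n_trials(self) -> int:
        return 2 * self.n_trials_per_class

    @property
    def duration_s(self) -> float:
        return self.n_trials * (self.rest_s + self.task_s) + self.post_s

    def null(self) -> "SimConfig":
        """Copy of this config with all class-effect amplitudes zeroed."""
        d = asdict(self)
        d.update(eeg_effect_amp=0.0, dip_amp=0.0, hrf_peak_amp=0.0)
        return SimConfig(**d)


@dataclass
class RawSession:
    """Synchronized raw EEG (µV) and fNIRS optical intensities."""

    eeg: np.ndarray               # samples × n_eeg, µV
    eeg_names: list[str]
    mastoids: np.ndarray          # samples × 2, µV
    fnirs_intensity: np.ndarray   # samples × n_fnirs × 2 (760, 850 nm)
    fs_eeg: float
    fs_fnirs: float
    events: EventList
    montage: Montage
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if np.any(self.fnirs_intensity <= 0):
            raise ValueError("fNIRS intensities must be strictly positive")
        dur_eeg = self.eeg.shape[0] / self.fs_eeg
        dur_f = self.fnirs_intensity.shape[0] / self.fs_fnirs
        last = self.events.onsets_s[-1] + self.events.durations_s[-1] if len(self.events) else 0.0
        if last > min(dur_eeg, dur_f):
            raise ValueError("events extend past the end of the recording")


def _event_schedule(cfg: SimConfig, rng: np.random.Generator) -> EventList:
    labels = np.array(["left"] * cfg.n_trials_per_class + ["right"] * cfg.n_trials_per_class,
                      dtype=object)
    rng.shuffle(labels)
    onsets = cfg.rest_s + np.arange(cfg.n_trials) * (cfg.rest_s + cfg.task_s)
    durations = np.full(cfg.n_trials, cfg.task_s)
    return EventList(onsets, durations, labels)


def _physio_noise(cfg: SimConfig, n: int, n_ch: int, rng: np.random.Generator) -> np.ndarray:
    """Structured fNIRS noise (µmol/L): white, drift, Mayer, respiration,
    cardiac, and sparse motion spikes. Sinusoid phases/frequencies vary per
    channel."""
    t = np.arange(n) / cfg.fs_fnirs
    out = cfg.fnirs_noise * rng.standard_normal((n, n_ch))
    for amp, f0, jitter in ((cfg.drift_amp, 0.008, 0.5),
                            (cfg.mayer_amp, 0.1, 0.15),
                            (cfg.resp_amp, 0.25, 0.15),
                            (cfg.cardiac_amp, 0.8, 0.1)):
        if amp == 0:
            continue
        freqs = f0 * (1.0 + jitter * (2 * rng.random(n_ch) - 1))
        phases = 2 * np.pi * rng.random(n_ch)
        out += amp * np.sin(2 * np.pi * np.outer(t, freqs) + phases)
    n_spikes = rng.poisson(cfg.motion_spike_rate * (n / cfg.fs_fnirs) / 60.0, size=n_ch)
    tau = 0.5  # s, spike decay
    for ch in range(n_ch):
        for _ in range(n_spikes[ch]):
            i0 = rng.integers(0, n)
            length = min(n - i0, int(np.ceil(5 * tau * cfg.fs_fnirs)))
            sign = rng.choice([-1.0, 1.0])
            decay = np.exp(-np.arange(length) / (tau * cfg.fs_fnirs))
            out[i0:i0 + length, ch] += sign * cfg.motion_spike_amp * decay
    return out


def hemoglobin_to_intensity(hbo: np.ndarray, hbr: np.ndarray,
                            sd_distance_cm: float,
                            baseline_intensity: float = 1.0) -> np.ndarray:
    """Forward modified Beer-Lambert model.

    Converts ΔHbO/ΔHbR (µmol/L) to dual-wavelength intensities around a
    positive baseline, using the same extinction coefficients and DPFs the
    preprocessing inversion applies.
    """
    conc = np.stack([hbo, hbr], axis=-1) * MICROMOLAR_TO_MOLAR  # mol/L
    dpf = np.array([DPF_760, DPF_850])
    od = np.einsum("tcj,wj->tcw", conc, EXTINCTION) * sd_distance_cm * dpf
    return baseline_intensity * 10.0 ** (-od)


def generate_session(cfg: SimConfig) -> RawSession:
    """Generate one seeded session.

    Class-locked effects are planted contralaterally: right-hand trials on
    the left-hemisphere target channel/electrode and vice versa. The truth
    record stores the planted locations and amplitudes.
    """
    rng = np.random.default_rng(cfg.seed)
    montage = default_montage(cfg.n_fnirs)
    ids = [c.id for c in montage.fnirs_channels]
    for hemi, cid in cfg.target_channels.items():
        if cid not in ids:
            raise ValueError(f"target channel {cid} not in montage")
        if montage.channel(cid).hemisphere != hemi:
            raise ValueError(f"target channel {cid} is not in the {hemi} hemisphere")
    events = _event_schedule(cfg, rng)

    n_f = int(np.round(cfg.duration_s * cfg.fs_fnirs))
    n_e = int(np.round(cfg.duration_s * cfg.fs_eeg))

    # --- ground-truth hemodynamics -------------------------------------
    k_hrf = hrf.hrf_kernel(cfg.fs_fnirs, cfg.task_s)
    k_dip = hrf.dip_kernel(cfg.fs_fnirs)
    hbo = np.zeros((n_f, cfg.n_fnirs))
    hbr = np.zeros((n_f, cfg.n_fnirs))
    col = {c.id: i for i, c in enumerate(montage.fnirs_channels)}
    contra = {"left": cfg.target_channels["right"], "right": cfg.target_channels["left"]}
    for onset, label in zip(events.onsets_s, events.labels):
        ch = col[contra[label]]
        i0 = int(np.round(onset * cfg.fs_fnirs))
        for kern, a_o, a_r in ((k_hrf, cfg.hrf_peak_amp, HBR_HRF_RATIO * cfg.hrf_peak_amp),
                               (k_dip, -cfg.dip_amp, HBR_DIP_RATIO * cfg.dip_amp)):
            sl = slice(i0, min(i0 + len(kern), n_f))
            seg = kern[: sl.stop - sl.start]
            hbo[sl, ch] += a_o * seg
            hbr[sl, ch] += a_r * seg
    truth_hbo, truth_hbr = hbo.copy(), hbr.copy()

    hbo = hbo + _physio_noise(cfg, n_f, cfg.n_fnirs, rng)
    hbr = hbr + 0.5 * _physio_noise(cfg, n_f, cfg.n_fnirs, rng)
    intensity = hemoglobin_to_intensity(hbo, hbr, montage.sd_distance_cm,
                                        cfg.baseline_intensity)

    # --- EEG ------------------------------------------------------------
    t_e = np.arange(n_e) / cfg.fs_eeg
    common = cfg.eeg_drift * np.sin(2 * np.pi * 0.05 * t_e + 2 * np.pi * rng.random())
    eeg = cfg.eeg_noise * rng.standard_normal((n_e, cfg.n_eeg)) + common[:, None]
    mastoids = cfg.eeg_noise * rng.standard_normal((n_e, 2)) + common[:, None]

    names = [e.name for e in montage.eeg_electrodes]
    target_electrodes = {}
    for hemi in ("left", "right"):
        c = montage.channel(cfg.target_channels[hemi])
        target_electrodes[hemi] = montage.nearest_electrode(c.x, c.y).name
    contra_el = {"left": target_electrodes["right"], "right": target_electrodes["left"]}

    n_tr = int(np.round(1.0 * cfg.fs_eeg))
    t_tr = np.arange(n_tr) / cfg.fs_eeg
    transient = cfg.eeg_effect_amp * np.exp(
        -0.5 * ((t_tr - cfg.eeg_transient_center_s) / cfg.eeg_transient_width_s) ** 2)
    for onset, label in zip(events.onsets_s, events.labels):
        ch = names.index(contra_el[label])
        i0 = int(np.round(onset * cfg.fs_eeg))
        sl = slice(i0, min(i0 + n_tr, n_e))
        eeg[sl, ch] += transient[: sl.stop - sl.start]

    truth = {
        "target_channels": dict(cfg.target_channels),
        "target_electrodes": target_electrodes,
        "eeg_effect_amp": cfg.eeg_effect_amp,
        "dip_amp": cfg.dip_amp,
        "hrf_peak_amp": cfg.hrf_peak_amp,
        "seed": cfg.seed,
    }
    session = RawSession(eeg=eeg, eeg_names=names, mastoids=mastoids,
                         fnirs_intensity=intensity, fs_eeg=cfg.fs_eeg,
                         fs_fnirs=cfg.fs_fnirs, events=events, montage=montage,
                         truth=truth)
    # stash noise-free truth for forward/inverse checks (not serialized)
    session.truth["_hbo"] = truth_hbo
    session.truth["_hbr"] = truth_hbr
    return session


# ---------------------------------------------------------------------------
# session directory round trip

_FMT = "%.17g"  # round-trippable float text


def _save_matrix(path: str, data: np.ndarray, names: list[str]) -> None:
    np.savetxt(path, data, fmt=_FMT, delimiter=",", header=",".join(names), comments="")


def _load_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"missing session file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    return df.to_numpy(float), list(df.columns)


def write_session(session: RawSession, dir_path: str) -> None:
    """Write a session as plain-text files (CSV/TSV/JSON)."""
    os.makedirs(dir_path, exist_ok=True)
    j = os.path.join
    _save_matrix(j(dir_path, "eeg.csv"), session.eeg, session.eeg_names)
    _save_matrix(j(dir_path, "mastoids.csv"), session.mastoids, ["M1", "M2"])
    ch_names = [f"ch{c.id:02d}" for c in session.montage.fnirs_channels]
    _save_matrix(j(dir_path, "fnirs_760.csv"), session.fnirs_intensity[:, :, 0], ch_names)
    _save_matrix(j(dir_path, "fnirs_850.csv"), session.fnirs_intensity[:, :, 1], ch_names)
    session.events.to_frame().to_csv(j(dir_path, "events.tsv"), sep="\t", index=False)
    meta = session.montage.to_dict()
    meta["fs_eeg"] = session.fs_eeg
    meta["fs_fnirs"] = session.fs_fnirs
    with open(j(dir_path, "montage.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    if session.truth is not None:
        truth = {k: v for k, v in session.truth.items() if not k.startswith("_")}
        with open(j(dir_path, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)


def read_session(dir_path: str) -> RawSession:
    j = os.path.join
    for fname in ("eeg.csv", "mastoids.csv", "fnirs_760.csv", "fnirs_850.csv",
                  "events.tsv", "montage.json"):
        if not os.path.exists(j(dir_path, fname)):
            raise FileNotFoundError(f"missing session file: {j(dir_path, fname)}")
    eeg, eeg_names = _load_matrix(j(dir_path, "eeg.csv"))
    mastoids, _ = _load_matrix(j(dir_path, "mastoids.csv"))
    i760, _ = _load_matrix(j(dir_path, "fnirs_760.csv"))
    i850, _ = _load_matrix(j(dir_path, "fnirs_850.csv"))
    with open(j(dir_path, "montage.json")) as fh:
        meta = json.load(fh)
    montage = Montage.from_dict(meta)
    if i760.shape[1] != len(montage.fnirs_channels):
        raise ValueError("intensity column count does not match montage channel count")
    events = EventList.from_frame(pd.read_csv(j(dir_path, "events.tsv"), sep="\t"))
    truth = None
    if os.path.exists(j(dir_path, "truth.json")):
        with open(j(dir_path, "truth.json")) as fh:
            truth = json.load(fh)
    return RawSession(eeg=eeg, eeg_names=eeg_names, mastoids=mastoids,
                      fnirs_intensity=np.stack([i760, i850], axis=-1),
                      fs_eeg=meta["fs_eeg"], fs_fnirs=meta["fs_fnirs"],
                      events=events, montage=montage, truth=truth)
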