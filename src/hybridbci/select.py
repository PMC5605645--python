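"""GLM-based channel selection.

Fits Y = Xβ + ε per fNIRS channel on the continuous preprocessed HbO
series, computes the left-vs-right contrast t-value, thresholds candidate
channels, picks the best channel per hemisphere and pairs it with the
nearest EEG electrode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import hrf
from . import constants as C
from .synthetic import EventList, Montage


class NoCandidateError(RuntimeError):
    """No channel reached significance in a hemisphere."""


@dataclass
class DesignMatrix:
    """N × 3 design: left regressor, right regressor, constant."""

    X: np.ndarray
    fs: float
    condition_names: tuple[str, ...] = ("left", "right", "constant")

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.condition_names):
            raise ValueError("design matrix column count mismatch")
        if not np.allclose(self.X[:, -1], 1.0):
            raise ValueError("last design column must be constant 1")


@dataclass
class GLMResult:
    beta: np.ndarray      # L × M
    sigma2: np.ndarray    # per-channel residual variance, dof = N - L
    dof: int
    tvalues: np.ndarray | None = None


@dataclass
class SelectedPair:
    fnirs_channel: int
    t_value: float
    eeg_electrode: str


@dataclass
class ChannelSelection:
    left: SelectedPair
    right: SelectedPair
    alpha: float
    dof: int
    candidates: dict = field(default_factory=dict)

    def electrodes(self) -> tuple[str, str]:
        return self.left.eeg_electrode, self.right.eeg_electrode

    def to_dict(self) -> dict:
        return {"left": asdict(self.left), "right": asdict(self.right),
                "alpha": self.alpha, "dof": self.dof,
                "candidates": self.candidates}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def build_design_matrix(events: EventList, fs: float, n_samples: int,
                        task_s: float | None = None) -> DesignMatrix:
    """One HRF-convolved boxcar column per class plus a constant."""
    if len(events) == 0:
        raise ValueError("empty event list")
    X = np.zeros((n_samples, 3))
    X[:, 2] = 1.0
    for j, label in enumerate(("left", "right")):
        u = np.zeros(n_samples)
        for onset, dur, lab in zip(events.onsets_s, events.durations_s, events.labels):
            if lab != label:
                continue
            i0 = int(np.round(onset * fs))
            i1 = int(np.round((onset + dur) * fs))
            u[i0:min(i1, n_samples)] = 1.0
        t = np.arange(int(np.round(hrf.HRF_DURATION_S * fs))) / fs
        h = hrf.double_gamma_hrf(t)
        X[:, j] = np.convolve(u, h)[:n_samples] / fs
    return DesignMatrix(X=X, fs=fs)


def glm_fit(Y: np.ndarray, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares per channel; sigma2 = RSS / (N − L)."""
    X = design.X
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, L = X.shape
    if Y.shape[0] != n:
        raise ValueError("Y and X sample counts differ")
    if n <= L:
        raise ValueError("need more samples than regressors")
    if np.linalg.matrix_rank(X) < L:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = n - L
    sigma2 = (resid ** 2).sum(axis=0) / dof
    return GLMResult(beta=beta, sigma2=sigma2, dof=dof)


def t_contrast(glm: GLMResult, c: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """t_m = cᵀβ_m / sqrt(σ̂²_m · cᵀ(XᵀX)⁻¹c), per channel.

    Channels with zero residual variance get ±inf with a warning rather
    than failing silently.
    """
    c = np.asarray(c, float)
    if c.shape != (glm.beta.shape[0],):
        raise ValueError("contrast length must match condition count")
    if not c.any():
        raise ValueError("contrast vector must not be all zeros")
    xtx_inv = np.linalg.inv(design.X.T @ design.X)
    var_scale = float(c @ xtx_inv @ c)
    effect = c @ glm.beta
    # residual variance at rounding level relative to the fitted effect means
    # the model reproduced Y exactly: flag as infinite t, don't fail silently
    scale = np.maximum((glm.beta ** 2).sum(axis=0), 1.0)
    degenerate = glm.sigma2 <= 1e-20 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(glm.sigma2 * var_scale)
        t = np.where(denom > 0, effect / np.where(denom > 0, denom, 1.0),
                     np.sign(effect) * np.inf)
    if degenerate.any():
        t = np.where(degenerate, np.sign(effect) * np.inf, t)
        warnings.warn("degenerate GLM fit: zero residual variance on some channels",
                      RuntimeWarning, stacklevel=2)
    glm.tvalues = t
    return t


def select_channels(tvalues: np.ndarray, montage: Montage, alpha: float,
                    dof: int, channel_ids: list[int] | None = None,
                    fallback: bool = False) -> ChannelSelection:
    """Pick the max-|t| significant channel per hemisphere and pair it with
    the montage-nearest EEG electrode.

    Candidates are channels with two-sided p < alpha. With no candidate in
    a hemisphere, raises :class:`NoCandidateError` unless ``fallback``,
    which then takes that hemisphere's global max-|t| channel.
    """
    tvalues = np.asarray(tvalues, float)
    if channel_ids is None:
        channel_ids = [ch.id for ch in montage.fnirs_channels]
    if len(channel_ids) != len(tvalues):
        raise ValueError("tvalues length must match channel count")
    col = {cid: i for i, cid in enumerate(channel_ids)}
    pvals = 2.0 * stats.t.sf(np.abs(tvalues), dof)
    picks = {}
    candidates = {}
    for hemi in ("left", "right"):
        chans = montage.channels_in(hemi)
        if not chans:
            raise ValueError(f"montage has no channels in hemisphere {hemi!r}")
        cand = [ch for ch in chans if pvals[col[ch.id]] < alpha]
        candidates[hemi] = [ch.id for ch in cand]
        pool = cand
        if not pool:
            if not fallback:
                raise NoCandidateError(
                    f"no significant channel in {hemi} hemisphere at alpha={alpha}")
            pool = chans
        best = max(pool, key=lambda ch: (abs(tvalues[col[ch.id]]), -ch.id))
        electrode = montage.nearest_electrode(best.x, best.y)
        picks[hemi] = SelectedPair(fnirs_channel=best.id,
                                   t_value=float(tvalues[col[best.id]]),
                                   eeg_electrode=electrode.name)
    return ChannelSelection(left=picks["left"], right=picks["right"],
                            alpha=alpha, dof=dof, candidates=candidates)


def select_from_hbo(hbo: np.ndarray, events: EventList, fs: float,
                    montage: Montage, alpha: float = C.GLM_ALPHA,
                    contrast: tuple[float, float, float] = (1.0, -1.0, 0.0),
                    fallback: bool = False) -> tuple[ChannelSelection, GLMResult]:
    """Full selection stage on a continuous preprocessed HbO series."""
    design = build_design_matrix(events, fs, hbo.shape[0])
    glm = glm_fit(hbo, design)
    t = t_contrast(glm, np.asarray(contrast), design)
    sel = select_channels(t, montage, alpha, glm.dof, fallback=fallback)
    return sel, glm
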