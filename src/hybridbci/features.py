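"""Early-temporal feature extraction and fusion.

EEG: final-level wavelet approximation coefficients of the 0-1 s window of
the two selected electrodes (22 coefficients each, 44 features). fNIRS:
per-class PCA trial filtering followed by mean HbO/HbR over the 0-2 s
initial-dip window of the two selected channels (4 features). Hybrid:
column concatenation after min-max normalization (48 features).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import constants as C
from .preprocess import EpochSet, HbEpochs
from .select import ChannelSelection
from .wavelets import dwt_approx

FNIRS_FEATURE_NAMES = ["fnirsL_hbo_mean", "fnirsL_hbr_mean",
                       "fnirsR_hbo_mean", "fnirsR_hbr_mean"]


@dataclass
class FeatureSet:
    """trials × d feature matrix with labels and a modality tag."""

    F: np.ndarray
    labels: np.ndarray
    modality: str  # "EEG" | "fNIRS" | "hybrid"
    feature_names: list[str] = field(default_factory=list)
    normalization_bounds: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, float)
        if self.F.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.F.shape[0] != len(self.labels):
            raise ValueError("label count must match trial count")
        if not self.feature_names:
            self.feature_names = [f"f{i:02d}" for i in range(self.F.shape[1])]
        if len(self.feature_names) != self.F.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n_trials(self) -> int:
        return self.F.shape[0]

    @property
    def dim(self) -> int:
        return self.F.shape[1]


def eeg_features(epochs: EpochSet, selection: ChannelSelection,
                 window_s: tuple[float, float] = C.EEG_FEATURE_WINDOW_S,
                 levels: int = C.DWT_LEVELS,
                 wavelet: str = C.DWT_WAVELET) -> FeatureSet:
    """Wavelet approximation coefficients, left electrode then right."""
    cropped = epochs.crop(*window_s)
    blocks = []
    names = []
    for side, electrode in (("L", selection.left.eeg_electrode),
                            ("R", selection.right.eeg_electrode)):
        trials = cropped.channel(electrode)  # trials × samples
        coeffs = np.stack([dwt_approx(tr, levels=levels, wavelet=wavelet)
                           for tr in trials])
        blocks.append(coeffs)
        names += [f"eeg{side}_a{levels}_{k:02d}" for k in range(coeffs.shape[1])]
    F = np.hstack(blocks)
    return FeatureSet(F=F, labels=epochs.labels, modality="EEG", feature_names=names)


def pca_trial_filter(X: np.ndarray, R: int = C.PCA_COMPONENTS,
                     return_info: bool = False):
    """Reconstruct a samples × trials matrix from its leading principal
    components.

    Trials (columns) are the observations; the mean trial waveform is
    removed, the top ``R`` principal directions over time are kept, and the
    reconstruction ``E_new @ (E_newᵀ X_c) + mean`` is returned. With
    ``return_info`` also returns (explained_variance_ratio, eigenvalues).
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be samples × trials")
    n, m = X.shape
    if m < 2:
        raise ValueError("need at least 2 trials for PCA")
    if R < 1:
        raise ValueError("R must be >= 1")
    if not X.any():
        raise ValueError("all-zero trial matrix: principal directions undefined")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s ** 2 / (m - 1)
    r = min(R, len(s))
    E_new = U[:, :r]
    X_recon = E_new @ (E_new.T @ Xc) + mean
    if return_info:
        total = eigvals.sum()
        evr = eigvals[:r].sum() / total if total > 0 else 1.0
        return X_recon, float(evr), eigvals
    return X_recon


def pca_filter_epochs(hb_epochs: HbEpochs, selection: ChannelSelection,
                      R: int = C.PCA_COMPONENTS,
                      trial_mask: Optional[np.ndarray] = None) -> HbEpochs:
    """Apply the PCA trial filter per class, per selected channel, per
    chromophore, in place of the raw epochs.

    Without ``trial_mask`` every trial of a class is both fitted and
    reconstructed with that class's basis. With ``trial_mask`` (training
    folds) the per-class bases are fitted on training trials only, and
    held-out trials — whose label must not inform the filter — are
    reconstructed with a pooled basis fitted on all training trials.
    """
    labels = hb_epochs.hbo.labels
    out = HbEpochs(
        hbo=_copy_epochs(hb_epochs.hbo),
        hbr=_copy_epochs(hb_epochs.hbr),
    )
    channels = {selection.left.fnirs_channel, selection.right.fnirs_channel}
    for eps in (out.hbo, out.hbr):
        for cid in channels:
            name = f"ch{cid:02d}"
            ci = eps.channel_names.index(name)
            src = hb_epochs.hbo if eps.modality == "HbO" else hb_epochs.hbr
            data = src.data[:, :, src.channel_names.index(name)]  # trials × samples
            for cls in ("left", "right"):
                rows = np.flatnonzero(labels == cls)
                fit_rows = rows if trial_mask is None else rows[trial_mask[rows]]
                if len(fit_rows) < 2:
                    continue
                basis = _pca_basis(data[fit_rows].T, R)
                eps.data[fit_rows if trial_mask is not None else rows, :, ci] = \
                    _pca_apply(data[fit_rows if trial_mask is not None else rows].T,
                               basis).T
            if trial_mask is not None:
                held = np.flatnonzero(~trial_mask)
                if len(held):
                    pooled = _pca_basis(data[trial_mask].T, R)
                    eps.data[held, :, ci] = _pca_apply(data[held].T, pooled).T
    return out


def _pca_basis(X_fit: np.ndarray, R: int) -> tuple[np.ndarray, np.ndarray]:
    """(mean, retained eigenvectors) of a samples × trials fit matrix."""
    mean = X_fit.mean(axis=1, keepdims=True)
    U, s, _ = np.linalg.svd(X_fit - mean, full_matrices=False)
    return mean, U[:, :min(R, U.shape[1])]


def _pca_apply(X: np.ndarray, basis: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    mean, E_new = basis
    return E_new @ (E_new.T @ (X - mean)) + mean


def _copy_epochs(eps: EpochSet) -> EpochSet:
    return EpochSet(eps.data.copy(), eps.fs, eps.window_s, eps.labels,
                    eps.baseline_window_s, eps.modality, list(eps.channel_names))


def initial_dip_features(hb_epochs: HbEpochs, selection: ChannelSelection,
                         window_s: tuple[float, float] = C.DIP_FEATURE_WINDOW_S
                         ) -> FeatureSet:
    """Per-trial mean HbO and HbR over the early window, ordered
    (left-HbO, left-HbR, right-HbO, right-HbR)."""
    cols = []
    for cid in (selection.left.fnirs_channel, selection.right.fnirs_channel):
        name = f"ch{cid:02d}"
        for eps in (hb_epochs.hbo, hb_epochs.hbr):
            cropped = eps.crop(*window_s)
            cols.append(cropped.channel(name).mean(axis=1))
    F = np.column_stack(cols)
    return FeatureSet(F=F, labels=hb_epochs.hbo.labels, modality="fNIRS",
                      feature_names=list(FNIRS_FEATURE_NAMES))


def minmax_normalize(fs: FeatureSet, mode: str = "paper",
                     train_idx: Optional[np.ndarray] = None) -> FeatureSet:
    """Column-wise rescaling to [0, 1].

    ``paper`` mode takes bounds over all trials; ``fold_safe`` takes them
    over ``train_idx`` only and clips held-out trials into [0, 1].
    Constant columns map to 0.
    """
    if fs.n_trials == 0:
        raise ValueError("empty feature set")
    if mode not in ("paper", "fold_safe"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    F = fs.F
    if mode == "fold_safe":
        if train_idx is None:
            raise ValueError("fold_safe mode requires train_idx")
        ref = F[np.asarray(train_idx)]
    else:
        ref = F
    lo = ref.min(axis=0)
    hi = ref.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    out = (F - lo) / safe
    out[:, span == 0] = 0.0
    if mode == "fold_safe":
        out = np.clip(out, 0.0, 1.0)
    return FeatureSet(F=out, labels=fs.labels, modality=fs.modality,
                      feature_names=list(fs.feature_names),
                      normalization_bounds=(lo, hi))


def fuse(eeg_fs: FeatureSet, fnirs_fs: FeatureSet) -> FeatureSet:
    """Column-concatenate [EEG | fNIRS] into the hybrid set."""
    if eeg_fs.n_trials == 0 or fnirs_fs.n_trials == 0:
        raise ValueError("cannot fuse an empty feature set")
    if eeg_fs.n_trials != fnirs_fs.n_trials:
        raise ValueError("trial counts differ between modalities")
    if not np.array_equal(eeg_fs.labels, fnirs_fs.labels):
        raise ValueError("label order differs between modalities")
    return FeatureSet(F=np.hstack([eeg_fs.F, fnirs_fs.F]), labels=eeg_fs.labels,
                      modality="hybrid",
                      feature_names=list(eeg_fs.feature_names) + list(fnirs_fs.feature_names))
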