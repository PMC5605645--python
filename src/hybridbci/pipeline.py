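"""End-to-end orchestration: simulate → preprocess → select → features →
classify, with per-stage artifacts and a machine-readable summary."""

from __future__ import annotations

import json
import logging
import os
import time
from typing import Optional

import numpy as np
import pandas as pd

from . import classify as clf
from . import features as feat
from . import preprocess as pre
from . import select as sel
from .config import PipelineConfig
from .synthetic import RawSession, generate_session, write_session

log = logging.getLogger("hybridbci")

MODALITIES = ("eeg", "fnirs", "hybrid")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, e) from e
            log.info("stage %-10s %.2f s", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def build_features(eeg_epochs: pre.EpochSet, hb_epochs: pre.HbEpochs,
                   selection: sel.ChannelSelection, cfg: PipelineConfig,
                   train_idx: Optional[np.ndarray] = None
                   ) -> dict[str, feat.FeatureSet]:
    """Raw (un-normalized) EEG and fNIRS feature sets.

    With ``train_idx`` the PCA trial filter is fitted on training trials
    only (held-out trials projected onto that basis).
    """
    mask = None
    if train_idx is not None:
        mask = np.zeros(eeg_epochs.data.shape[0], dtype=bool)
        mask[train_idx] = True
    filtered = feat.pca_filter_epochs(hb_epochs, selection,
                                      R=cfg.features.pca_components,
                                      trial_mask=mask)
    eeg_fs = feat.eeg_features(eeg_epochs, selection,
                               levels=cfg.features.dwt_levels,
                               wavelet=cfg.features.wavelet)
    fnirs_fs = feat.initial_dip_features(filtered, selection)
    return {"eeg": eeg_fs, "fnirs": fnirs_fs}


def classify_all(eeg_epochs: pre.EpochSet, hb_epochs: pre.HbEpochs,
                 selection: sel.ChannelSelection, cfg: PipelineConfig,
                 modalities: tuple[str, ...] = MODALITIES
                 ) -> dict[str, clf.ClassificationResult]:
    """LOOCV accuracies per requested modality in the configured mode."""
    spec = clf.ClassifierSpec(C=cfg.classifier.C, gamma=cfg.classifier.gamma)
    raw = build_features(eeg_epochs, hb_epochs, selection, cfg)
    norm = {k: feat.minmax_normalize(v, mode="paper") for k, v in raw.items()}
    sets = dict(norm)
    sets["hybrid"] = feat.fuse(norm["eeg"], norm["fnirs"])
    results = {}
    for m in modalities:
        if not cfg.features.fold_safe:
            results[m] = clf.loocv_svm(sets[m], spec, mode="paper")
        else:
            builder = _fold_builder(m, eeg_epochs, hb_epochs, selection, cfg, raw)
            results[m] = clf.loocv_svm(sets[m], spec, mode="fold_safe",
                                       fold_builder=builder)
    return results


def _fold_builder(modality: str, eeg_epochs: pre.EpochSet, hb_epochs: pre.HbEpochs,
                  selection: sel.ChannelSelection, cfg: PipelineConfig,
                  raw: dict[str, feat.FeatureSet]) -> clf.FoldBuilder:
    def build(train_idx: np.ndarray, test_idx: np.ndarray):
        fold_raw = build_features(eeg_epochs, hb_epochs, selection, cfg,
                                  train_idx=train_idx)
        parts_train, parts_test, labels = [], [], None
        wanted = ("eeg", "fnirs") if modality == "hybrid" else (modality,)
        for m in wanted:
            fs = fold_raw[m]
            normed = feat.minmax_normalize(fs, mode="fold_safe", train_idx=train_idx)
            parts_train.append(normed.F[train_idx])
            parts_test.append(normed.F[test_idx])
            labels = np.asarray(fs.labels)[train_idx]
        return np.hstack(parts_train), labels, np.hstack(parts_test)
    return build


def run_pipeline(cfg: PipelineConfig, out_dir: Optional[str] = None,
                 session: Optional[RawSession] = None,
                 modalities: tuple[str, ...] = MODALITIES) -> dict:
    """Execute every stage and return (and optionally write) the summary."""
    simulate = _stage("simulate")(lambda: generate_session(cfg.sim))
    if session is None:
        session = simulate()

    p = cfg.preprocess
    eeg_epochs = _stage("preprocess")(pre.preprocess_eeg)(
        session, fs_out=p.eeg_fs_out, band_hz=p.eeg_band_hz,
        order=p.eeg_filter_order, zero_phase=p.zero_phase,
        filter_before_downsample=p.filter_before_downsample)
    hb_series, hb_epochs = _stage("preprocess")(pre.preprocess_fnirs)(
        session, band_hz=p.fnirs_band_hz, order=p.fnirs_filter_order,
        motion_window_s=p.motion_window_s, motion_k=p.motion_k,
        zero_phase=p.zero_phase)

    selection, _ = _stage("select")(sel.select_from_hbo)(
        hb_series.hbo, session.events, session.fs_fnirs, session.montage,
        alpha=cfg.select.alpha, contrast=cfg.select.contrast,
        fallback=cfg.select.fallback)

    results = _stage("classify")(classify_all)(
        eeg_epochs, hb_epochs, selection, cfg, modalities=modalities)

    summary = {
        "seed": cfg.sim.seed,
        "mode": "fold_safe" if cfg.features.fold_safe else "paper",
        "selection": selection.to_dict(),
        "accuracies": {m: r.accuracy for m, r in results.items()},
        "n_trials": int(len(session.events)),
    }
    if session.truth is not None:
        truth = {k: v for k, v in session.truth.items() if not k.startswith("_")}
        summary["truth"] = truth
        summary["recovered_targets"] = {
            h: selection.to_dict()[h]["fnirs_channel"] == truth["target_channels"][h]
            for h in ("left", "right")
        }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_session(session, os.path.join(out_dir, "session"))
        selection.to_json(os.path.join(out_dir, "selection.json"))
        _write_features(eeg_epochs, hb_epochs, selection, cfg, out_dir)
        with open(os.path.join(out_dir, "results.json"), "w") as fh:
            json.dump({m: {"accuracy": r.accuracy,
                           "predictions": [str(x) for x in r.predictions],
                           "mode": r.mode} for m, r in results.items()},
                      fh, indent=1, sort_keys=True)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _write_features(eeg_epochs, hb_epochs, selection, cfg, out_dir: str) -> None:
    raw = build_features(eeg_epochs, hb_epochs, selection, cfg)
    for m, fs in raw.items():
        df = pd.DataFrame(fs.F, columns=fs.feature_names)
        df["labels"] = fs.labels
        df.to_csv(os.path.join(out_dir, f"features_{m}.csv"), index=False)
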