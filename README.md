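# hybridbci

A hybrid EEG-fNIRS brain-computer-interface pipeline for binary motor
classification, exercised end to end on seeded synthetic sessions:

1. **synthetic** — generates raw sessions (16-channel EEG at 500 Hz plus two
   mastoids, 34-channel dual-wavelength fNIRS intensities at 7.81 Hz) with a
   block paradigm of 25 left- and 25 right-hand trials (20 s rest, 5 s task),
   lateralized class-locked effects (an early EEG transient and a hemodynamic
   response with an initial dip), and structured noise (white, drift, Mayer
   ~0.1 Hz, respiration ~0.25 Hz, cardiac ~0.8 Hz, motion spikes). fNIRS
   intensities come from a forward modified Beer-Lambert model so the
   preprocessing stage inverts them exactly.
2. **preprocess** — EEG: mastoid re-referencing, downsampling to 250 Hz,
   1–45 Hz 3rd-order Butterworth (zero-phase); fNIRS: MBLL inversion
   (DPF 7.15 @ 760 nm, 6.38 @ 850 nm), 0.01–0.2 Hz 4th-order Butterworth,
   moving-std spline motion correction; onset-locked epoching with per-trial
   baseline subtraction.
3. **select** — a per-channel GLM on the continuous HbO series with
   HRF-convolved left/right regressors; the left-vs-right contrast t-value
   picks the max-|t| significant fNIRS channel per hemisphere and pairs it
   with the nearest EEG electrode.
4. **features** — 4-level Symlet-4 wavelet approximation coefficients of the
   0–1 s EEG window (22 per electrode → 44), per-class PCA trial filtering
   and 0–2 s initial-dip HbO/HbR means (4), min-max normalization and fusion
   into a 48-dimensional hybrid set.
5. **classify** — RBF-SVM (C = 1, γ = 1/d) under leave-one-out
   cross-validation with balanced training folds, plus summary statistics
   (range/sd normality check, paired t-tests).

The default feature/normalization mode replicates the original procedure
(PCA and normalization fitted once on all trials, which leaks held-out
information); `--fold-safe` refits both inside every training fold, with
held-out trials reconstructed by a pooled, label-agnostic PCA basis.

## CLI

```sh
hybridbci simulate --seed 1 --out session_dir          # write a session
hybridbci simulate --seed 1 --out nulldir --null       # zero class effects
hybridbci preprocess session_dir                       # write hbo/hbr.csv
hybridbci select session_dir --alpha 0.05              # selection.json
hybridbci classify session_dir --modality all          # results.json
hybridbci run-all --seed 1 --out run_dir [--fold-safe] # all stages
```

All stages accept `--config cfg.yaml`; see `hybridbci.config.PipelineConfig`
for the schema (unknown keys are rejected). Session directories are plain
text: `eeg.csv`, `mastoids.csv`, `fnirs_760.csv`, `fnirs_850.csv`,
`events.tsv`, `montage.json`, `truth.json`.

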