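# vigilance

Detection of physical-fatigue-induced inattention from wearable biosignals:
a tested, reusable pipeline covering synthetic paired-condition cohorts,
ECG heart-rate-variability features, skin-conductance (electrodermal)
decomposition, normality-gated paired statistics, and leave-one-subject-out
classifier evaluation.

## What it does

- **`vigilance.synthetic`** — generates paired-condition cohorts (one
  *focused* and one *distracted* session per subject) of ECG waveforms, skin
  conductance traces, and go/no-go behavioral responses, with a ground-truth
  channel (planted R-peak instants and SCR events) so every downstream stage
  can be tested against known answers. Fully deterministic per seed.
- **`vigilance.hrv`** — ECG band-pass filtering, Pan–Tompkins R-wave
  detection (adaptive dual thresholds, search-back, 200 ms refractory,
  sub-sample peak refinement), RR-series construction with median-filter
  artifact correction, and 14 HRV features: time-domain (mRR, SDRR, RMSSD,
  pNN50), Lomb–Scargle frequency-domain (VLF/LF/HF/TP, LF/HF, nLF, nHF),
  Poincaré (SD1/SD2), and approximate/sample entropy.
- **`vigilance.eda`** — continuous decomposition of skin conductance into a
  tonic baseline and a nonnegative phasic driver (Bateman-kernel
  deconvolution via FISTA + active-set polish), SCR event detection with a
  0.01 µS amplitude threshold, and 7 electrodermal features (SCR, nSCR,
  ISCR, Latency, AmpSum, PhasicMax, Tonic) inside a 5-minute response
  window.
- **`vigilance.paired`** — the paired-comparison decision procedure:
  1.5·IQR outlier screen and Shapiro–Wilk normality gate on the
  within-subject differences, then paired t-test or exact Wilcoxon
  signed-rank (enumeration for n ≤ 25, normal approximation above), with
  branch-matched descriptives (mean ± SD vs median (P25, P75)).
- **`vigilance.classify`** — per-fold z-score normalization,
  |t|-ranked backward feature elimination, leave-one-subject-out CV with
  grid search over four classifier families (RBF-SVM, KNN with a
  nearest-neighbor tie-break, LDA, random forest), and full evaluation
  (confusion matrix, accuracy, sensitivity, specificity, F1, ROC/AUC with
  *distracted* as the positive class).
- **`vigilance.pipeline` / `vigilance.cli`** — config-driven orchestration
  with a checksummed run manifest.

## CLI

```bash
vigilance simulate --subjects 30 --seed 1 --out data/           # cohort
vigilance extract-hrv --in data/sessions/S01_focused_ecg.csv --out hrv.csv
vigilance extract-eda --in data/sessions/S01_focused_gsr.csv --out eda.csv
vigilance stats --features features.csv --out stats.csv
vigilance train-eval --features features.csv --family knn \
    --feature-set combined --out report.json
vigilance run-all --seed 7 --out run_out/                       # everything
```

Sessions are stored as `time_s,value` CSVs with a JSON sidecar
(subject, condition, sampling rate, units); single-channel EDF input is also
supported for ECG. `run-all` accepts a YAML config overriding any pipeline
constant (effect sizes, filter bands, entropy parameters, SCR threshold,
classifier grids, ...).

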