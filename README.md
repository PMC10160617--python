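# maldi-tma

Classification analysis of MALDI mass-spectrometry-imaging (MSI)
tissue-microarray (TMA) cohorts — built for the question of whether
synovial-tissue peptide spectra discriminate patients treated with
leukocyte-poor platelet-rich plasma (LpPRP-1) from untreated patients
(LpPRP-0), and which m/z features carry that discrimination.

The package is aimed at computational proteomics researchers who want a
reproducible, fully tested version of this workflow:

1. **Synthetic cohort generation** — no raw spectra are publicly
   deposited, so a generator emulates the study cohort (289 classifiable
   patients, 128 LpPRP-1 / 161 LpPRP-0, duplicate cores on seven TMAs,
   muscle control cores) with a planted panel of 48 discriminative m/z
   features whose per-feature AUROCs are realized exactly: a feature with
   target AUROC *a* gets the class-mean shift δ = √2·Φ⁻¹(a) on a latent
   log-intensity axis, and all class signal flows through a single
   patient-level "treatment response" factor so the joint Bayes accuracy
   stays in the realistic Φ(Δ/2) ≈ 84% regime (see `docs/methods.md`).
2. **Preprocessing** — total-ion-count normalization and mass alignment
   by fixed-width binning (default 0.5 Da), annotation masking, patient
   mean spectra; imzML I/O via pyimzml.
3. **Feature screening** — per-feature AUROC (LpPRP-1 positive; values
   < 0.5 mean elevated in untreated tissue) and two-sided Wilcoxon
   rank-sum p (exact for small n), with the screening rule
   max(AUROC, 1−AUROC) ≥ 0.7 and p ≤ 0.001, plus forward stepwise
   selection maximizing cross-validated accuracy (gain threshold 0.001).
4. **Classification** — LDA and linear SVM under LOOCV and stratified
   10-fold CV, at the spectrum level (with per-patient majority voting)
   and the patient level, with nested feature selection, per-class
   correct/total counts, accuracy, F1, and random-guess baselines.
5. **QC** — random TMA-group Wilcoxon diagnostics, muscle-control
   stability, PCA/UMAP embeddings.

## Worked example

```python
from maldi_tma import CohortClassifier, CohortConfig, CVScheme, generate_cohort

sset, meta = generate_cohort(CohortConfig(spectra_per_core=5, seed=1))
model = CohortClassifier.from_spectra(
    sset, meta, level="patient", model="lda",
    scheme=CVScheme("kfold", k=10, seed=0),
)
results = model.fit()
print(results.summary())
```

prints

```
Treatment-group classification
==============================================
model:            LDA
cross-validation: kfold (k=10)
unit level:       patient
features used:    388
LpPRP-0:          146/161 correct
LpPRP-1:          111/128 correct
accuracy:         89%
F1 (LpPRP-0 pos): 0.90
baselines:        max-class 0.56, random-weighted 0.51
```

Reading: on a freshly generated 289-patient synthetic cohort, 10-fold
cross-validated LDA on patient mean spectra (388 aligned 0.5-Da bins)
recovers the treatment label for 257/289 patients (89%), far above the
55.7% majority-class and 50.7% prior-weighted random baselines; F1 is
reported with LpPRP-0 as the positive label.  The planted cohort is
calibrated so that published-style strategies land in the study's
77–90% accuracy band.

The full strategy table (spectrum-level voting, patient means,
AUROC-screened and forward-selected features, each with LDA and SVM) is
produced by the pipeline:

```sh
maldi-tma run-all --seed 0 --out runs/demo
maldi-tma report --run-dir runs/demo
```

Every run directory contains the config (with a SHA-256 hash stamped
into each output table), cohort metadata, the feature-statistics table,
the 12-row classification table, QC summaries and a log; re-running the
same config reproduces the tables byte for byte.

## Layout

```
src/maldi_tma/
  cohort.py       SpectrumSet / CohortMeta containers
  synth.py        synthetic cohort generator, effect-size calibration
  preprocess.py   TIC normalization, binning, masks, imzML I/O
  featstats.py    AUROC, Wilcoxon, screening, forward selection
  classify.py     CohortClassifier / ClassificationResults, CV, voting
  qc.py           random-group tests, embeddings, muscle stability
  pipeline.py     run_all orchestration, RunConfig
  cli.py          maldi-tma command-line interface
```

See `docs/methods.md` for the model, its assumptions, parameter
defaults, and known limitations.
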