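# qusr — quantitative ultrasound radiomics for early treatment-response prediction

`qusr` implements a week-1 quantitative-ultrasound (QUS) radiomics pipeline for
predicting tumour response to neoadjuvant chemotherapy from raw RF ultrasound
echo data, together with a synthetic RF data generator so that every stage is
exercisable without patient data.

The pipeline:

1. **`qusr.rf_synth`** — synthetic RF generation: Gaussian-enveloped cosine
   pulse (6.5 MHz centre, 3.0–8.5 MHz band, 40 MHz sampling), random
   point-scatterer media with controllable size / concentration / spacing /
   clustering, reference phantoms of known backscatter and attenuation, and
   two-timepoint patient cohorts with known responder (R) / non-responder (NR)
   labels (development-style n=100 at 19 % NR, validation-style n=51 at 12 % NR).
2. **`qusr.spectra`** — sliding-window Welch-style power spectra
   (2 mm × 2 mm Hann windows, 80 % overlap by default) and reference-phantom
   normalization that cancels the system transfer function.
3. **`qusr.qus_params`** — per-window estimation of the six QUS parameters:
   mid-band fit (MBF), spectral slope (SS), spectral intercept (SI),
   scatterer spacing (SAS), effective scatterer diameter (ASD, Gaussian form
   factor) and acoustic concentration (AAC), plus spectral-difference
   attenuation; assembled into ROI-masked parametric maps.
4. **`qusr.texture`** — grey-level co-occurrence matrix (GLCM) texture
   analysis of each parametric map (contrast, correlation, homogeneity,
   energy; 16 levels, distance 1, four angles averaged), the 31-feature
   vector per patient-timepoint (6 means + 24 textures + attenuation) and
   week1 − week0 delta features.
5. **`qusr.response_model`** — greedy forward feature selection (stratified-CV
   balanced accuracy) and an SVM-RBF classifier on standardized selected
   delta features. Positive class score ⇒ predicted non-responder.
6. **`qusr.evaluation`** — confusion matrix (NR = positive class),
   sensitivity / specificity / PPV / NPV / accuracy with exact
   Clopper–Pearson and standard logit confidence intervals, ROC/AUC, and
   per-feature unpaired (Welch) t-tests between response groups.
7. **`qusr.pipeline` / `qusr.cli`** — YAML-configured orchestration with a
   manifest (seeds, config digest, artifact SHA-256s) for end-to-end
   reproducibility.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the acceptance
criteria: exact reproduction of the reference validation metrics from the
reference confusion counts, oracle equivalence of the GLCM and texture
features against brute-force enumeration, spectral-fit identities,
reference-phantom system invariance (≤ 0.5 dB), parameter-recovery
tolerances (ASD within 5 %, AAC concentration-doubling shift 3.01 ± 0.5 dB,
SAS within one spectral bin, attenuation within 15 %), classifier sanity on
the default synthetic development cohort, confidence-interval correctness
and coverage, AUC identities, and a byte-reproducible end-to-end smoke run.

## CLI

```bash
qusr run-all --out out/ --seed 1                 # full pipeline, default demo config
qusr simulate --config cfg.yaml --out rf/        # write per-patient HDF5 RF scans
qusr extract  --config cfg.yaml --manifest rf/manifest.csv --out features/
qusr train    --deltas features/deltas.csv --labels features/labels.csv --out model.json
qusr predict  --model model.json --deltas features/deltas.csv --out preds.csv
qusr evaluate --predictions preds.csv --truth truth.csv [--exclude ids.txt]
```

All configuration lives in one YAML file validated against a strict schema
(unknown keys are rejected). With no `--config`, the built-in demo
configuration (development n=100 at 19 % NR, validation n=51 at 12 % NR,
3 frames per scan) is used; it completes on a single CPU in a few minutes.

## Notes and conventions

- Attenuation coefficients are one-way amplitude attenuation in dB·cm⁻¹·MHz⁻¹;
  round-trip power spectra decay by `2·α·f·z` dB at depth `z` cm.
- AAC is reported in relative dB; absolute physical backscatter units are not
  claimed.
- SAS is the dominant scatterer-spacing estimate (mm) from spectral-ripple
  autocorrelation; in parts of the clinical literature the same acronym is
  expanded "spectral average slope" — the naming discrepancy is documented,
  not silently resolved.
- Zero class scores predict the majority class (responder); scores within a
  configurable margin of zero are flagged as indeterminate.
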