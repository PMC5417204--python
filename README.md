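# nirscreen

Chemometric screening of medicines from handheld near-infrared (NIR)
diffuse-reflectance spectra in the 740–1,060 nm range:

* **Falsified-product detection** — spectral library matching: replicate
  scans are averaged, converted to absorbance, and Savitzky–Golay
  second-differentiated; a brand's quality-assured spectra define a PCA
  subspace with a score mean and covariance, and a test dose is accepted
  as genuine iff its Mahalanobis distance stays under a
  chi-square-quantile threshold. Falsified samples are never allowed into
  training sets, and quality-assured samples are evaluated with the batch
  under test excluded from training (leave-batch-out cross-validation).
* **Substandard-product detection** — single-response NIPALS partial
  least squares regression of % stated-API content on smoothed,
  baseline-subtracted absorbance, evaluated with leave-one-out
  cross-validation; quantitation accuracy is the SD of the cross-validated
  residuals (the ± coverage half-width is twice that SD), and predicted
  content is filtered by an inclusive 85–115 % tolerance band (90–110 %
  pharmacopeia band selectable).
* **Synthetic library generator** — a Beer–Lambert forward model
  (Gaussian-band component signatures, per-batch and per-sample baseline
  effects, triplicate scans with additive absorbance noise, bilayer
  tablets scanned per side) producing quality-assured, substandard and
  falsified doses with ground-truth labels, so the whole pipeline is
  testable without any measured data.

## CLI

```sh
nirscreen generate --config examples/library_config.yaml --out out/
nirscreen preprocess --spectra out/spectra.csv --pipeline qualitative --out out/d2.csv
nirscreen train-library --spectra out/spectra.csv --metadata out/metadata.csv \
    --brand EXAMPLE --out out/model.json
nirscreen authenticate --model out/model.json --spectra out/spectra.csv \
    --out out/verdicts.csv
nirscreen quantify --spectra out/spectra.csv --metadata out/metadata.csv \
    --brand EXAMPLE --component api --out out/quant.json
nirscreen report --spectra out/spectra.csv --metadata out/metadata.csv \
    --out out/report.txt
```

Every `generate` run echoes its fully-resolved config (with the seed) next
to its outputs, so results are regenerable from a committed config.

## File formats

Committed examples of every format live in `examples/`:

* `spectra.csv` — wide CSV: `sample_id,batch_id,brand,replicate,side,state`
  followed by one column per wavelength, named by its nm value; one row per
  scan. `state` is one of `reflectance`, `absorbance`, `smoothed`,
  `second_derivative`. Floats are written with 9 significant digits so
  writes are deterministic and roundtrips stable.
* `metadata.csv` — long CSV `sample_id,brand,batch_id,quality_class,
  component,sapi_percent`: one row per (sample, component) with the
  reference-assay % of label and the quality label
  (`quality_assured|substandard|falsified|degraded|unknown`).
* `class_model.json` / `plsr_model.json` — versioned JSON model documents
  (row-major arrays, wavelength grid included); loading reproduces
  predictions exactly, and a model refuses spectra on a different grid.
* `library_config.yaml` — generator config with an explicit `seed`.

## Layout

| module | role |
| --- | --- |
| `nirscreen.spectra` | core types: `Spectrum`, `SampleRecord`, `SampleSet` |
| `nirscreen.synthetic_data` | Beer–Lambert library generator |
| `nirscreen.scenarios` | ready-made separable-regime configurations |
| `nirscreen.spectra_io` | CSV/JSON readers and writers |
| `nirscreen.preprocess` | averaging, absorbance, Savitzky–Golay, baseline |
| `nirscreen.authenticate` | PCA–Mahalanobis library matching + evaluation |
| `nirscreen.quantify` | NIPALS PLSR, LOOCV, tolerance-band classification |
| `nirscreen.cli` | `nirscreen` command-line interface |
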