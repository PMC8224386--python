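# hsifresh

Hyperspectral-imaging chemometrics for predicting fish-fillet freshness
indicators — total volatile basic nitrogen (TVB-N, mg/100 g) and
thio-barbituric acid value (TBA, mg/kg) — from VIS-NIR reflectance cubes
(400–1000 nm, 472 bands).

The package implements the full workflow:

1. **Synthetic data** (`hsifresh.synthetic_data`) — a fillet hypercube
   simulator with Gaussian absorption features near 417/553/836/974 nm,
   per-pixel multiplicative/additive scatter, sensor noise, reference-assay
   noise, and spatial indicator fields whose fillet edges carry elevated
   values. Every downstream stage is testable offline against this
   generator's ground truth.
2. **Hypercube I/O** (`hsifresh.hypercube_io`) — ENVI header/raw
   reading and writing (BSQ/BIL/BIP), white/black reflectance calibration
   `(R₀ − B)/(W − B)`, ROI mean-spectrum extraction, dataset assembly.
3. **Preprocessing** (`hsifresh.preprocessing`) — multiplicative scatter
   correction (MSC), per-band z-score normalization, and a seeded 85:15
   hold-out split; all statistics fitted on the calibration set only.
4. **Calibration models** (`hsifresh.calibration_models`) — NIPALS PLSR
   with PRESS-driven latent-variable selection, and a numpy feed-forward
   network (LeakyReLU, width/depth grid search by cross-validated PRESS).
5. **Wavelength selection** (`hsifresh.wavelength_selection`) — optimal
   wavelengths as local extrema of the PLSR regression-coefficient vector;
   the published 35-wavelength (TVB-N) and 18-wavelength (TBA) lists ship
   as package fixtures.
6. **Evaluation** (`hsifresh.evaluation`) — r, R², and RMSE on calibration
   and prediction sets, with comparison-table reporting.
7. **Chemical maps** (`hsifresh.chemmap`) — pixel-wise indicator
   prediction over a fillet ROI and false-colour PNG rendering.
8. **Pipeline** (`hsifresh.pipeline`, `hsifresh.cli`) — one-config
   orchestration with a seeds-and-digests manifest for reproducibility.

## CLI

```bash
hsifresh simulate --indicator tvbn --n-fish 15 --seed 1 --out-dir sim/
hsifresh calibrate --model plsr --indicator tvbn --train train.csv --out model.json
hsifresh select --model model.json --prominence 0.0 --out subset.csv
hsifresh calibrate --model fnn --indicator tvbn --train train.csv \
    --subset subset.csv --out model_simplified.json
hsifresh evaluate --model model_simplified.json --train train.csv \
    --test test.csv --out report.csv
hsifresh map --cube sim/F001P01.hdr --mask sim/F001P01_mask.png \
    --model model_simplified.json --white sim/white.hdr --black sim/black.hdr \
    --out map.png
hsifresh run --config pipeline.yaml --out-dir run/   # full workflow
hsifresh schema                                      # pipeline config schema
```

Spectra CSVs use the layout `sample_id, wl_<nm>..., target`; wavelength
subsets are `index, wavelength_nm` CSVs; models serialize to a single JSON
file embedding their preprocessing chain.

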