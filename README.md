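# ftirprint

Chemometric classification and biomarker discovery for ATR-FTIR leaf
spectra. The package implements the full analysis chain used to
discriminate clonal plant material by geographic origin from its infrared
spectral fingerprint:

- **spectra_io** — wide-CSV/TSV and per-spectrum two-column text readers and
  writers for absorbance tables on a uniform wavenumber grid, with
  hierarchical sample metadata (region / site / cane / leaf position / leaf
  side / replicate) encoded in row labels.
- **preprocess** — fingerprint-region cut (1800–900 cm⁻¹), 9-point
  Savitzky–Golay second differentiation, unit-vector normalization,
  train-mean centering, and rubber-band (lower convex hull) baseline
  correction.
- **chemometrics_core** — SVD-based PCA and NIPALS PLS1 regression with
  venetian-blinds latent-variable selection.
- **classifiers** — PCA-LDA (Mahalanobis distance to class means under a
  pooled covariance, canonical scores) and one-vs-one RBF-kernel SVM with
  Platt class probabilities and grid-search hyperparameter tuning.
- **validation** — venetian-blinds fold assignment, stratified 70/30
  external split, and per-class quality parameters (sensitivity,
  specificity, precision; per-class accuracy = (sens + spec)/2).
- **biomarkers** — difference-between-mean-support-vector spectra (pairwise
  and one-vs-others), prominence-based peak picking, and molecular
  assignment against a bundled wavenumber reference table.
- **soil_env** — autoscaled soil PCA with Hotelling-T² outlier flags,
  Kruskal–Wallis tests with rank-based LSD post hoc and compact letter
  displays, and PLS correlation of spectra against soil/climate covariates.
- **synthetic_data** — a generator that emulates the hierarchical sampling
  design (7 sites × 3 canes × 3 leaves × 2 sides × 10 replicates = 1260
  spectra from 63 leaves) with Gaussian band structure, injected
  class-specific amplitude/position effects, baseline drift, multiplicative
  scatter and noise, plus soil/climate covariate tables — so every stage is
  testable without external data.
- **pipeline / cli** — config-driven end-to-end drivers and the `ftirprint`
  command.

## CLI

```sh
# generate a synthetic study-shaped dataset (wide CSV + truth sidecar)
ftirprint synth --out spectra.csv --seed 1 --soil-out soil.csv

# region or site classification: metrics, probabilities, biomarkers
ftirprint classify --input spectra.csv --label-field region --seed 1 --out out/

# spectra vs soil/climate correlation, soil PCA and letter displays
ftirprint envcorr --input spectra.csv --soil soil.csv --out env/
```

`classify` also accepts `--config run.yaml` (keys mirror `RunConfig` /
`PreprocessConfig` fields) plus `--cost`, `--gamma`, `--n-pcs` overrides.
Exit codes: 0 success, 1 configuration error, 2 runtime error.

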