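# fluorpheno

Kinetic chlorophyll-fluorescence and UV-excited multicolor fluorescence
phenotyping of rosette plants under drought stress, as a tested, fully
synthetic-data-driven pipeline:

- **`fluorpheno.protocol`** — the quenching-kinetics acquisition timeline
  (dark Fo window, Fm saturating flash at 5.56 s, 70 s of actinic light with
  saturating flashes at 32.24–92.24 s, dark-relaxation flashes at
  122.24–182.24 s), with validation and YAML round-tripping.
- **`fluorpheno.fluorsim`** — synthetic-data generator: rasterized rosette
  scenes, per-pixel physiology ground truth under control/drought severity
  presets (with leaf-tip/edge gradients and between-plant variation), and a
  forward model rendering timestamped fluorescence frame stacks plus the
  4-band × 5-exposure multicolor acquisition.
- **`fluorpheno.imaging`** — Otsu/fixed-threshold background segmentation,
  canopy-mean kinetic-trace extraction, projected leaf area.
- **`fluorpheno.fluorparams`** — base-signal location (Fo, Fm, Fp, Ft/Fm
  pairs at every flash; Fo′ via the Oxborough–Baker estimate) and the
  parameter catalogue: 89 chlorophyll parameters + 16 multicolor parameters
  (band means and all 12 ordered pairwise ratios) = 105 per sample.
- **`fluorpheno.stats`** — Welch treatment comparison with star coding,
  the |r| > 0.40 & P < 0.01 Pearson trait network (GraphML/CSV export), and
  the TBA-assay MDA computation (ε = 155 mM⁻¹ cm⁻¹).
- **`fluorpheno.phenoml`** — Fisher-criterion sequential forward selection
  (default k = 9 of 105), linear-SVM stratified 10-fold cross-validation
  with per-class/overall accuracy reporting, and the end-to-end per-day
  pipeline.

## CLI

```sh
fluorpheno simulate --preset day7 --n-control 54 --n-drought 54 --seed 7 --out cohort/
fluorpheno extract  --in cohort/ --out features.csv
fluorpheno select   --in features.csv --k 9 --out selection.json
fluorpheno classify --in features.csv --features selection.json --folds 10 --seed 7
fluorpheno report   --days day1,day3,day5,day7,day8 --out report/
```

Stacks are written as multi-frame 16-bit TIFF with a JSON sidecar
(times, light states, metadata); feature tables and reports as CSV.
A custom protocol can be supplied with `--protocol protocol.yaml`.

## Configuration

All defaults (protocol timings, simulator baselines, drought severity
presets, segmentation and classifier settings) live in
`src/fluorpheno/data/default_config.yaml`; `fluorpheno.config.load_config`
merges a user YAML over them.
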