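# speckleshock

A laser speckle contrast imaging (LSCI) toolkit for peripheral-perfusion
shock assessment. It covers the full measurement chain with synthetic
ground truth at every stage:

- **`speckleshock.simulate`** — synthetic raw speckle stacks from flow
  phantoms with known decorrelation-time maps (negative-exponential
  field autocorrelation, AR(1) sub-exposure integration, optional shot
  noise), two-group clinical cohort tables, and RR-interval series.
- **`speckleshock.contrast`** — sliding-window spatial speckle contrast
  (`K = sigma / mean`), temporal contrast as a cross-check, perfusion
  maps (`P = 1/K**2`), and stream decimation from 15 fps to a 2.7 Hz
  output rate.
- **`speckleshock.inversion`** — the single-exposure contrast models
  (with and without the speckle-averaging factor beta), bracketed
  numerical inversion to decorrelation time, velocity conversion
  (`v = lambda / (2 pi tau_c)`), and beta calibration from static stacks.
- **`speckleshock.roi`** — circular dual-ROI extraction (fingernail
  ROI1 vs fingertip-skin ROI2) and the shock statistics `roi_diff` and
  the gain-invariant `roi_diff / ROI2` over configurable windows.
- **`speckleshock.evaluate`** — cutoff classification (defaults:
  roi_diff < 6966.43, ratio < 0.36, SBP < 95, MAP < 65), confusion
  matrices and their inversion from printed summaries, ROC/AUC with the
  Youden-optimal criterion, Mann-Whitney U (exact for small samples),
  Spearman correlation, Cohen's d, shock index, and the disjunctive
  clinical screening rule.
- **`speckleshock.hrv`** — SDRR, RMSSD, pNN50, Poincare SD1/SD2,
  VLF/LF band power, sample entropy, and Higuchi fractal dimension.
- **`speckleshock.io` / `speckleshock.cli`** — TIFF + JSON stack I/O,
  CSV schemas, run manifests, and a subcommand CLI.

## CLI

```sh
speckleshock simulate-stack --seed 1 --output stack.tif \
    --kind two_region --tau 0.002 --tau 0.008 --shape 64 128
speckleshock contrast --stack stack.tif --output maps/
speckleshock simulate-cohort --seed 1 --output cohort.csv
speckleshock evaluate --cohort cohort.csv --metric roi_ratio \
    --cutoff 0.36 --output eval.csv
speckleshock invert --contrast 0.65752 --exposure 0.005 \
    --model fercher_briers --output invert.csv
speckleshock hrv --seed 1 --output hrv.csv
```

Every subcommand takes `--config` (TOML), `--seed`, `--output`, and
`--log-level`.

## Conventions

- Pixel coordinates are 0-based `(x, y)`; timestamps are seconds from
  recording start.
- Contrast windows use the population standard deviation; border pixels
  without a full window are masked, not padded.
- Static regions of a phantom are encoded as `tau_c = inf` and keep a
  frozen speckle realization across frames; static contrast squared
  equals beta.
- Classification ties at a cutoff are negative (non-shock).
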