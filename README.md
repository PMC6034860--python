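# chromaquant

Batch processing and targeted quantitation of HPLC-FD chromatograms
(time vs. fluorescence intensity), aimed at high-throughput glycan and
glycopeptide profiling:

- **I/O** — reads ThermoFisher-Chromeleon-style `.txt`, Waters-Empower-style
  `.arw` and plain two-column TSV exports; peak lists are 3-column TSV
  (name, retention time, half-window).
- **Peak detection** — smoothing-spline first-derivative bracketing plus
  iterative Gaussian fit-and-subtract until a relative intensity cutoff;
  produces a quantitation peak list (window = FWHM/2) and a suggested
  evenly spaced calibrant set.
- **Retention-time calibration** — degree-2 polynomial through
  S/N-gated calibrant peaks, applied as `t_new = f(t_observed)`.
- **Quantitation** — windowed integration (sampling interval × summed,
  background-subtracted intensities) with per-analyte local background
  and noise from the lowest-mean window.
- **Quality control** — residual retention time (spline apex vs.
  expected), signal-to-noise, and Gaussian Peak Quality (fitted-Gaussian
  area over integrated area; values away from 1 flag tailing, fronting
  and overlap).
- **Batch orchestration** — calibrate → quantify a folder of exports,
  aggregate per-analyte mean/SD/CV across replicates, optional
  normalised overlay plot, and the Fab-glycosylation composite metric.
- **Synthetic data** — seeded generator for multi-peak chromatograms
  (Gaussian and exponentially modified Gaussian shapes, baseline drift,
  white noise, polynomial retention warps, replicate jitter) with ground
  truth, used throughout the test suite.

## CLI

```sh
# write synthetic fixtures (any of the three dialects)
chromaquant simulate --out data/ --format chromeleon --n-replicates 9 --seed 1 --area-cv 0.01

# detect peaks and write a peak list (+ suggested calibrants)
chromaquant detect --input data/sim_rep1.txt --start 11.0 --end 25.0 \
    --cutoff 0.01 --out peaks.tsv --calibrants-out calibrants.tsv

# retention-time calibrate a folder
chromaquant calibrate --input data/ --calibrants calibrants.tsv \
    --min-sn 9 --min-calibrants 4 --out calibrated/

# quantify + aggregate a batch
chromaquant batch --input data/ --config examples/mab_glycopeptides.toml \
    --calibrants calibrants.tsv --analytes peaks.tsv --out results/ --overlay
```

Per-sample result tables (`*_results.tsv`) carry name, absolute and
relative area, background, noise, S/N, retention-time residual and GPQ;
`summary.tsv` holds per-analyte mean/SD/CV across the batch. Two example
configuration files are under `examples/`.

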