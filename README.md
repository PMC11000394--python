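# restalpha

Resting-state EEG alpha-rhythm case-control analysis, plus a seeded
synthetic-cohort generator so the full pipeline can be exercised and
verified without access to clinical recordings.

The pipeline, per subject:

1. **EDF input** — plain 16-bit EDF read/write with a 25-electrode clinical
   montage (ten-twenty sites + the inferior chain F9/F10, T9/T10, P9/P10);
   old nomenclature (T3/T4/T5/T6) is canonical, modern names (T7/T8/P7/P8)
   accepted on input.
2. **Preprocessing** — zero-phase Butterworth band-pass (1–45 Hz),
   re-referencing to the mean of T9/T10, and deterministic selection of the
   eight cleanest non-overlapping 20-s epochs by peak-to-peak screening
   (optional ICA-based blink removal).
3. **Spectra** — Welch PSD (Hann, 4-s segments, 50% overlap, 0.25 Hz
   resolution) averaged over epochs; the individual alpha peak frequency
   (IAF) is the largest local PSD maximum in 8–13 Hz (with flagged edge
   fallback), and the primary outcome is the mean PSD in the closed window
   IAF ± 1 Hz (µV²/Hz).
4. **Group statistics** — Lilliefors/KS normality check, Kruskal–Wallis
   omnibus on the per-subject ROI-mean alpha PSD, per-electrode two-sided
   Wilcoxon–Mann–Whitney post-hocs (exact for small tie-free samples),
   Benjamini–Hochberg FDR across the 11-electrode posterior ROI, medians
   and IQRs, and migraine-stratified IAF comparisons.
5. **Reports** — topographic median and p-value maps (thin-plate-spline
   interpolation, untested electrodes left blank), per-subject spectrum
   plots, IAF strata plots, and delimited/JSON tables.

The synthetic generator produces matched case/control cohorts: per channel a
1/f^β aperiodic background, a narrowband (1 Hz FWHM) alpha component with
posterior-dominant topography and per-subject peak frequency, white sensor
noise, and frontally weighted blink transients. Cases receive a
multiplicative alpha-amplitude factor `delta` at configurable effect
channels. Everything is deterministic given the seed, down to EDF bytes.

## CLI

```sh
restalpha simulate --config cohort.yaml --seed 1 --out-dir out/edf
restalpha metrics  --in-dir out/edf --out-dir out
restalpha stats    --in-dir out --out-dir out
restalpha report   --in-dir out --out-dir out
restalpha run-all  --config cohort.yaml --seed 1 --out-dir out
```

Example config:

```yaml
cohort:
  n_per_group: 21
  delta: 0.5
  duration: 200.0
  fs: 250.0
epochs:
  n_select: 8
iaf:
  mode: per_electrode   # or occipital_mean
```

Every parameter actually used is written to `parameters.json` alongside the
outputs.

## Layout

```
src/restalpha/
  montage.py     electrode montage: names, aliases, 2D positions, regions
  edfio.py       Recording type + plain 16-bit EDF reader/writer
  synth.py       synthetic subject/cohort generator
  preprocess.py  band-pass, re-reference, epoch screening, optional ICA
  spectral.py    Welch spectra, IAF detection, alpha-band PSD
  stats.py       MWU / KW / BH-FDR / KS, group comparison tables
  viz.py         topographic maps and figures
  pipeline.py    configuration and end-to-end glue
  cli.py         click-based CLI
tests/           pytest suite; test_acceptance.py holds the acceptance criteria
scripts/acceptance.py
```
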