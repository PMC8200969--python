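# dermaflux

Facial-skin photometry and longitudinal fluctuation analytics. The package
quantifies three skin-appearance metrics from calibrated RGB patch images —

- **pore area**: circular dark blobs detected on an edge-enhanced
  (difference-of-Gaussians) binary image of the cheek region, screened by
  area, circularity (`4πA/P²`) and contrast; total blob area per ROI area,
  in arbitrary units (au);
- **roughness**: RMS of the illumination-normalized relative-shadow map,
  band-passed with a radial Fourier annulus (fine-texture band);
- **redness**: brightness plus band-limited spatial variation of a
  hemoglobin-tone map (`log10(R/G)`, blotch-scale band) —

and analyzes them over an 8-week, three-sessions-per-day schedule
(morning after wake-up, morning after face wash, evening after face wash):
weekly averages, within-day **delta fluctuation** (max − min of the three
timepoints), paired Wilcoxon signed-rank baseline/treatment comparisons with
Holm adjustment, and Welch's t between cohorts.

Every image is color-calibrated first against a neutral **gray tip** at a
fixed frame location (per-channel linear gain), which makes all three scores
invariant to channel casts.

Because no public data exist for this kind of capture, the package ships a
first-class synthetic module: ground-truth patch generation (pores, in-band
texture, chromatic blotch fields, illumination gradients, gray tip, channel
gains) and cohort simulation (`value = μ + b_subject + τ_timepoint +
δ_treatment + ε`), in both values mode and rendered-image mode, so the whole
pipeline is testable end to end.

## CLI

```bash
# simulate a cohort (values or rendered 256×256 images + sidecar.csv)
dermaflux simulate-cohort --mode images --seed 1 --out cohort/

# batch analysis: calibrate + score every image listed in the sidecar
dermaflux analyze --image-dir cohort/images --sidecar cohort/images/sidecar.csv \
    --config cfg.yaml --out metrics.csv

# single-image metrics
dermaflux pores     --image x.tiff --roi 96,480,96,480 --out pores.csv
dermaflux roughness --image x.tiff --roi 96,480,96,480 --band 0.02,0.15 --out r.csv
dermaflux redness   --image x.tiff --roi 96,480,96,480 --band 0.005,0.05 --out h.csv

# weekly tables, comparisons and fluctuation plot
dermaflux report --records metrics.csv --metric pore_area --out report/
```

Configuration is YAML (`--config`), merged over defaults with unknown keys
rejected; every run writes its fully-resolved config next to its outputs.
Exit codes: 0 clean, 1 hard error, 2 completed with skipped files.

## Layout

```
src/dermaflux/
  core_io.py      image/table I/O, ROI handling, shared data model
  calibration.py  gray-tip per-channel gain calibration
  pores.py        DoG → robust binarization → shape-screened blob area
  roughness.py    relative-shadow map + Fourier annulus RMS
  redness.py      hemoglobin map, brightness + variation decomposition
  stats.py        Wilcoxon signed-rank (exact/approx), Welch's t, Holm
  fluctuation.py  triples, weekly averages, delta fluctuation, comparisons
  synthetic.py    ground-truth patch generator and cohort simulator
  batch.py        sidecar-driven batch orchestration
  config.py, cli.py
```
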