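# scopeqc

Automated confocal-microscope performance monitoring as a batch library +
CLI: laser stability and noise, axial resolution and chromatic correction,
field-illumination uniformity, multi-channel bead co-registration, point
spread function metrology, spectral-detector (lambda-scan) accuracy,
motorised-stage repeatability/accuracy, and Z-focus drift — with tab-delimited
measurement output and an amendable per-system, per-objective HTML record.

## Input model

Recordings are keyword-named multi-page TIFF stacks (one directory per
objective lens), each accompanied by a plain-text sidecar
(`<stem>.meta.yaml` or `.meta.json`) carrying the physical calibration:

```yaml
pixel_size_xy_um: 0.03
z_step_um: 0.15
frame_interval_s: 20.0
channel_wavelengths_nm: [405, 488, 561, 633]
size_t: 1
size_c: 4
size_z: 21
# optional: wavelength_axis_nm, stage_positions_um, bit_depth, axes_sign
```

Pages are ordered T-slowest, then C, then Z. Sidecar values always win over
embedded TIFF metadata (a disagreement is logged). Recognised file-stem
keywords: `laser`, `axial405`, `axial488`, `field<nm>`, `bead`, `psf`,
`scanpmt<k>`, `grid`, `stage1`–`stage3`, `stageacc1`–`stageacc3`, `zgalvo`.
File and folder names must not contain spaces.

A line-oriented configuration file lists the installed objectives and the
laser lines used per assay:

```
system=MyScope
objectives=10x,20x,63x
lasers.field=405,488,561,633
lasers.scan=488,561,633
```

## CLI

```sh
# generate a complete synthetic dataset (every keyword) with known truth
scopeqc demo --out demo_data --seed 1

# analyse one objective's directory; appends to measurements.tsv and amends
# the HTML record (prior entries are preserved byte-for-byte)
scopeqc run --config demo_data/scopeqc_config.txt --objective 10x \
            --input demo_data/10x --out results_dir

# regenerate the HTML tree from the TSV alone (the TSV is the source of truth)
scopeqc report --rebuild --tsv results_dir/measurements.tsv --html html_dir
```

Outputs: `measurements.tsv` (columns: timestamp, system, objective, assay,
parameter, value, units), PNG figures per assay, and a static HTML tree
`html/<system>/index.html` + `html/<system>/<objective>.html`.

## Library layout

| module | role |
| --- | --- |
| `scopeqc.core` | data model (`ImageStack`), config parsing, keyword discovery, TIFF+sidecar I/O |
| `scopeqc.profiles` | 1-D profile extraction, peak/FWHM measurement, Gaussian fitting |
| `scopeqc.laser` | intensity drift/noise traces and µs-to-hour change histograms |
| `scopeqc.axial` | XZ reflection-band peak/FWHM per channel, chromatic Δz, Z-drift traces |
| `scopeqc.field` | flat-field smoothing, centre profiles, fall-off percentages |
| `scopeqc.beads` | 3-D bead centroids, pairwise XY/Z co-registration, PSF FWHMs |
| `scopeqc.spectral` | lambda-scan peak detection and laser-line matching |
| `scopeqc.stage` | bead tracking, repeatability/accuracy statistics, grid pass-through |
| `scopeqc.fixtures` | seeded synthetic recordings with ground truth for every assay |
| `scopeqc.reporting` | TSV persistence, amendable HTML record, batch orchestration |

Conventions: 0-based pixel-centre coordinates (position = index × spacing);
population standard deviations throughout; FWHM half level measured above
the profile minimum; percentage intensity changes normalised by the
whole-series mean.

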