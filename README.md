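# fretmix

Quantitative analysis of genetically encoded ratiometric FRET metabolite
sensors (lactate / pyruvate / 2-oxoglutarate class) imaged in strongly
autofluorescent tissue.

Tissue autofluorescence is spatially heterogeneous, so subtracting one
background constant per channel makes the apparent FRET ratio depend on the
sensor expression level. `fretmix` implements the corrective method: a
dedicated third emission window (~600 nm) in which only autofluorescence is
detected lets a per-pixel three-species **linear unmixing** (donor
fluorophore, acceptor fluorophore, autofluorescence) remove the
autofluorescence contribution at single-pixel resolution, yielding FRET
maps that are independent of expression level. The constant-background
baseline is also provided for comparison.

The package contains:

- `fretmix.image_io` — multi-page TIFF acquisitions (donor ~490 nm,
  acceptor ~530 nm, autofluorescence ~600 nm windows), float32 FRET maps
  with NaN-coded invalid pixels + sidecar validity masks, integer label
  masks; explicit caller-supplied channel ordering, saturation flagging.
- `fretmix.unmixing` — spectral signature estimation from control /
  single-fluorophore references, 3×3 mixing-matrix construction with
  condition-number guard, vectorized per-pixel solve (unconstrained+clamp
  or NNLS), constant-background baseline, FRET-map construction with
  validity thresholding.
- `fretmix.sensor_model` — single-site binding model, dose-response
  (Kd, r_max, r_min) calibration by nonlinear least squares, acceptor
  photobleaching analysis (donor de-quenching), direct acceptor-excitation
  control, donor/acceptor anti-correlation across cells.
- `fretmix.quantify` — per-ROI statistics of FRET maps, time courses,
  control normalization, and the comparison pipeline: Shapiro–Wilk-gated
  Student's t / Mann–Whitney for two groups; Shapiro–Wilk + Levene with
  Box-Cox fallback, one-way ANOVA and two-sided Dunnett many-to-one
  comparisons for multiple groups.
- `fretmix.synthetic` — forward simulator (Voronoi cell mosaic, per-cell
  expression and metabolite concentration, smoothed-lognormal + granule
  autofluorescence field, Poisson photon + Gaussian read noise) providing
  ground truth for every test.
- `fretmix.benchmarks` — end-to-end reference benchmarks (expression
  independence, solver-oracle agreement, per-cell recovery, photobleach
  closed form, dose-response recovery, anti-correlation, statistical
  calibration, constant-AF limit equivalence).

## CLI

```sh
fretmix simulate --seed 7 --out bundle/           # synthetic tissue bundle
fretmix unmix bundle/acquisition.tif --out run/   # ratio + mask TIFF + JSON summary
fretmix quantify run/fret_map.tif bundle/cell_labels.tif --out run/
fretmix compare groups.csv --control ctrl --out run/
fretmix dose-response titration.csv --out run/
fretmix timecourse f0.tif f1.tif --mask labels.tif --out run/
```

Configuration is a TOML file (`--config`) validated strictly (unknown keys
rejected); flags override config values. Exit codes: 0 ok, 2 config error,
3 I/O error, 4 numerical failure. Every command writes a JSON manifest with
the package version, config hash and seed.

## Assumptions

- The autofluorescence spectral *shape* is spatially uniform; only its
  amplitude varies per pixel. This is the key assumption of the
  three-channel design.
- The FRET signal is the acceptor/donor abundance ratio by default
  (sensitized-emission ratio, configurable); for these sensors metabolite
  binding separates the fluorophore pair and abolishes FRET, so high ratio
  corresponds to low metabolite.
- Shipped `SensorSpec` defaults are uncalibrated placeholders; simulations
  define their own ground truth.
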