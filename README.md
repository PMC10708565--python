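# spectransfer

A chemometrics toolkit for predicting log10 total viable count (TVC, in
log10 CFU/g) from NIR hyperspectral reflectance spectra when the same
samples exist in two physical forms (crushed vs. full/intact). The crushed
form gives cleaner spectra and a better model; `spectransfer` transfers
full-form spectra into the crushed model's space with direct
standardization (DS) and augments the calibration set with transferred
spectra (hybrid models) so the crushed-form model predicts intact samples
accurately.

## What's inside

| Module | Purpose |
| --- | --- |
| `spectransfer.hsi_io` | ENVI / flat-table cube reading, white/dark reflectance calibration, ROI mean spectra, replicate averaging, tabular spectra I/O |
| `spectransfer.preprocessing` | Multiplicative scatter correction (MSC) with a frozen calibration reference |
| `spectransfer.variable_selection` | CARS wavelength screening (exponentially decreasing retention schedule, adaptive reweighted sampling, PLS-based weights), two-form union rule, wavelength-to-band mapping |
| `spectransfer.sample_selection` | Kennard–Stone and SPXY subset selection, seeded 4:1 splits, cross-form standard-sample pairing |
| `spectransfer.calibration_transfer` | DS transfer matrix via truncated-SVD pseudoinverse, application with mean-offset handling, standard-sample-number (SSN) optimization by minimum RMSEP |
| `spectransfer.modeling` | ε-SVR training (seeded grid search), cross-validation, R²/RMSE/RPD/RER metrics, hybrid-model construction and sweeps, model comparison |
| `spectransfer.microbiology` | Plate-count TVC and log10 transform |
| `spectransfer.synthetic_fixtures` | Paired crushed/full synthetic datasets with known generative truth, and synthetic raw-count cubes |
| `spectransfer.pipeline` | End-to-end orchestration (`run_experiment` / `run_pipeline`) with single-seed reproducibility |
| `spectransfer.cli` | `spectransfer` command-line entry point |

## CLI

```bash
# simulate a paired fixture and run the whole workflow on it
spectransfer simulate --n 100 --seed 42 --out-dir fixtures/
spectransfer run --seed 1 --out-dir runs/demo

# individual stages
spectransfer extract-roi --cube cube.hdr --white white.csv --dark dark.csv \
    --foreground fg.csv --margin-mm 2 --px-per-mm 4 --out spectra.csv
spectransfer preprocess --method msc --in spectra.csv --out corrected.csv --model msc.json
spectransfer select-vars --in corrected.csv --ref tvc.csv --iterations 50 --seed 7 --out vars.json
spectransfer split --in corrected.csv --seed 42 --ratio 4:1 --out split.json
spectransfer select-standards --in cs.csv --ref tvc.csv --method spxy --n 70 --out std.json
spectransfer transfer --slave fs_std.csv --master cs_std.csv --in fs.csv \
    --svd-tol 1e-6 --out fs_transferred.csv --model ds.json
spectransfer train --in cs.csv --ref tvc.csv --seed 7 --model svr.json
spectransfer hybrid-sweep --base cs.csv --base-ref tvc.csv --added fs_t.csv \
    --added-ref tvc.csv --eval fs_pred.csv --eval-ref tvc.csv --k-grid 5:80:5 --out sweep.csv
spectransfer tvc --counts counts.csv --out tvc.csv
```

`spectransfer run` also accepts a TOML config (`--config pipeline.toml`)
with sections `io`, `msc`, `cars`, `split`, `standards`, `transfer`,
`model`, `hybrid` and a single master `seed` from which every stage seed is
derived, so one seed reproduces the whole run.

## Reproducibility notes

- Every stochastic operation (splits, Monte-Carlo subsampling in CARS, SVR
  tuning folds, fixtures) takes an explicit seed; identical seeds give
  bit-identical results.
- Reflectance is never clamped to [0, 100]; MSC is affine-invariant so
  out-of-range values are retained (and logged).
- DS is fitted on column-centred standard matrices; unknown spectra are
  centred with the slave standard mean and shifted onto the master standard
  mean after multiplication, so the per-wavelength offset term is handled
  exactly.
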