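# sptdiff

Single-particle-tracking diffusion analysis for membrane proteins on rod-shaped
bacteria: a Monte Carlo track simulator (Brownian motion on a cylindrical
membrane with fast/slow state switching, a TIRF visibility window, projection
to the image plane and localization noise), MSD-based diffusion estimation with
bootstrap and permutation inference, and multi-lag step-size CDF fitting that
decomposes a track population into mobile and immobile fractions.

## What is in the box

| module | contents |
| --- | --- |
| `sptdiff.simcell` | `CellGeometry`, `DiffusionModel`, `SimulationConfig`, surface stepping, TIRF projection, `simulate_tracks` (cylinder + TIRF + switching) and `simulate_planar_tracks` (free-plane reference generator) |
| `sptdiff.track_io` | `Track`/`TrackSet`, CSV read/write with validation, length filtering (default 4–12 points) |
| `sptdiff.diffusion_stats` | ensemble MSD (per-track mean, s.e.m. over tracks), apparent D from an OLS fit to the first four MSD points, track bootstrap, label-permutation test, growth-rate helper |
| `sptdiff.stepsize_cdf` | pooled squared displacements at lags 1–4 frames, one-/two-species CDF models `1 − exp(−r²/(4Dt + 4σ²))`, joint multi-lag bounded least-squares fit with deterministic multi-start, BIC + nested-F model comparison |
| `sptdiff.pipeline` / `sptdiff.cli` | configured end-to-end runs with provenance (config echo + hash), deterministic outputs |

Track CSV schema: header `track_id,condition,frame,x_um,y_um`, one row per
localization, μm coordinates with 6 decimals, 0-based frames.  The frame
interval and provenance live in a sidecar `<name>.meta.json`.

## CLI

```sh
sptdiff simulate --config sim.yaml --out out/            # tracks.csv + truth.csv
sptdiff msd      --tracks tracks.csv --seed 1 --out out/ # msd.csv + diffusion.json
sptdiff fit-cdf  --tracks tracks.csv --seed 1 --out out/ # cdf_fit.json + cdf_table.csv
sptdiff compare  --tracks-a a.csv --tracks-b b.csv --seed 1 --out out/
sptdiff report   --config run.yaml [--config-b run_b.yaml] --out out/
```

Exit codes: 0 success, 2 validation failure, 3 fit non-convergence.  `--seed`
is required wherever randomness enters; identical configs give byte-identical
outputs.

A minimal simulation config (JSON or YAML):

```yaml
seed: 1
n_molecules: 5000
mixture_mode: kinetic
geometry: {radius: 0.5, length: 3.0, tirf_depth: 0.125}
model:
  d_fast: 0.05
  d_slow: 0.0
  alpha: null            # derived from the switching rates
  sigma_loc: 0.03
  rate_fast_to_slow: 5.0
  rate_slow_to_fast: 5.0
  frame_interval: 0.03
```

## Conventions

- σ is the **per-coordinate** localization SD; a displacement between two
  noisy localizations adds 4σ² to the squared-displacement scale (and to the
  MSD intercept).
- MSD is the mean over tracks of per-track mean squared displacements using
  all overlapping pairs at each frame lag; uncertainty is the s.e.m. over
  tracks.
- The CDF fit estimates one parameter vector jointly across all lags; the
  reported BIC scores the sample likelihood of the squared displacements, not
  the (correlated) pointwise CDF residuals.
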