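# sdmuq — simulating uncertainty in species distribution models

`sdmuq` is a Monte Carlo tool for making the uncertainty in species
distribution models (SDMs) visible. Correlative SDMs are routinely projected
at fine resolution onto current and future climates without any statement of
how fragile those maps are to error in the inputs. `sdmuq` takes the inputs
of a presence–background SDM — occurrence points and monthly climate grids —
perturbs them according to explicit error models, refits the SDM for each
perturbed replicate, and aggregates the thresholded predictions into a
**presence-probability map**: the per-cell proportion of model runs that
predict presence. Where the map is 0 or 1 the prediction is robust to the
simulated error; fractional values mark the cells where the stated data
quality genuinely does not determine the answer.

It is aimed at ecologists and conservation analysts who need to communicate
the reliability of habitat projections, particularly projections onto future
climates from multiple GCMs and emissions scenarios.

## What is simulated

For occurrences `s_i` and a suitability model `p(x) = σ(β·f(x))` fit against
background samples, each uncertainty source defines a perturbation kernel
applied independently per replicate `r = 1..R` (default `R = 100`):

| source | error model |
|---|---|
| `locational` | each point displaced by an isotropic Gaussian offset whose **mean Euclidean displacement** is `d` km (default 10); per-axis σ = `d`/√(π/2), so the displacement magnitude is Rayleigh(σ) |
| `spatial_bias` | the `⌈0.10·n⌉` records farthest from a uniformly random anchor point are removed (non-random loss) |
| `random_loss` | `⌈0.10·n⌉` uniformly chosen records removed |
| `climate_error` | for each of the 36 monthly layers (12 × tmin/tmax/prec): iid N(0,1) draws on a coarse lattice (0.5° spacing for temperature, 0.25° for precipitation, or metric equivalents), bicubic-interpolated to the fine grid, scaled by the per-cell standard-error surface, and added |
| `model_variance` | 100-fold cross-validation: replicate `r` refits on all segments but the `r`-th |
| `combined` | locational + biased loss + climate error + a random 99/1 train–test split, simultaneously |

Each replicate refits the SDM (a ridge-penalized presence–background
logistic regression on standardized linear + quadratic terms of six
bioclimatic predictors — the minimal member of the MaxEnt family, and
pluggable), recomputes the max(sensitivity+specificity) threshold, and
projects onto every climate scenario. The six predictors are annual mean
temperature, min temperature of the coldest month, max temperature of the
warmest month, annual precipitation, and precipitation of the warmest and
coldest quarters (quarters are wrap-around 3-month windows selected per
cell). Future scenarios are built by the delta method: additive temperature
anomalies and relative (or additive) precipitation anomalies per
GCM × emissions scenario, upsampled to the model grid if coarser.

A synthetic-landscape module (`sdmuq.synth`) generates complete study
fixtures — spatially autocorrelated monthly climate, terrain-linked
standard-error surfaces, GCM-like delta fields, and a virtual species
sampled from a known logistic niche — so the whole pipeline is testable
with known ground truth and no data downloads.

## Worked example

Generate a 60×60 km synthetic fixture with 200 virtual-species records, then
run the baseline model and the locational-uncertainty simulation:

```
$ sdmuq synth --out demo/fixture --seed 7 --n-occurrences 200 --rows 60 --cols 60
wrote synthetic fixture to demo/fixture

$ cat demo/config.yaml
climate_dir: demo/fixture/climate
errors_dir: demo/fixture/errors
occurrences: demo/fixture/occurrences.csv
output_dir: demo/out
sources: [baseline, locational]
master_seed: 11
perturbations:
  n_replicates: 100
  locational_mean_km: 10.0

$ sdmuq run --config demo/config.yaml
INFO sdmuq: wrote presence_prob_baseline_current.asc (1 replicates)
INFO sdmuq: wrote presence_prob_locational_current.asc (100 replicates)
wrote 2 probability rasters to demo/out
```

The baseline raster is binary (presence/absence from a single unperturbed
fit; predicted presence over 19.0% of the region here). The locational
raster holds each cell's proportion of the 100 runs predicting presence: in
this small, noisy demo 50% of cells end up with fractional probabilities
(0 < p < 1) — with 10 km of coordinate error on a 60 km landscape, half the
map is genuinely undetermined. `sdmuq render demo/out/presence_prob_locational_current.asc map.png`
draws the probability ramp with masked sea cells in gray. Adding a
`deltas_dir` produces one raster per scenario (e.g. 13 outputs for current
climate plus 6 GCMs × 2 emissions scenarios), all projected from models
fitted on current climate within each replicate.

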