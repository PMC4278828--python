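# Methods

## The model and the Monte Carlo design

`sdmuq` treats an SDM projection as a function of uncertain inputs and
propagates input error by simulation. One *run* fixes an uncertainty source
and a replicate count `R`; one *replicate* draws a perturbed copy of the
inputs from that source's error model, refits the suitability model, and
produces one binary presence/absence map per climate scenario. The run's
output is the per-cell mean of the binary stack — an estimate of the
probability that a cell is classified "presence" given the stated input
error. All randomness descends from one master seed through
`numpy.random.SeedSequence(master, spawn_key=(replicate, step, ...))`
substreams, so any replicate is reproducible in isolation and runs are
bit-identical across repeats.

Within a replicate the model is fit once on (possibly perturbed)
current-climate predictors and projected onto every scenario with the same
training threshold. This mirrors the practice of projecting a
current-climate model forward rather than refitting per scenario; it also
means scenario maps within a replicate share all sampling noise, so
scenario differences are attributable to the climate anomalies alone.

Replicates that fail (a perturbation leaving fewer than 5 usable presences)
are dropped and the probability denominator renormalized; a run aborts if
more than 20% of replicates fail, since at that point the requested
perturbation magnitude is incompatible with the dataset.

### The suitability backend

The default backend is a ridge-penalized presence–background logistic
regression on the six bioclimatic predictors. Features are the standardized
linear terms plus their squares (standardize-then-square: squaring raw
climate values, whose coefficient of variation is small, would make each
quadratic term nearly affine in its linear term and the fit
ill-conditioned); the expanded features are standardized again before
entering the logistic. Presences and background each receive total class
weight 1, so duplicated records and class imbalance do not move the fit,
and the same weights define the standardization moments. This is the
minimal member of the MaxEnt family — logistic output over background
samples with quadratic response shapes — and the backend boundary
(`fit_sdm`/`predict_suitability`) is the place to substitute a full MaxEnt
implementation.

`reg_weight` (default 0.01) multiplies a fixed ½‖β‖² penalty against the
class-weighted log-likelihood, whose total weight is 2 by construction;
regularization therefore does not weaken as records are duplicated.
Constant predictors are dropped with a warning. Optimization is scipy
L-BFGS via scikit-learn with tolerance 1e-10, tight enough that fits are
deterministic to well below the thresholds used anywhere downstream.

Thresholding uses max(sensitivity + specificity) over the observed training
suitabilities by default (lowest maximizer on ties), with fixed-value and
nearest-rank training-presence-percentile rules available. Binary maps use
`suitability ≥ threshold`.

### Error models

**Locational.** "Mean displacement `d` km" is read as the mean Euclidean
length of an isotropic bivariate Gaussian offset: per-axis
σ = d/√(π/2) ≈ 0.7979·d, since the norm is Rayleigh(σ) with mean σ√(π/2).
Two alternative readings (σ = d; per-axis mean |offset| = d) are selectable
by `locational_calibration`. On geographic grids km convert to degrees at
111.19 km/° (spherical Earth) with a cos(latitude) longitude correction per
point. Points displaced off the region or into masked cells are redrawn up
to 100 times, then dropped with a warning — redraw-then-drop keeps the
sample size stable without biasing interior points.

**Spatially biased vs random loss.** Biased loss removes the
`⌈fraction·n⌉` records farthest (Euclidean, or great-circle on geographic
grids) from an anchor drawn uniformly over the unmasked region — uniform
over the *region*, not the data, as the weaker assumption. Ties at the
cutoff break by record id, making the subsample a pure function of the
seed. Random loss removes the same count uniformly.

**Climate measurement error.** Interpolation error in gridded climate is
spatially correlated; simulating it as iid per-cell noise would be far too
optimistic at the scales SDMs use. Per monthly variable, independent
standard-normal draws are made on a coarse lattice — spacing 0.5° for
temperature and 0.25° for precipitation by default (their 111.19 km/°
metric equivalents on projected grids), the scales at which interpolation
errors decorrelate — then bicubic-interpolated to the model grid, scaled by
the per-cell standard-error surface, and added. The 36 variables use 36
independent substreams; cross-variable correlation is deliberately not
modelled (30-year monthly means largely remove it). Precipitation is
clamped at 0; tmin is clamped to tmax with a logged count. The bicubic
kernel is Catmull–Rom (interpolating, a = −½), so the noise field equals
the raw draw exactly at lattice nodes — which is what makes the calibration
testable — and edge nodes are replicated. With zero-valued error surfaces
the operation is exactly the identity, so the Monte Carlo degenerates to
the baseline bit-for-bit.

**Model variance.** k-fold cross-validation (default k = 100): a random
partition into segments whose sizes differ by at most one; replicate r
trains without segment r.

**Combined.** Locational noise, one subsampling flavour (biased by
default), climate error, and a random train/test split (default 99/1,
mirroring the 100-fold CV's training share) applied simultaneously; the
bootstrap-style split is used instead of CV because each replicate already
sees different data, and test sets may overlap across replicates.

### Background sampling

Background points (default 10,000, capped at the number of unmasked cells)
are drawn uniformly without replacement at unmasked cell centers, once per
run with a seed derived from the master seed, and shared across replicates.
Holding the background fixed within a run makes every zero-magnitude
perturbation reduce exactly to the baseline model and attributes all
between-replicate variance to the uncertainty source under study.
Background variability itself can be studied by varying the master seed
between runs.

## Bioclim derivation and deltas

Monthly mean temperature is (tmin+tmax)/2 (the standard convention).
Quarters are the 12 consecutive wrap-around 3-month windows; warmest and
coldest quarters are selected per cell by mean monthly mean temperature
with ties to the earliest starting month. The implementation is vectorized
over the 12 windows and is tested against an exhaustive per-cell scan.

Future climates are `current + Δ` for temperature and either
`current + Δ` (clamped at 0) or `current × ratio` for precipitation;
relative deltas are the default as the safer choice for skewed
precipitation fields. Coarser delta grids are Catmull–Rom-upsampled before
application; tmin > tmax crossings after perturbation are clamped with a
logged count.

## The synthetic landscape and what it does (not) show

The default fixture is a 100×100 grid of 1-km cells on a projected-metric
CRS with ~20% of cells masked as sea along a smooth "coast". Monthly mean
temperature = latitudinal gradient + a smooth terrain-like anomaly + a
sinusoidal seasonal cycle whose amplitude is itself a smooth spatial field
(continentality); tmin/tmax bracket it by a ≥ 2 °C diurnal range.
Precipitation is log-normal over a Gaussian-filtered spatial field (filter
σ chosen so the autocorrelation e-folds at the configured correlation
length, default 10 km) with a seasonally *rotating* anomaly so winter and
summer rainfall have partially independent spatial patterns. The rotation
and spatial continentality exist for an identifiability reason: with a
single shared pattern, annual and quarterly precipitation (and the
temperature mean and extremes) are perfectly collinear, and recovering the
generating niche's coefficients is ill-posed no matter how good the
estimator. Standard-error surfaces are a base level (0.3 °C / 5 mm) plus a
term proportional to the local temperature-gradient magnitude, emulating
larger interpolation error in rough terrain.

The default virtual species is logistic in standardized annual mean
temperature (+5) and warm-quarter precipitation (−3.5) with intercept
−7.5: a warm-adapted, summer-drought-limited endemic occupying ~10% of the
landscape. The sharpness and low prevalence are calibrated so that the
species is genuinely climate-limited — the *generating* model itself
discriminates presences from background at AUC ≈ 0.92. Occurrences are
cells sampled without replacement with probability proportional to true
suitability.

GCM-like deltas are smooth spatial anomaly patterns around six
(warming °C, precipitation ratio) profiles spanning wetter/cooler to
warmer/drier futures, scaled 1.0 (high-emissions, A2-like) or 0.5
(low-emissions, B1-like), so low-emissions anomalies are exactly half the
high-emissions ones.

What passing tests on this fixture do **not** show: real occurrence data
carry detection and identification error, real roads bias sampling in ways
an anchor-distance model only caricatures, real climate-interpolation
errors are anisotropic and terrain-locked rather than stationary, and real
niches are not exactly logistic-quadratic. The fixture demonstrates that
the machinery propagates each stated error model correctly and that the
qualitative claims (heterogeneous uncertainty, monotone blur, bias-driven
skew, combined-source dominance) follow from those error models — not that
any particular real map's uncertainty is as small as the fixture's.

## Numerical choices and conventions

- Cell-center coordinates; row 0 is the northern edge; a cell owns
  `[x, x+cell)`. Square cells only — rectangular rasters are rejected.
- Alignment means exact equality of all geometry fields.
- ESRI ASCII writes `%.10g` (round-trips float32-scale values within 1e-6);
  GeoTIFF writes float32 with ModelPixelScale/ModelTiepoint/GDAL-nodata
  tags. Nodata is −9999 in both dialects.
- Catmull–Rom reproduces constants and linear ramps exactly (interior) and
  is linear in its input; an all-zero field upsamples to exactly zero.
- Removal counts use `⌈fraction·n⌉`; the bootstrap split rounds half-up on
  the training side; k-fold segment sizes differ by at most one.
- Degenerate threshold inputs (all suitabilities equal) fall back to 0.5
  with a warning. Thresholds are clipped to (0,1) open interval endpoints
  (1e-9) before binarization so all-presence/all-absence models remain
  representable.
- Problem sizes in the test suite: unit tests run on a 40×40 fixture; the
  acceptance suite uses the default 100×100 fixture with 100 replicates per
  source and 300 occurrence records, which keeps a full run of all sources
  in the low minutes on one CPU.

## Known limitations

- The backend omits MaxEnt's hinge/product/threshold features; strongly
  non-quadratic niches will be under-fit, which understates model-variance
  uncertainty somewhat.
- Error surfaces are inputs (or synthesized); estimating them from station
  data is out of scope.
- No reprojection: all inputs must share one grid. Geographic and projected
  CRSs are both supported, with explicit km↔degree conversion.
- No multimodel-mean ensembling across GCMs, by design: averaging conceals
  exactly the variation the tool exists to display. Run the scenario matrix
  and present the per-GCM maps.
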