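"""Synthetic landscapes, error surfaces, GCM-like deltas and virtual species.

Everything the pipeline consumes can be generated here with known ground
truth: smooth monthly climate fields with latitudinal and terrain-like
gradients and sinusoidal seasonality, per-variable standard-error surfaces
that grow with local terrain roughness, spatially smooth GCM anomaly
fields, and occurrence points sampled from a known logistic niche. The
default landscape is a 100 x 100 cell, 1-km projected grid with a
clustered coastline mask — small enough that a 100-replicate run of any
single source completes in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .climate import BIOCLIM_NAMES, BioclimSet, ClimateStack, DeltaStack
from .grids import CRSKind, Grid, GridGeometry
from .perturb import ErrorSurfaceSet
from .sdm import OccurrenceSet

__all__ = [
    "SyntheticNiche",
    "LandscapeParams",
    "generate_landscape",
    "generate_occurrences",
    "generate_deltas",
    "true_suitability",
    "DEFAULT_NICHE",
]


@dataclass
class SyntheticNiche:
    """A known logistic niche over named bioclim variables.

    True suitability is logistic(intercept + sum beta_i * z_i) with each
    predictor standardized over the landscape, so coefficient recovery can
    be checked against the generating signs.
    """

    coefficients: dict[str, float]
    intercept: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(BIOCLIM_NAMES)
        if unknown:
            raise ValueError(f"unknown bioclim variables in niche: {sorted(unknown)}")


#: Default virtual species: a warm-adapted, summer-drought-limited endemic
#: occupying ~10% of the landscape. The sharp niche and low prevalence make
#: it strongly climate-limited, so presence-background discrimination is
#: informative and the generating signs are recoverable at modest n.
DEFAULT_NICHE = SyntheticNiche(
    {"annual_mean_temp": 5.0, "precip_warmest_quarter": -3.5}, intercept=-7.5
)


@dataclass
class LandscapeParams:
    """Parameters of the synthetic study region.

    Units: temperatures °C, precipitation mm, distances in map units of the
    geometry (metres on the default projected grid).
    """

    geometry: GridGeometry = field(
        default_factory=lambda: GridGeometry(100, 100, 0.0, 100_000.0, 1000.0, CRSKind.projected_metric)
    )
    mean_temp: float = 10.0  # °C at the grid center
    lat_gradient: float = 5e-5  # °C per map unit, south-to-north cooling
    seasonal_amplitude: float = 6.0  # °C peak-to-mean seasonal swing
    diurnal_range: float = 8.0  # °C tmax - tmin, >= 2 by construction
    terrain_relief: float = 4.0  # °C relief of the terrain-like temperature anomaly
    mean_precip: float = 80.0  # mm per month (median of the log-normal field)
    precip_dispersion: float = 0.4  # sd of log precipitation
    precip_correlation_length: float = 10_000.0  # map units
    precip_seasonality: float = 0.3  # relative winter/summer swing
    coast_fraction: float = 0.2  # fraction of cells masked as sea
    se_temp_base: float = 0.3  # °C floor of temperature error surfaces
    se_prec_base: float = 5.0  # mm floor of precipitation error surfaces
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.precip_correlation_length < self.geometry.cell_size:
            raise ValueError("correlation length must be >= cell size")
        if not (0 <= self.coast_fraction < 1):
            raise ValueError("coast_fraction must be in [0, 1)")
        if self.diurnal_range < 2.0:
            raise ValueError("diurnal_range must be >= 2 °C")


def _smooth_field(shape, sigma_cells, rng) -> np.ndarray:
    """Gaussian-filtered white noise, rescaled to unit variance."""
    white = rng.standard_normal(shape)
    f = gaussian_filter(white, sigma_cells, mode="reflect")
    return (f - f.mean()) / max(f.std(), 1e-12)


def generate_landscape(params: LandscapeParams) -> tuple[ClimateStack, ErrorSurfaceSet]:
    """Synthesize a 12-month climate stack and matching error surfaces.

    Monthly mean temperature = south-north gradient + terrain-like smooth
    anomaly + sinusoidal seasonal cycle (warmest in February, a southern-
    hemisphere-like phase); tmin/tmax bracket it by half the diurnal range.
    Precipitation is log-normal with Gaussian-filter spatial correlation and
    a seasonal cycle in antiphase with temperature. Error surfaces are a
    base level plus a term proportional to the local temperature gradient
    magnitude, so they are largest in "rough terrain".
    """
    g = params.geometry
    rng = np.random.default_rng(params.rng_seed)
    rows, cols = np.indices((g.n_rows, g.n_cols))
    # y increases northward; row 0 is the northern edge
    y_from_center = (g.n_rows / 2 - rows - 0.5) * g.cell_size

    terrain = _smooth_field((g.n_rows, g.n_cols), sigma_cells=8.0, rng=rng)
    t_base = params.mean_temp + params.lat_gradient * y_from_center + 0.5 * params.terrain_relief * terrain

    # clustered coastline: sea where a smooth field is below its quantile
    coast_field = _smooth_field((g.n_rows, g.n_cols), sigma_cells=12.0, rng=rng)
    if params.coast_fraction > 0:
        sea = coast_field < np.quantile(coast_field, params.coast_fraction)
    else:
        sea = np.zeros((g.n_rows, g.n_cols), dtype=bool)

    # local roughness of the temperature field drives the error surfaces
    gy, gx = np.gradient(t_base, g.cell_size)
    rough = np.hypot(gx, gy)
    rough = rough / max(rough.max(), 1e-12)

    # Gaussian-filtered white noise has autocorrelation exp(-lag^2 / (4 sigma^2));
    # sigma = L/2 puts the e-folding distance at the configured correlation length
    corr_cells = params.precip_correlation_length / g.cell_size
    sigma_prec = corr_cells / 2.0
    log_prec_field = _smooth_field((g.n_rows, g.n_cols), sigma_cells=sigma_prec, rng=rng)
    # seasonally rotating anomaly: winter and summer rainfall have partially
    # independent spatial patterns, as frontal vs convective regimes do
    prec_cos_field = _smooth_field((g.n_rows, g.n_cols), sigma_cells=sigma_prec, rng=rng)
    prec_sin_field = _smooth_field((g.n_rows, g.n_cols), sigma_cells=sigma_prec, rng=rng)

    # continentality: seasonal swings vary smoothly in space, so annual
    # means and seasonal extremes are not collinear across the landscape
    temp_amp = params.seasonal_amplitude * (1.0 + 0.4 * _smooth_field((g.n_rows, g.n_cols), 10.0, rng))
    temp_amp = np.clip(temp_amp, 0.2 * params.seasonal_amplitude, None)
    prec_amp = np.clip(
        params.precip_seasonality * (1.0 + 0.8 * _smooth_field((g.n_rows, g.n_cols), 10.0, rng)), 0.0, 0.9
    )

    tmin, tmax, prec = [], [], []
    se_tmin, se_tmax, se_prec = [], [], []
    for m in range(12):
        # phase: warmest in February (m = 1)
        season = np.cos(2 * np.pi * (m - 1) / 12.0)
        tmean_m = t_base + temp_amp * season
        tmin_m = tmean_m - 0.5 * params.diurnal_range
        tmax_m = tmean_m + 0.5 * params.diurnal_range
        prec_season = 1.0 - prec_amp * season  # wetter winters
        phase_c = np.cos(2 * np.pi * m / 12.0)
        phase_s = np.sin(2 * np.pi * m / 12.0)
        log_prec_m = log_prec_field + 1.6 * (phase_c * prec_cos_field + phase_s * prec_sin_field)
        prec_m = params.mean_precip * prec_season * np.exp(params.precip_dispersion * log_prec_m)
        tmin.append(Grid(g, tmin_m, sea.copy()))
        tmax.append(Grid(g, tmax_m, sea.copy()))
        prec.append(Grid(g, prec_m, sea.copy()))
        se_t = params.se_temp_base * (1.0 + 2.0 * rough)
        se_p = params.se_prec_base * (1.0 + 2.0 * rough)
        se_tmin.append(Grid(g, se_t, sea.copy()))
        se_tmax.append(Grid(g, se_t.copy(), sea.copy()))
        se_prec.append(Grid(g, se_p, sea.copy()))

    stack = ClimateStack(g, tmin, tmax, prec, period_label="synthetic_current")
    errors = ErrorSurfaceSet(g, se_tmin, se_tmax, se_prec)
    return stack, errors


def true_suitability(niche: SyntheticNiche, predictors: BioclimSet) -> Grid:
    """The generating suitability surface, for oracle comparisons."""
    g = predictors.geometry
    mask = predictors.mask
    eta = np.full((g.n_rows, g.n_cols), niche.intercept, dtype=float)
    for name, beta in niche.coefficients.items():
        vals = predictors[name].values
        v = vals[~mask]
        mu, sd = v.mean(), max(v.std(), 1e-12)
        eta += beta * (vals - mu) / sd
    suit = 1.0 / (1.0 + np.exp(-eta))
    return Grid(g, np.where(mask, 0.0, suit), mask.copy())


def generate_occurrences(
    niche: SyntheticNiche,
    predictors: BioclimSet,
    n: int,
    rng_seed: int = 0,
) -> OccurrenceSet:
    """Sample n occurrence cells without replacement, P(cell) ∝ true suitability."""
    suit = true_suitability(niche, predictors)
    rows, cols = np.nonzero(~suit.mask)
    p = suit.values[rows, cols]
    if p.sum() <= 0:
        raise ValueError("all-zero suitability: cannot sample occurrences")
    if n == 0:
        return OccurrenceSet(np.array([], dtype=object), np.array([]), np.array([]), predictors.geometry)
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(len(rows), size=n, replace=False, p=p / p.sum())
    g = predictors.geometry
    xs = g.x_origin + (cols[idx] + 0.5) * g.cell_size
    ys = g.y_origin - (rows[idx] + 0.5) * g.cell_size
    ids = np.array([f"occ{i}" for i in range(n)], dtype=object)
    return OccurrenceSet(ids, xs, ys, g)


def generate_deltas(
    geometry: GridGeometry,
    gcm_profiles: list[tuple[str, float, float]],
    scenarios: list[tuple[str, float]],
    rng_seed: int = 0,
    spatial_relief: float = 0.3,
) -> list[DeltaStack]:
    """One smooth anomaly stack per (GCM profile x emissions scenario).

    Each profile is (gcm_id, warming °C, precipitation ratio); each scenario
    is (scenario_id, scale). Scenario scaling is applied to the anomaly, so
    a scale of 0 yields identity deltas (0 °C, ratio 1) and a half-scale
    scenario has anomalies exactly half the full-scale ones — qualitatively
    similar but smaller in magnitude, as lower-emission futures are.
    """
    if not gcm_profiles or not scenarios:
        raise ValueError("need at least one GCM profile and one scenario")
    out = []
    for gi, (gcm_id, warming, pr_ratio) in enumerate(gcm_profiles):
        rng = np.random.default_rng(np.random.SeedSequence(rng_seed, spawn_key=(gi,)))
        pattern = _smooth_field((geometry.n_rows, geometry.n_cols), sigma_cells=15.0, rng=rng)
        for scen_id, scale in scenarios:
            dtmin, dtmax, dprec = [], [], []
            zeros_mask = np.zeros((geometry.n_rows, geometry.n_cols), dtype=bool)
            for m in range(12):
                dt = scale * (warming + spatial_relief * warming * pattern)
                ratio = 1.0 + scale * ((pr_ratio - 1.0) * (1.0 + spatial_relief * pattern))
                dtmin.append(Grid(geometry, dt, zeros_mask.copy()))
                dtmax.append(Grid(geometry, dt.copy(), zeros_mask.copy()))
                dprec.append(Grid(geometry, np.maximum(ratio, 0.0), zeros_mask.copy()))
            out.append(DeltaStack(geometry, dtmin, dtmax, dprec, gcm_id=gcm_id, scenario_id=scen_id))
    return out


#: Six GCM-like profiles spanning wetter/cooler to warmer/drier futures.
DEFAULT_GCM_PROFILES = [
    ("gcm_wet_cool", 1.5, 1.15),
    ("gcm_wet_warm", 2.5, 1.10),
    ("gcm_mid_a", 2.0, 1.00),
    ("gcm_mid_b", 2.2, 0.95),
    ("gcm_dry_warm", 3.0, 0.85),
    ("gcm_dry_hot", 3.5, 0.80),
]

#: High- and low-emissions scaling, A2-like and B1-like.
DEFAULT_SCENARIOS = [("A2", 1.0), ("B1", 0.5)]
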