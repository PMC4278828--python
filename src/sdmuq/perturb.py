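"""Uncertainty-source simulators.

Each operation is a pure function of (clean inputs, seed) producing the
perturbed inputs for one Monte Carlo replicate:

* ``perturb_locations`` — locational (coordinate) measurement error as an
  isotropic bivariate Gaussian displacement whose *mean Euclidean length*
  is the configured kilometre value (Rayleigh calibration).
* ``biased_subsample`` / ``random_subsample`` — spatially biased vs random
  loss of a fixed fraction of the occurrence records.
* ``simulate_climate_error`` — spatially correlated interpolation error in
  the monthly climate grids: independent standard-normal draws on a coarse
  lattice per variable, bicubic-interpolated to the fine grid and scaled by
  the per-cell standard-error surface.
* ``cv_segments`` — k-fold partition for the model-variance source.
* ``bootstrap_split`` — random train/test split for the combined source
  (test sets are allowed to overlap between replicates).

Seed management: a master seed spawns per-replicate / per-source /
per-variable substreams via ``numpy.random.SeedSequence(master, spawn_key=...)``
so any single replicate is reproducible in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .climate import ClimateStack
from .grids import (
    KM_PER_DEGREE,
    CRSKind,
    Grid,
    GridGeometry,
    bicubic_upsample,
    km_to_map_units,
)
from .sdm import OccurrenceSet

log = logging.getLogger(__name__)

__all__ = [
    "ErrorSurfaceSet",
    "PerturbationConfig",
    "substream",
    "perturb_locations",
    "biased_subsample",
    "random_subsample",
    "simulate_climate_error",
    "cv_segments",
    "bootstrap_split",
]

#: Rayleigh mean factor: mean |displacement| of an isotropic Gaussian with
#: per-axis sd sigma is sigma * sqrt(pi/2).
RAYLEIGH_MEAN_FACTOR = math.sqrt(math.pi / 2.0)


def substream(master_seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible random substream for a (replicate, source, variable) key."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=tuple(key)))


@dataclass
class ErrorSurfaceSet:
    """36 aligned standard-deviation rasters (°C for temperatures, mm for precipitation)."""

    geometry: GridGeometry
    se_tmin: list[Grid]
    se_tmax: list[Grid]
    se_prec: list[Grid]

    def __post_init__(self) -> None:
        for name, layers in (("se_tmin", self.se_tmin), ("se_tmax", self.se_tmax), ("se_prec", self.se_prec)):
            if len(layers) != 12:
                raise ValueError(f"{name} must have 12 monthly layers")
            for g in layers:
                if g.geometry != self.geometry:
                    raise ValueError(f"{name} layer not aligned")
                if np.any(g.values[~g.mask] < 0):
                    raise ValueError(f"{name} contains negative standard deviations")

    def all_layers(self):
        return [*self.se_tmin, *self.se_tmax, *self.se_prec]


@dataclass
class PerturbationConfig:
    """Magnitudes and bookkeeping for every uncertainty source.

    ``coarse_spacing_temp``/``coarse_spacing_prec`` are the lattice spacings
    of the coarse noise grids, in map units (defaults: 0.5° and 0.25° on
    geographic grids, their 111.19 km/° metric equivalents on projected
    grids — the scales at which spatial correlation between interpolation
    errors becomes negligible for temperature and precipitation).
    """

    locational_mean_km: float = 10.0
    subsample_fraction: float = 0.10
    cv_segments: int = 100
    coarse_spacing_temp: float | None = None  # map units; None -> CRS default
    coarse_spacing_prec: float | None = None
    combined_train_fraction: float = 0.99
    n_replicates: int = 100
    master_seed: int = 0
    background_n: int = 10_000
    locational_calibration: str = "mean_displacement"  # or "sigma" / "mean_abs_axis"

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction < 1):
            raise ValueError("subsample_fraction must be in (0, 1)")
        if not (0 < self.combined_train_fraction < 1):
            raise ValueError("combined_train_fraction must be in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.locational_mean_km < 0:
            raise ValueError("locational_mean_km must be >= 0")
        if self.locational_calibration not in ("mean_displacement", "sigma", "mean_abs_axis"):
            raise ValueError(f"unknown locational calibration {self.locational_calibration!r}")

    def spacing_temp(self, crs_kind: CRSKind) -> float:
        if self.coarse_spacing_temp is not None:
            return self.coarse_spacing_temp
        return 0.5 if CRSKind(crs_kind) is CRSKind.geographic_degrees else 0.5 * KM_PER_DEGREE * 1000

    def spacing_prec(self, crs_kind: CRSKind) -> float:
        if self.coarse_spacing_prec is not None:
            return self.coarse_spacing_prec
        return 0.25 if CRSKind(crs_kind) is CRSKind.geographic_degrees else 0.25 * KM_PER_DEGREE * 1000


# ---------------------------------------------------------------------------
# Locational uncertainty
# ---------------------------------------------------------------------------


def _axis_sigma_km(mean_km: float, calibration: str) -> float:
    if calibration == "sigma":
        return mean_km
    if calibration == "mean_abs_axis":
        # E|N(0, sigma)| = sigma * sqrt(2/pi)
        return mean_km / math.sqrt(2.0 / math.pi)
    # mean Euclidean displacement of the 2-D offset equals mean_km
    return mean_km / RAYLEIGH_MEAN_FACTOR


def perturb_locations(
    occ: OccurrenceSet,
    mean_km: float,
    rng_seed,
    region_mask: Grid | None = None,
    calibration: str = "mean_displacement",
    max_attempts: int = 100,
) -> OccurrenceSet:
    """Displace each occurrence by isotropic Gaussian noise.

    Per-axis sigma is chosen so the mean Euclidean displacement equals
    ``mean_km`` (Rayleigh calibration; alternatives selectable). Kilometres
    convert to map units via the grid CRS, with the cos(latitude) longitude
    correction applied per point on geographic grids. Points landing outside
    the study region or on masked cells are redrawn up to ``max_attempts``
    times, then dropped with a warning.
    """
    if mean_km < 0:
        raise ValueError("mean_km must be >= 0")
    if mean_km == 0 or len(occ) == 0:
        return occ.subset(np.arange(len(occ)))
    geom = occ.geometry_ref if occ.geometry_ref is not None else (region_mask.geometry if region_mask else None)
    if geom is None:
        raise ValueError("perturb_locations needs a geometry (occ.geometry_ref or region_mask)")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    sigma_km = _axis_sigma_km(mean_km, calibration)

    geographic = geom.crs_kind is CRSKind.geographic_degrees
    x = occ.x.copy()
    y = occ.y.copy()
    pending = np.arange(len(occ))
    placed = np.zeros(len(occ), dtype=bool)
    for _ in range(max_attempts):
        if len(pending) == 0:
            break
        base = km_to_map_units(sigma_km, 0.0, geom.crs_kind)
        dy = rng.normal(0.0, base, size=len(pending))
        if geographic:
            dx = rng.normal(0.0, base / np.cos(np.radians(occ.y[pending])), size=len(pending))
        else:
            dx = rng.normal(0.0, base, size=len(pending))
        nx = occ.x[pending] + dx
        ny = occ.y[pending] + dy
        ok = geom.contains(nx, ny)
        if region_mask is not None:
            row, col = geom.rowcol_of(nx[ok], ny[ok])
            ok_idx = np.flatnonzero(ok)
            ok2 = ~region_mask.mask[row, col]
            ok = np.zeros(len(pending), dtype=bool)
            ok[ok_idx[ok2]] = True
        x[pending[ok]] = nx[ok]
        y[pending[ok]] = ny[ok]
        placed[pending[ok]] = True
        pending = pending[~ok]
    if len(pending):
        log.warning("dropped %d occurrence(s) that could not be placed after %d redraws", len(pending), max_attempts)
    keep = placed
    return OccurrenceSet(occ.ids[keep], x[keep], y[keep], occ.geometry_ref)


# ---------------------------------------------------------------------------
# Sampling-bias simulators
# ---------------------------------------------------------------------------


def _removal_count(fraction: float, n: int) -> int:
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    k = math.ceil(fraction * n)
    if k >= n:
        raise ValueError(f"removing {k} of {n} records would leave nothing")
    return k


def biased_subsample(
    occ: OccurrenceSet,
    fraction: float,
    region: GridGeometry | None = None,
    rng_seed=0,
    region_mask: Grid | None = None,
) -> OccurrenceSet:
    """Spatially biased loss: drop the records farthest from a random anchor.

    The anchor is uniform over the unmasked study region; the
    ``ceil(fraction * n)`` records with the largest distance to it are
    removed. Ties at the cutoff break by record-id order, so the result is
    deterministic per seed.
    """
    n = len(occ)
    if n < 2:
        raise ValueError("biased_subsample needs at least 2 records")
    k = _removal_count(fraction, n)
    geom = region or occ.geometry_ref or (region_mask.geometry if region_mask else None)
    if geom is None:
        raise ValueError("biased_subsample needs a region geometry")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    if region_mask is not None:
        rows, cols = np.nonzero(~region_mask.mask)
        pick = rng.integers(len(rows))
        ax = geom.x_origin + (cols[pick] + 0.5) * geom.cell_size
        ay = geom.y_origin - (rows[pick] + 0.5) * geom.cell_size
    else:
        ax = geom.x_origin + rng.uniform(0, geom.n_cols * geom.cell_size)
        ay = geom.y_origin - rng.uniform(0, geom.n_rows * geom.cell_size)

    if geom.crs_kind is CRSKind.geographic_degrees:
        # great-circle (haversine) distance in degrees-equivalent km
        lat1, lat2 = np.radians(ay), np.radians(occ.y)
        dlat = lat2 - lat1
        dlon = np.radians(occ.x - ax)
        h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
        dist = 2 * 6371.0 * np.arcsin(np.sqrt(h))
    else:
        dist = np.hypot(occ.x - ax, occ.y - ay)

    # sort by (distance, record id): the k largest under this order go
    order = np.lexsort((occ.ids.astype(str), dist))
    keep = np.sort(order[: n - k])
    return occ.subset(keep)


def random_subsample(occ: OccurrenceSet, fraction: float, rng_seed=0) -> OccurrenceSet:
    """Random loss: drop ceil(fraction * n) uniformly chosen records."""
    n = len(occ)
    k = _removal_count(fraction, n)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    drop = rng.choice(n, size=k, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    return occ.subset(keep)


# ---------------------------------------------------------------------------
# Climate measurement error
# ---------------------------------------------------------------------------


def _coarse_geometry_for(fine: GridGeometry, spacing: float) -> GridGeometry:
    """Coarse noise lattice covering the fine extent with one node of padding."""
    if spacing < fine.cell_size:
        raise ValueError(f"coarse spacing {spacing} is below the fine cell size {fine.cell_size}")
    n_cols = int(math.ceil(fine.n_cols * fine.cell_size / spacing)) + 3
    n_rows = int(math.ceil(fine.n_rows * fine.cell_size / spacing)) + 3
    return GridGeometry(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=fine.x_origin - spacing,
        y_origin=fine.y_origin + spacing,
        cell_size=spacing,
        crs_kind=fine.crs_kind,
    )


def correlated_noise_field(fine: GridGeometry, spacing: float, rng: np.random.Generator) -> Grid:
    """Unit-variance noise, smooth below ``spacing``: iid N(0,1) at coarse
    nodes, bicubic-interpolated to the fine grid."""
    coarse_geom = _coarse_geometry_for(fine, spacing)
    draws = rng.standard_normal((coarse_geom.n_rows, coarse_geom.n_cols))
    coarse = Grid(coarse_geom, draws, np.zeros(draws.shape, dtype=bool))
    return bicubic_upsample(coarse, fine)


def simulate_climate_error(
    stack: ClimateStack,
    errors: ErrorSurfaceSet,
    cfg: PerturbationConfig,
    rng_seed: int,
) -> ClimateStack:
    """Perturb all 36 monthly layers with spatially correlated Gaussian error.

    Per variable, independently: draw iid standard normals on a coarse
    lattice (temperature spacing ``cfg.coarse_spacing_temp``, precipitation
    ``cfg.coarse_spacing_prec``), bicubic-interpolate to the fine grid,
    scale cell-wise by the standard-error surface and add. No cross-variable
    correlation is modelled. Precipitation is clamped at zero; tmin is
    clamped to tmax where the draws cross, with a logged count.
    """
    if errors.geometry != stack.geometry:
        raise ValueError("error surfaces are not aligned with the climate stack")
    fine = stack.geometry
    sp_t = cfg.spacing_temp(fine.crs_kind)
    sp_p = cfg.spacing_prec(fine.crs_kind)

    def perturbed(layers, se_layers, spacing, var_index):
        out = []
        for m in range(12):
            rng = substream(rng_seed, var_index, m) if np.isscalar(rng_seed) else rng_seed
            noise = correlated_noise_field(fine, spacing, rng)
            vals = layers[m].values + noise.values * se_layers[m].values
            out.append(Grid(fine, np.where(layers[m].mask, 0.0, vals), layers[m].mask.copy()))
        return out

    new_tmin = perturbed(stack.tmin, errors.se_tmin, sp_t, 0)
    new_tmax = perturbed(stack.tmax, errors.se_tmax, sp_t, 1)
    new_prec = perturbed(stack.prec, errors.se_prec, sp_p, 2)

    n_clamped = 0
    for m in range(12):
        mask = stack.mask
        over = (~mask) & (new_tmin[m].values > new_tmax[m].values)
        n_clamped += int(over.sum())
        new_tmin[m].values = np.where(over, new_tmax[m].values, new_tmin[m].values)
        new_prec[m].values = np.maximum(0.0, new_prec[m].values)
    if n_clamped:
        log.warning("simulate_climate_error: clamped tmin to tmax in %d cell-months", n_clamped)
    return ClimateStack(fine, new_tmin, new_tmax, new_prec, period_label=stack.period_label + "_perturbed")


# ---------------------------------------------------------------------------
# Resampling of the occurrence set
# ---------------------------------------------------------------------------


def cv_segments(occ: OccurrenceSet, k: int, rng_seed=0) -> list[set]:
    """Random partition of the record ids into k segments of near-equal size.

    Sizes differ by at most one; segments are disjoint and exhaustive.
    Replicate r of the model-variance source trains on all records except
    segment r.
    """
    n = len(occ)
    if k > n:
        raise ValueError(f"cannot split {n} records into {k} segments")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    return [set(occ.ids[part]) for part in np.array_split(perm, k)]


def bootstrap_split(occ: OccurrenceSet, train_fraction: float, rng_seed=0) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint train/test split (round-half-up on the training side)."""
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(occ)
    n_train = int(math.floor(train_fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    if n_train < 5:
        raise ValueError(f"split would leave only {n_train} training records")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    train = np.sort(perm[:n_train])
    test = np.sort(perm[n_train:])
    return occ.subset(train), occ.subset(test)
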