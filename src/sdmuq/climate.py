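"""Bioclimatic predictors from monthly climate, and future-climate deltas.

Six predictors summarise the mean, extremes and seasonality of climate:
annual mean temperature, minimum temperature of the coldest month, maximum
temperature of the warmest month, annual precipitation, and precipitation of
the warmest and coldest quarters. A "quarter" is any of the 12 consecutive
3-month windows (December wraps to January), selected per cell by mean
monthly temperature; ties go to the earliest starting month.

Future climates are represented by the delta (anomaly) method: additive
temperature anomalies and either additive or relative (ratio) precipitation
anomalies per GCM x emissions scenario.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .grids import Grid, GridGeometry, bicubic_upsample

log = logging.getLogger(__name__)

__all__ = [
    "ClimateStack",
    "BioclimSet",
    "DeltaStack",
    "BIOCLIM_NAMES",
    "derive_bioclim",
    "apply_deltas",
]

BIOCLIM_NAMES = (
    "annual_mean_temp",
    "min_temp_coldest_month",
    "max_temp_warmest_month",
    "annual_precip",
    "precip_warmest_quarter",
    "precip_coldest_quarter",
)


def _stack_layers(grids: list[Grid]) -> np.ndarray:
    return np.stack([g.values for g in grids])


@dataclass
class ClimateStack:
    """36 aligned monthly layers: tmin, tmax (°C) and prec (mm) for 12 months.

    A cell masked in any layer is masked in all; ``tmax >= tmin`` and
    ``prec >= 0`` cell-wise where unmasked.
    """

    geometry: GridGeometry
    tmin: list[Grid]
    tmax: list[Grid]
    prec: list[Grid]
    period_label: str = "current"

    def __post_init__(self) -> None:
        for name, layers in (("tmin", self.tmin), ("tmax", self.tmax), ("prec", self.prec)):
            if len(layers) != 12:
                raise ValueError(f"{name} must have 12 monthly layers, got {len(layers)}")
            for g in layers:
                if g.geometry != self.geometry:
                    raise ValueError(f"{name} layer not aligned with stack geometry")
        # unify masks across all 36 layers
        mask = np.zeros((self.geometry.n_rows, self.geometry.n_cols), dtype=bool)
        for g in self.all_layers():
            mask |= g.mask
        for g in self.all_layers():
            g.mask = mask.copy()
            g.values = np.where(mask, 0.0, g.values)
        valid = ~mask
        for m in range(12):
            if np.any(self.tmax[m].values[valid] < self.tmin[m].values[valid] - 1e-9):
                raise ValueError(f"tmax < tmin in month {m + 1}")
            if np.any(self.prec[m].values[valid] < -1e-9):
                raise ValueError(f"negative precipitation in month {m + 1}")

    @property
    def mask(self) -> np.ndarray:
        return self.tmin[0].mask

    def all_layers(self):
        return [*self.tmin, *self.tmax, *self.prec]

    def copy(self) -> "ClimateStack":
        return ClimateStack(
            self.geometry,
            [g.copy() for g in self.tmin],
            [g.copy() for g in self.tmax],
            [g.copy() for g in self.prec],
            self.period_label,
        )


@dataclass
class BioclimSet:
    """The six bioclim predictor grids, aligned to one geometry."""

    geometry: GridGeometry
    layers: dict[str, Grid]

    def __post_init__(self) -> None:
        missing = set(BIOCLIM_NAMES) - set(self.layers)
        if missing:
            raise ValueError(f"missing bioclim layers: {sorted(missing)}")
        for name, g in self.layers.items():
            if g.geometry != self.geometry:
                raise ValueError(f"bioclim layer {name} not aligned")

    @property
    def mask(self) -> np.ndarray:
        mask = np.zeros((self.geometry.n_rows, self.geometry.n_cols), dtype=bool)
        for g in self.layers.values():
            mask |= g.mask
        return mask

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def as_array(self, names=BIOCLIM_NAMES) -> np.ndarray:
        """(n_layers, n_rows, n_cols) array in the given layer order."""
        return np.stack([self.layers[n].values for n in names])


@dataclass
class DeltaStack:
    """Climate-change anomalies relative to the current period.

    Temperature deltas are additive (°C); precipitation deltas are either
    additive (mm) or relative (unitless ratio) depending on how they are
    applied. The stack may be coarser than the current climate; it is then
    bicubic-upsampled on application.
    """

    geometry: GridGeometry
    dtmin: list[Grid]
    dtmax: list[Grid]
    dprec: list[Grid]
    gcm_id: str = "custom"
    scenario_id: str = "custom"
    target_year: int = 2085

    def __post_init__(self) -> None:
        for name, layers in (("dtmin", self.dtmin), ("dtmax", self.dtmax), ("dprec", self.dprec)):
            if len(layers) != 12:
                raise ValueError(f"{name} must have 12 monthly layers")

    @property
    def label(self) -> str:
        return f"{self.gcm_id}_{self.scenario_id}"


# ---------------------------------------------------------------------------
# Bioclim derivation
# ---------------------------------------------------------------------------

# the 12 wrap-around 3-month windows, as month-index triples
_QUARTER_WINDOWS = [((m, (m + 1) % 12, (m + 2) % 12)) for m in range(12)]


def derive_bioclim(stack: ClimateStack) -> BioclimSet:
    """Derive the six bioclim predictors from a monthly climate stack.

    Monthly mean temperature is (tmin + tmax) / 2. Warmest/coldest quarters
    are selected per cell among the 12 wrap-around windows by mean monthly
    mean temperature, ties broken by earliest starting month.
    """
    for g in stack.all_layers():
        if g.mask.all():
            raise ValueError("cannot derive bioclim from a fully masked layer")
    tmin = _stack_layers(stack.tmin)  # (12, r, c)
    tmax = _stack_layers(stack.tmax)
    prec = _stack_layers(stack.prec)
    tmean = 0.5 * (tmin + tmax)

    annual_mean_temp = tmean.mean(axis=0)
    min_temp_coldest_month = tmin.min(axis=0)
    max_temp_warmest_month = tmax.max(axis=0)
    annual_precip = prec.sum(axis=0)

    # quarter means/totals for the 12 wrap-around windows: (12, r, c)
    qt_mean = np.stack([tmean[list(w)].mean(axis=0) for w in _QUARTER_WINDOWS])
    qt_prec = np.stack([prec[list(w)].sum(axis=0) for w in _QUARTER_WINDOWS])

    # argmax/argmin return the first (earliest-start) window on ties
    warm_idx = qt_mean.argmax(axis=0)
    cold_idx = qt_mean.argmin(axis=0)
    rows, cols = np.indices(warm_idx.shape)
    precip_warmest_quarter = qt_prec[warm_idx, rows, cols]
    precip_coldest_quarter = qt_prec[cold_idx, rows, cols]

    mask = stack.mask
    geom = stack.geometry
    out = {
        "annual_mean_temp": annual_mean_temp,
        "min_temp_coldest_month": min_temp_coldest_month,
        "max_temp_warmest_month": max_temp_warmest_month,
        "annual_precip": annual_precip,
        "precip_warmest_quarter": precip_warmest_quarter,
        "precip_coldest_quarter": precip_coldest_quarter,
    }
    return BioclimSet(geom, {k: Grid(geom, v, mask.copy()) for k, v in out.items()})


def _upsample_delta_layers(layers: list[Grid], target: GridGeometry) -> list[Grid]:
    return [bicubic_upsample(g, target) for g in layers]


def apply_deltas(current: ClimateStack, deltas: DeltaStack, precip_mode: str = "relative") -> ClimateStack:
    """Apply a GCM anomaly stack to the current climate.

    Temperatures shift additively. Precipitation is either ``current + delta``
    clamped at zero (``additive``) or ``current * delta`` (``relative``).
    Cells where the shifted tmin exceeds tmax are clamped to tmax; the count
    of clamped cells is logged as a warning.
    """
    if precip_mode not in ("additive", "relative"):
        raise ValueError(f"precip_mode must be 'additive' or 'relative', got {precip_mode!r}")
    if deltas.geometry != current.geometry:
        if deltas.geometry.cell_size <= current.geometry.cell_size:
            raise ValueError("delta stack geometry is misaligned with the current climate")
        dtmin = _upsample_delta_layers(deltas.dtmin, current.geometry)
        dtmax = _upsample_delta_layers(deltas.dtmax, current.geometry)
        dprec = _upsample_delta_layers(deltas.dprec, current.geometry)
    else:
        dtmin, dtmax, dprec = deltas.dtmin, deltas.dtmax, deltas.dprec

    mask = current.mask
    tmin_out, tmax_out, prec_out = [], [], []
    n_clamped = 0
    for m in range(12):
        new_tmax = current.tmax[m].values + dtmax[m].values
        new_tmin = current.tmin[m].values + dtmin[m].values
        over = (~mask) & (new_tmin > new_tmax)
        n_clamped += int(over.sum())
        new_tmin = np.where(over, new_tmax, new_tmin)
        if precip_mode == "additive":
            new_prec = np.maximum(0.0, current.prec[m].values + dprec[m].values)
        else:
            ratio = np.maximum(0.0, dprec[m].values)
            new_prec = current.prec[m].values * ratio
        geom = current.geometry
        tmin_out.append(Grid(geom, new_tmin, mask.copy()))
        tmax_out.append(Grid(geom, new_tmax, mask.copy()))
        prec_out.append(Grid(geom, new_prec, mask.copy()))
    if n_clamped:
        log.warning("apply_deltas: clamped tmin to tmax in %d cell-months", n_clamped)
    return ClimateStack(
        current.geometry, tmin_out, tmax_out, prec_out,
        period_label=f"{deltas.gcm_id}_{deltas.scenario_id}_{deltas.target_year}",
    )
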