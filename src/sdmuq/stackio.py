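"""Directory-level I/O for climate stacks, error surfaces, deltas and occurrences.

Monthly layers are discovered by filename template ``{var}_{month:02d}``
(variables tmin, tmax, prec) under a per-period directory; error surfaces
use ``se_{var}_{month:02d}``; delta stacks use ``d{var}_{month:02d}`` under
one directory per (gcm, scenario) named ``{gcm}_{scenario}``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import ClimateStack, DeltaStack
from .grids import CRSKind, Grid, read_raster, write_raster
from .perturb import ErrorSurfaceSet
from .sdm import OccurrenceSet

log = logging.getLogger(__name__)

__all__ = [
    "read_climate_dir",
    "write_climate_dir",
    "read_errors_dir",
    "write_errors_dir",
    "read_deltas_dir",
    "write_deltas_dir",
    "read_occurrences_csv",
    "write_occurrences_csv",
]

_VARS = ("tmin", "tmax", "prec")


def _find_layer(directory: Path, stem: str) -> Path:
    for ext in (".asc", ".tif", ".tiff", ".txt"):
        p = directory / f"{stem}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"no raster named {stem}.(asc|tif) in {directory}")


def _read_monthly(directory: Path, template: str, crs_kind: CRSKind) -> dict[str, list[Grid]]:
    out: dict[str, list[Grid]] = {}
    for var in _VARS:
        out[var] = [
            read_raster(_find_layer(directory, template.format(var=var, month=m + 1)), crs_kind=crs_kind)
            for m in range(12)
        ]
    return out


def read_climate_dir(directory, crs_kind: CRSKind = CRSKind.projected_metric, period_label: str | None = None) -> ClimateStack:
    directory = Path(directory)
    layers = _read_monthly(directory, "{var}_{month:02d}", crs_kind)
    return ClimateStack(
        layers["tmin"][0].geometry, layers["tmin"], layers["tmax"], layers["prec"],
        period_label=period_label or directory.name,
    )


def write_climate_dir(stack: ClimateStack, directory, format: str = "esri_ascii") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".asc" if format == "esri_ascii" else ".tif"
    for var, layers in (("tmin", stack.tmin), ("tmax", stack.tmax), ("prec", stack.prec)):
        for m, g in enumerate(layers):
            write_raster(g, directory / f"{var}_{m + 1:02d}{ext}", format)


def read_errors_dir(directory, crs_kind: CRSKind = CRSKind.projected_metric) -> ErrorSurfaceSet:
    directory = Path(directory)
    layers = _read_monthly(directory, "se_{var}_{month:02d}", crs_kind)
    return ErrorSurfaceSet(layers["tmin"][0].geometry, layers["tmin"], layers["tmax"], layers["prec"])


def write_errors_dir(errors: ErrorSurfaceSet, directory, format: str = "esri_ascii") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".asc" if format == "esri_ascii" else ".tif"
    for var, layers in (("tmin", errors.se_tmin), ("tmax", errors.se_tmax), ("prec", errors.se_prec)):
        for m, g in enumerate(layers):
            write_raster(g, directory / f"se_{var}_{m + 1:02d}{ext}", format)


def read_deltas_dir(directory, crs_kind: CRSKind = CRSKind.projected_metric) -> list[DeltaStack]:
    """Each subdirectory named {gcm}_{scenario} holds d{var}_{month:02d} layers."""
    directory = Path(directory)
    out = []
    for sub in sorted(p for p in directory.iterdir() if p.is_dir()):
        layers = _read_monthly(sub, "d{var}_{month:02d}", crs_kind)
        gcm_id, _, scenario_id = sub.name.rpartition("_")
        out.append(
            DeltaStack(
                layers["tmin"][0].geometry, layers["tmin"], layers["tmax"], layers["prec"],
                gcm_id=gcm_id or sub.name, scenario_id=scenario_id,
            )
        )
    return out


def write_deltas_dir(deltas: list[DeltaStack], directory, format: str = "esri_ascii") -> None:
    directory = Path(directory)
    ext = ".asc" if format == "esri_ascii" else ".tif"
    for d in deltas:
        sub = directory / d.label
        sub.mkdir(parents=True, exist_ok=True)
        for var, layers in (("tmin", d.dtmin), ("tmax", d.dtmax), ("prec", d.dprec)):
            for m, g in enumerate(layers):
                write_raster(g, sub / f"d{var}_{m + 1:02d}{ext}", format)


def read_occurrences_csv(path, region_mask: Grid | None = None) -> OccurrenceSet:
    """CSV with header id,x,y (an optional date column is ignored)."""
    df = pd.read_csv(path)
    return OccurrenceSet.from_dataframe(df, region_mask=region_mask)


def write_occurrences_csv(occ: OccurrenceSet, path) -> None:
    df = pd.DataFrame({"id": occ.ids, "x": occ.x, "y": occ.y})
    df.to_csv(path, index=False)
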