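"""Monte Carlo orchestration and presence-probability aggregation.

For each uncertainty source the loop is: perturb the inputs for replicate
r, derive bioclim predictors from the (possibly perturbed) climate, fit the
suitability model on the (possibly subsampled/displaced) occurrences,
project onto every scenario's bioclim, threshold, and aggregate the binary
maps into a per-cell presence probability — the proportion of replicates
classifying the cell as presence.

Models are fit once per replicate on current-climate predictors and
projected to all scenarios with the training threshold, matching the design
of projecting a current-climate model forward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .climate import BioclimSet, ClimateStack, DeltaStack, apply_deltas, derive_bioclim
from .grids import Grid
from .perturb import (
    ErrorSurfaceSet,
    PerturbationConfig,
    biased_subsample,
    bootstrap_split,
    cv_segments,
    perturb_locations,
    random_subsample,
    simulate_climate_error,
    substream,
)
from .sdm import (
    OccurrenceSet,
    ThresholdRule,
    compute_threshold,
    fit_sdm,
    predict_suitability,
    sample_background,
    threshold_map,
)

log = logging.getLogger(__name__)

__all__ = [
    "SOURCE_IDS",
    "SourceSpec",
    "ScenarioSpec",
    "PresenceProbabilityMap",
    "aggregate_presence_probability",
    "run_source",
    "run_scenario_matrix",
]

SOURCE_IDS = (
    "baseline",
    "locational",
    "spatial_bias",
    "random_loss",
    "climate_error",
    "model_variance",
    "combined",
)

#: Abort when more than this fraction of replicates fail.
MAX_FAILED_FRACTION = 0.20


@dataclass(frozen=True)
class SourceSpec:
    """Which uncertainty source a run simulates.

    ``combined`` applies locational noise, one subsampling flavour
    (``combined_bias`` selects spatially biased vs random loss), climate
    error, and a random train/test split simultaneously. ``baseline`` is a
    single unperturbed replicate.
    """

    source_id: str
    combined_bias: str = "spatial_bias"  # or "random_loss"

    def __post_init__(self) -> None:
        if self.source_id not in SOURCE_IDS:
            raise ValueError(f"unknown source {self.source_id!r}; expected one of {SOURCE_IDS}")
        if self.combined_bias not in ("spatial_bias", "random_loss"):
            raise ValueError("combined_bias must be 'spatial_bias' or 'random_loss'")


@dataclass
class ScenarioSpec:
    """One climate scenario: current, or current plus a GCM anomaly stack."""

    label: str
    deltas: DeltaStack | None = None
    precip_mode: str = "relative"

    @property
    def is_current(self) -> bool:
        return self.deltas is None


@dataclass
class PresenceProbabilityMap:
    """Per-cell proportion of Monte Carlo replicates predicting presence."""

    grid: Grid
    n_replicates: int
    source_id: str
    scenario_label: str

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask


def aggregate_presence_probability(binary_maps: list[Grid]) -> Grid:
    """Cell-wise mean of a stack of aligned binary maps; masks union."""
    if not binary_maps:
        raise ValueError("need at least one binary map")
    geom = binary_maps[0].geometry
    for g in binary_maps[1:]:
        if g.geometry != geom:
            raise ValueError("binary maps have misaligned geometries")
    mask = np.zeros((geom.n_rows, geom.n_cols), dtype=bool)
    for g in binary_maps:
        mask |= g.mask
    mean = np.mean([g.values for g in binary_maps], axis=0)
    return Grid(geom, np.where(mask, 0.0, mean), mask)


def _perturbed_inputs(
    source: SourceSpec,
    replicate: int,
    occ: OccurrenceSet,
    climate: ClimateStack,
    errors: ErrorSurfaceSet | None,
    cfg: PerturbationConfig,
    region_mask: Grid,
    segments: list[set] | None,
) -> tuple[OccurrenceSet, ClimateStack]:
    """Inputs for one replicate of one source. Substream keys: (replicate, step)."""
    sid = source.source_id
    occ_r, clim_r = occ, climate
    if sid == "baseline":
        return occ_r, clim_r
    if sid in ("locational", "combined"):
        occ_r = perturb_locations(
            occ_r, cfg.locational_mean_km, substream(cfg.master_seed, replicate, 1),
            region_mask=region_mask, calibration=cfg.locational_calibration,
        )
    if sid == "spatial_bias" or (sid == "combined" and source.combined_bias == "spatial_bias"):
        occ_r = biased_subsample(
            occ_r, cfg.subsample_fraction, region_mask.geometry,
            substream(cfg.master_seed, replicate, 2), region_mask=region_mask,
        )
    if sid == "random_loss" or (sid == "combined" and source.combined_bias == "random_loss"):
        occ_r = random_subsample(occ_r, cfg.subsample_fraction, substream(cfg.master_seed, replicate, 3))
    if sid in ("climate_error", "combined"):
        if errors is None:
            raise ValueError(f"source {sid!r} requires error surfaces")
        clim_r = simulate_climate_error(clim_r, errors, cfg, substream(cfg.master_seed, replicate, 4))
    if sid == "model_variance":
        assert segments is not None
        held_out = segments[replicate]
        keep = np.array([rid not in held_out for rid in occ_r.ids])
        occ_r = occ_r.subset(np.flatnonzero(keep))
    if sid == "combined":
        occ_r, _test = bootstrap_split(occ_r, cfg.combined_train_fraction, substream(cfg.master_seed, replicate, 5))
    return occ_r, clim_r


def run_scenario_matrix(
    occ: OccurrenceSet,
    current_climate: ClimateStack,
    errors: ErrorSurfaceSet | None,
    deltas: list[DeltaStack],
    cfg: PerturbationConfig,
    source: SourceSpec,
    region_mask: Grid | None = None,
    threshold_rule: ThresholdRule | None = None,
    reg_weight: float = 0.01,
    precip_mode: str = "relative",
) -> list[PresenceProbabilityMap]:
    """One presence-probability map per scenario: current plus each GCM x scenario delta.

    Within a replicate the model is fit once on the (possibly perturbed)
    current climate and projected onto every scenario's bioclim with the
    same training threshold. Replicates whose perturbation leaves too few
    presences are excluded from the denominator; more than 20% failures
    aborts.
    """
    labels = ["current"] + [d.label for d in deltas]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate (gcm, scenario) labels in delta list")
    scenarios = [ScenarioSpec("current")] + [ScenarioSpec(d.label, d, precip_mode) for d in deltas]
    threshold_rule = threshold_rule or ThresholdRule()

    if region_mask is None:
        region_mask = Grid(current_climate.geometry, np.zeros_like(current_climate.mask, dtype=float), current_climate.mask.copy())

    n_rep = 1 if source.source_id == "baseline" else cfg.n_replicates
    segments = None
    if source.source_id == "model_variance":
        if cfg.cv_segments > len(occ):
            raise ValueError(f"cv_segments={cfg.cv_segments} exceeds the {len(occ)} occurrence records")
        segments = cv_segments(occ, cfg.cv_segments, substream(cfg.master_seed, 0, 6))
        n_rep = cfg.cv_segments

    # one background sample per run, shared by all replicates so that
    # zero-magnitude perturbations reduce exactly to the baseline model
    n_bg = min(cfg.background_n, int((~region_mask.mask).sum()))
    background = sample_background(region_mask, n_bg, int(np.random.SeedSequence(cfg.master_seed, spawn_key=(7,)).generate_state(1)[0] % (2**31)))

    binary_stacks: list[list[Grid]] = [[] for _ in scenarios]
    n_failed = 0
    for r in range(n_rep):
        try:
            occ_r, clim_r = _perturbed_inputs(source, r, occ, current_climate, errors, cfg, region_mask, segments)
            bio_current = derive_bioclim(clim_r)
            model = fit_sdm(occ_r, background, bio_current, reg_weight=reg_weight, rng_seed=0)
            thr = compute_threshold(model, occ_r, background, bio_current, threshold_rule)
            thr = min(max(thr, 1e-9), 1 - 1e-9)
            model.training_threshold = thr
            for i, scen in enumerate(scenarios):
                bio_s = bio_current if scen.is_current else derive_bioclim(apply_deltas(clim_r, scen.deltas, scen.precip_mode))
                suit = predict_suitability(model, bio_s)
                binary_stacks[i].append(threshold_map(suit, thr))
        except ValueError as exc:
            n_failed += 1
            log.warning("replicate %d failed and was excluded: %s", r, exc)
            if n_failed > MAX_FAILED_FRACTION * n_rep:
                raise RuntimeError(
                    f"{n_failed} of {n_rep} replicates failed (> {MAX_FAILED_FRACTION:.0%}); "
                    "check perturbation magnitudes against the data"
                ) from exc
    n_eff = n_rep - n_failed
    return [
        PresenceProbabilityMap(aggregate_presence_probability(stack), n_eff, source.source_id, scen.label)
        for stack, scen in zip(binary_stacks, scenarios)
    ]


def run_source(
    occ: OccurrenceSet,
    current_climate: ClimateStack,
    errors: ErrorSurfaceSet | None,
    cfg: PerturbationConfig,
    source: SourceSpec,
    scenario_deltas: DeltaStack | None = None,
    **kwargs,
) -> PresenceProbabilityMap:
    """Presence-probability map for one source under one scenario."""
    deltas = [scenario_deltas] if scenario_deltas is not None else []
    maps = run_scenario_matrix(occ, current_climate, errors, deltas, cfg, source, **kwargs)
    return maps[-1] if scenario_deltas is not None else maps[0]
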