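"""Strict YAML run configuration.

Unknown keys are rejected with the offending key named, before any compute
starts. CLI flags override config keys one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .grids import CRSKind
from .montecarlo import SOURCE_IDS
from .perturb import PerturbationConfig
from .sdm import ThresholdRule

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """The configuration file is invalid; the message names the problem."""


_TOP_KEYS = {
    "climate_dir", "errors_dir", "deltas_dir", "occurrences", "output_dir",
    "crs_kind", "sources", "combined_bias", "perturbations", "sdm", "threshold",
    "master_seed", "log_level", "precip_mode",
}
_PERTURB_KEYS = {
    "locational_mean_km", "subsample_fraction", "cv_segments",
    "coarse_spacing_temp", "coarse_spacing_prec", "combined_train_fraction",
    "n_replicates", "background_n", "locational_calibration",
}
_SDM_KEYS = {"reg_weight", "background_n"}
_THRESHOLD_KEYS = {"rule", "parameter"}


@dataclass
class RunConfig:
    climate_dir: Path | None = None
    errors_dir: Path | None = None
    deltas_dir: Path | None = None
    occurrences: Path | None = None
    output_dir: Path = Path("sdmuq_output")
    crs_kind: CRSKind = CRSKind.projected_metric
    sources: list[str] = field(default_factory=lambda: ["baseline"])
    combined_bias: str = "spatial_bias"
    perturbations: PerturbationConfig = field(default_factory=PerturbationConfig)
    reg_weight: float = 0.01
    threshold_rule: ThresholdRule = field(default_factory=ThresholdRule)
    master_seed: int = 0
    precip_mode: str = "relative"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for s in self.sources:
            if s not in SOURCE_IDS:
                raise ConfigError(f"unknown source {s!r}; expected one of {SOURCE_IDS}")
        if self.precip_mode not in ("additive", "relative"):
            raise ConfigError(f"precip_mode must be 'additive' or 'relative', got {self.precip_mode!r}")


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Parse and validate a YAML config file; ``overrides`` wins key-by-key."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
    _check_keys(raw, _TOP_KEYS, "config root")
    pert_raw = raw.get("perturbations", {}) or {}
    _check_keys(pert_raw, _PERTURB_KEYS, "perturbations")
    sdm_raw = raw.get("sdm", {}) or {}
    _check_keys(sdm_raw, _SDM_KEYS, "sdm")
    thr_raw = raw.get("threshold", {}) or {}
    _check_keys(thr_raw, _THRESHOLD_KEYS, "threshold")

    master_seed = int(raw.get("master_seed", 0))
    try:
        pert = PerturbationConfig(master_seed=master_seed, **pert_raw)
        rule = ThresholdRule(
            rule_id=thr_raw.get("rule", "max_sens_plus_spec"),
            parameter=float(thr_raw.get("parameter", 0.5)),
        )
        cfg = RunConfig(
            climate_dir=Path(raw["climate_dir"]) if "climate_dir" in raw else None,
            errors_dir=Path(raw["errors_dir"]) if "errors_dir" in raw else None,
            deltas_dir=Path(raw["deltas_dir"]) if "deltas_dir" in raw else None,
            occurrences=Path(raw["occurrences"]) if "occurrences" in raw else None,
            output_dir=Path(raw.get("output_dir", "sdmuq_output")),
            crs_kind=CRSKind(raw.get("crs_kind", "projected_metric")),
            sources=list(raw.get("sources", ["baseline"])),
            combined_bias=raw.get("combined_bias", "spatial_bias"),
            perturbations=pert,
            reg_weight=float(sdm_raw.get("reg_weight", 0.01)),
            threshold_rule=rule,
            master_seed=master_seed,
            precip_mode=raw.get("precip_mode", "relative"),
            log_level=str(raw.get("log_level", "INFO")),
        )
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc
    if "background_n" in sdm_raw:
        cfg.perturbations.background_n = int(sdm_raw["background_n"])
    return cfg
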