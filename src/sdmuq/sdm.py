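"""Presence–background suitability modelling, prediction and thresholding.

The default backend is a ridge-penalized presence–background logistic
regression on standardized linear + quadratic bioclim features — the
minimal member of the MaxEnt model family. The backend is pluggable: any
object exposing the same fit/predict surface can be substituted.

Presence points are species occurrences; background points are pseudo-
absences drawn uniformly from the unmasked study region and stand in for
true absences. The logistic output in [0, 1] is read as habitat
suitability, and a threshold rule converts it to a binary presence/absence
map per model run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .climate import BIOCLIM_NAMES, BioclimSet
from .grids import Grid, GridGeometry

log = logging.getLogger(__name__)

__all__ = [
    "OccurrenceSet",
    "SDMModel",
    "ThresholdRule",
    "sample_background",
    "fit_sdm",
    "predict_suitability",
    "compute_threshold",
    "threshold_map",
]


@dataclass
class OccurrenceSet:
    """Species presence (or background) points in grid map coordinates."""

    ids: np.ndarray  # dtype=object or str
    x: np.ndarray
    y: np.ndarray
    geometry_ref: GridGeometry | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.ids) == len(self.x) == len(self.y)):
            raise ValueError("ids, x, y must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("record ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, index: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.ids[index], self.x[index], self.y[index], self.geometry_ref)

    @classmethod
    def from_dataframe(cls, df, geometry_ref=None, region_mask: Grid | None = None) -> "OccurrenceSet":
        """Build from a DataFrame with columns id, x, y.

        Points outside the study extent or on masked cells are dropped with a
        logged count.
        """
        for col in ("id", "x", "y"):
            if col not in df.columns:
                raise ValueError(f"occurrence table missing required column {col!r}")
        ids = df["id"].astype(str).to_numpy()
        x = df["x"].to_numpy(dtype=float)
        y = df["y"].to_numpy(dtype=float)
        if region_mask is not None:
            geometry_ref = geometry_ref or region_mask.geometry
            keep = region_mask.geometry.contains(x, y)
            row, col = region_mask.geometry.rowcol_of(x[keep], y[keep])
            on_land = ~region_mask.mask[row, col]
            kept = np.flatnonzero(keep)[on_land]
            dropped = len(ids) - len(kept)
            if dropped:
                log.warning("dropped %d occurrence(s) outside the study region or on masked cells", dropped)
            ids, x, y = ids[kept], x[kept], y[kept]
        return cls(ids, x, y, geometry_ref)


@dataclass
class ThresholdRule:
    """How to cut continuous suitability into presence/absence.

    ``max_sens_plus_spec`` maximizes sensitivity + specificity over observed
    suitability values; ``fixed_value`` uses ``parameter`` directly;
    ``training_presence_percentile`` takes the nearest-rank percentile of the
    presence suitabilities.
    """

    rule_id: str = "max_sens_plus_spec"
    parameter: float = 0.5

    def __post_init__(self) -> None:
        if self.rule_id not in ("max_sens_plus_spec", "fixed_value", "training_presence_percentile"):
            raise ValueError(f"unknown threshold rule {self.rule_id!r}")
        if self.rule_id == "fixed_value" and not (0 < self.parameter < 1):
            raise ValueError("fixed_value threshold must be in (0, 1)")
        if self.rule_id == "training_presence_percentile" and not (0 <= self.parameter <= 100):
            raise ValueError("percentile must be in [0, 100]")


@dataclass
class SDMModel:
    """A fitted presence–background logistic suitability model.

    Predictors are standardized (``linear_means``/``linear_stds``) before the
    quadratic expansion — squaring raw climate values would make each
    quadratic term nearly affine in its linear term and the fit
    ill-conditioned. The expanded features are standardized a second time
    (``feature_means``/``feature_stds``) before entering the logistic.
    """

    backend_id: str
    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    linear_means: np.ndarray
    linear_stds: np.ndarray
    feature_means: np.ndarray
    feature_stds: np.ndarray
    regularization_weight: float
    n_presence: int
    n_background: int
    training_threshold: float = 0.5

    def linear_coefficient(self, bioclim_name: str) -> float:
        """Coefficient of the linear term for one bioclim variable."""
        return float(self.coefficients[self.feature_names.index(bioclim_name)])

    def to_dict(self) -> dict:
        return {
            "backend_id": self.backend_id,
            "feature_names": self.feature_names,
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "linear_means": self.linear_means.tolist(),
            "linear_stds": self.linear_stds.tolist(),
            "feature_means": self.feature_means.tolist(),
            "feature_stds": self.feature_stds.tolist(),
            "regularization_weight": self.regularization_weight,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "training_threshold": self.training_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SDMModel":
        return cls(
            backend_id=d["backend_id"],
            feature_names=list(d["feature_names"]),
            coefficients=np.asarray(d["coefficients"], float),
            intercept=float(d["intercept"]),
            linear_means=np.asarray(d["linear_means"], float),
            linear_stds=np.asarray(d["linear_stds"], float),
            feature_means=np.asarray(d["feature_means"], float),
            feature_stds=np.asarray(d["feature_stds"], float),
            regularization_weight=float(d["regularization_weight"]),
            n_presence=int(d["n_presence"]),
            n_background=int(d["n_background"]),
            training_threshold=float(d["training_threshold"]),
        )


# ---------------------------------------------------------------------------


def sample_background(region_mask: Grid, n: int, rng_seed: int, replace: bool = False) -> OccurrenceSet:
    """Sample n background points at centers of unmasked cells.

    Uniform without replacement by default; capped sampling raises if n
    exceeds the number of unmasked cells and replacement is off.
    """
    rows, cols = np.nonzero(~region_mask.mask)
    n_avail = len(rows)
    if n_avail == 0:
        raise ValueError("region has no unmasked cells")
    if not replace and n > n_avail:
        raise ValueError(f"cannot sample {n} background points from {n_avail} unmasked cells without replacement")
    rng = np.random.default_rng(rng_seed)
    idx = rng.choice(n_avail, size=n, replace=replace)
    g = region_mask.geometry
    xs = g.x_origin + (cols[idx] + 0.5) * g.cell_size
    ys = g.y_origin - (rows[idx] + 0.5) * g.cell_size
    ids = np.array([f"bg{i}" for i in range(n)], dtype=object)
    return OccurrenceSet(ids, xs, ys, g)


def extract_predictor_matrix(points: OccurrenceSet, predictors: BioclimSet, names=BIOCLIM_NAMES) -> np.ndarray:
    """Bioclim values at the cell containing each point; NaN where masked."""
    g = predictors.geometry
    row, col = g.rowcol_of(points.x, points.y)
    inside = (row >= 0) & (row < g.n_rows) & (col >= 0) & (col < g.n_cols)
    out = np.full((len(points), len(names)), np.nan)
    mask = predictors.mask
    r_in, c_in = row[inside], col[inside]
    ok = ~mask[r_in, c_in]
    for j, name in enumerate(names):
        vals = predictors[name].values[r_in[ok], c_in[ok]]
        out[np.flatnonzero(inside)[ok], j] = vals
    return out


def _expand_features(raw: np.ndarray, names, lin_means: np.ndarray, lin_stds: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Standardize the linear predictors, then append their squares."""
    z = (raw - lin_means) / lin_stds
    feat_names = list(names) + [f"{n}^2" for n in names]
    return np.concatenate([z, z**2], axis=1), feat_names


def fit_sdm(
    presences: OccurrenceSet,
    background: OccurrenceSet,
    predictors: BioclimSet,
    reg_weight: float = 0.01,
    rng_seed: int = 0,
    predictor_names=BIOCLIM_NAMES,
) -> SDMModel:
    """Fit the ridge-penalized presence–background logistic backend.

    Features are the linear and quadratic terms of the bioclim predictors,
    standardized to zero mean and unit variance over the pooled training
    data. Presence and background class weights are normalized so each class
    contributes equal total weight regardless of counts. Deterministic given
    inputs and seed.
    """
    if reg_weight < 0:
        raise ValueError("reg_weight must be nonnegative")
    xp = extract_predictor_matrix(presences, predictors, predictor_names)
    xb = extract_predictor_matrix(background, predictors, predictor_names)
    xp = xp[np.all(np.isfinite(xp), axis=1)]
    xb = xb[np.all(np.isfinite(xb), axis=1)]
    if len(xp) < 5:
        raise ValueError(f"need at least 5 presences with finite predictor values, got {len(xp)}")
    if len(xb) < 5:
        raise ValueError(f"need at least 5 background points with finite predictor values, got {len(xb)}")

    raw = np.vstack([xp, xb])
    y = np.concatenate([np.ones(len(xp)), np.zeros(len(xb))])

    # each class contributes total weight 1 regardless of counts; with the
    # penalty fixed, duplicating the records of a class is then a no-op, and
    # the same weights enter the standardization moments
    w = np.where(y == 1, 1.0 / len(xp), 1.0 / len(xb))
    wn = w / w.sum()

    def _wmoments(m):
        mean = wn @ m
        std = np.sqrt(wn @ (m - mean) ** 2)
        return mean, std

    lin_means, lin_stds = _wmoments(raw)
    lin_constant = lin_stds < 1e-12
    if lin_constant.any():
        dropped = [predictor_names[i] for i in np.flatnonzero(lin_constant)]
        log.warning("dropping constant predictor(s): %s", ", ".join(dropped))
    lin_stds = np.where(lin_constant, 1.0, lin_stds)

    feats, feat_names = _expand_features(raw, predictor_names, lin_means, lin_stds)
    means, stds = _wmoments(feats)
    constant = stds < 1e-12
    constant |= np.concatenate([lin_constant, lin_constant])
    stds_safe = np.where(constant, 1.0, stds)
    z = (feats - means) / stds_safe
    z[:, constant] = 0.0

    # sklearn's C is inverse penalty strength on the (weight-sum-2) data term
    C = 1.0 / max(reg_weight, 1e-10)
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, tol=1e-10, random_state=rng_seed)
    clf.fit(z, y, sample_weight=w)

    coefs = clf.coef_[0].copy()
    coefs[constant] = 0.0
    return SDMModel(
        backend_id="ridge_logistic",
        feature_names=feat_names,
        coefficients=coefs,
        intercept=float(clf.intercept_[0]),
        linear_means=lin_means,
        linear_stds=lin_stds,
        feature_means=means,
        feature_stds=stds_safe,
        regularization_weight=reg_weight,
        n_presence=len(xp),
        n_background=len(xb),
    )


def _model_suitability(model: SDMModel, linear_values: np.ndarray) -> np.ndarray:
    """Logistic suitability for raw (unstandardized) linear predictor rows."""
    base_names = [n for n in model.feature_names if "^2" not in n]
    feats, _ = _expand_features(linear_values, base_names, model.linear_means, model.linear_stds)
    z = (feats - model.feature_means) / model.feature_stds
    eta = z @ model.coefficients + model.intercept
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


def predict_suitability(model: SDMModel, predictors: BioclimSet) -> Grid:
    """Logistic suitability in [0, 1] on the predictor grid; masked where any predictor is."""
    base_names = [n for n in model.feature_names if "^2" not in n]
    for name in base_names:
        if name not in predictors.layers:
            raise ValueError(f"predictor layer {name!r} missing from bioclim set")
    mask = predictors.mask
    arr = predictors.as_array(base_names)  # (k, r, c)
    flat = arr.reshape(len(base_names), -1).T
    suit = _model_suitability(model, flat).reshape(mask.shape)
    return Grid(predictors.geometry, np.where(mask, 0.0, suit), mask.copy())


def suitability_at_points(model: SDMModel, points: OccurrenceSet, predictors: BioclimSet) -> np.ndarray:
    base_names = [n for n in model.feature_names if "^2" not in n]
    vals = extract_predictor_matrix(points, predictors, base_names)
    ok = np.all(np.isfinite(vals), axis=1)
    out = np.full(len(points), np.nan)
    out[ok] = _model_suitability(model, vals[ok])
    return out


def compute_threshold(
    model: SDMModel,
    presences: OccurrenceSet,
    background: OccurrenceSet,
    predictors: BioclimSet,
    rule: ThresholdRule,
) -> float:
    """Training threshold separating presence from absence.

    For ``max_sens_plus_spec`` the candidate set is the observed suitability
    values at presences and background; the lowest candidate attaining the
    maximal sensitivity + specificity wins. Degenerate inputs (all
    suitabilities equal) fall back to 0.5 with a warning.
    """
    if rule.rule_id == "fixed_value":
        return float(rule.parameter)
    sp = suitability_at_points(model, presences, predictors)
    sp = sp[np.isfinite(sp)]
    if rule.rule_id == "training_presence_percentile":
        # nearest-rank percentile of presence suitabilities
        s = np.sort(sp)
        rank = max(1, math.ceil(rule.parameter / 100.0 * len(s)))
        return float(s[rank - 1])
    sb = suitability_at_points(model, background, predictors)
    sb = sb[np.isfinite(sb)]
    candidates = np.unique(np.concatenate([sp, sb]))
    if len(candidates) == 1:
        log.warning("degenerate suitabilities (all equal); falling back to threshold 0.5")
        return 0.5
    best_score, best_t = -np.inf, 0.5
    for t in candidates:  # ascending; strict > keeps the lowest maximizer
        sens = np.mean(sp >= t)
        spec = np.mean(sb < t)
        score = sens + spec
        if score > best_score:
            best_score, best_t = score, float(t)
    return best_t


def threshold_map(suitability: Grid, threshold: float) -> Grid:
    """Binary presence map: 1 where suitability >= threshold, masked cells stay masked."""
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    binary = (suitability.values >= threshold).astype(float)
    return Grid(suitability.geometry, np.where(suitability.mask, 0.0, binary), suitability.mask.copy())
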