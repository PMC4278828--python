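"""Presence–background model: sampling, fitting, prediction, thresholding."""

import numpy as np
import pytest

import sdmuq as q
from sdmuq.climate import BIOCLIM_NAMES, BioclimSet
from sdmuq.grids import Grid, GridGeometry
from sdmuq.sdm import (
    OccurrenceSet,
    SDMModel,
    ThresholdRule,
    compute_threshold,
    extract_predictor_matrix,
    fit_sdm,
    predict_suitability,
    sample_background,
    suitability_at_points,
    threshold_map,
)


def _bioclim_from(values_by_name, geom):
    layers = {}
    for name in BIOCLIM_NAMES:
        v = values_by_name.get(name, np.zeros((geom.n_rows, geom.n_cols)))
        layers[name] = Grid(geom, np.asarray(v, float))
    return BioclimSet(geom, layers)


def _points(geom, rowcols, prefix="p"):
    xs = np.array([geom.x_origin + (c + 0.5) * geom.cell_size for _, c in rowcols])
    ys = np.array([geom.y_origin - (r + 0.5) * geom.cell_size for r, _ in rowcols])
    ids = np.array([f"{prefix}{i}" for i in range(len(rowcols))], dtype=object)
    return OccurrenceSet(ids, xs, ys, geom)


class TestSampleBackground:
    def test_exhaustive_mask_samples_every_cell(self):
        geom = GridGeometry(4, 4, 0.0, 4000.0, 1000.0)
        mask = np.ones((4, 4), bool)
        mask[1:3, 1:3] = False  # 4 unmasked cells
        region = Grid(geom, np.zeros((4, 4)), mask)
        occ = sample_background(region, 4, rng_seed=3)
        rows, cols = geom.rowcol_of(occ.x, occ.y)
        assert sorted(zip(rows, cols)) == [(1, 1), (1, 2), (2, 1), (2, 2)]

    def test_same_seed_is_deterministic(self, small_region_mask):
        a = sample_background(small_region_mask, 50, 9)
        b = sample_background(small_region_mask, 50, 9)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_oversampling_without_replacement_rejected(self):
        geom = GridGeometry(2, 2, 0.0, 2000.0, 1000.0)
        region = Grid(geom, np.zeros((2, 2)), np.zeros((2, 2), bool))
        with pytest.raises(ValueError):
            sample_background(region, 5, 0)
        assert len(sample_background(region, 5, 0, replace=True)) == 5

    def test_single_draw_frequencies_uniform(self):
        # multinomial check: each of 4 cells drawn with p=1/4 over 10,000 draws
        geom = GridGeometry(2, 2, 0.0, 2000.0, 1000.0)
        region = Grid(geom, np.zeros((2, 2)), np.zeros((2, 2), bool))
        counts = np.zeros(4)
        for s in range(10_000):
            occ = sample_background(region, 1, s)
            r, c = geom.rowcol_of(occ.x[0], occ.y[0])
            counts[2 * r + c] += 1
        p = 0.25
        se = np.sqrt(p * (1 - p) * 10_000)
        assert np.all(np.abs(counts - 2500) < 3 * se)


class TestFitPredict:
    def test_separation_gives_positive_coefficient(self):
        geom = GridGeometry(2, 10, 0.0, 2000.0, 1000.0)
        bio1 = np.zeros((2, 10))
        bio1[0, :] = 1.0  # presences on the bio1=1 row
        bio = _bioclim_from({"annual_mean_temp": bio1}, geom)
        pres = _points(geom, [(0, c) for c in range(10)], "pr")
        bg = _points(geom, [(1, c) for c in range(10)], "bg")
        model = fit_sdm(pres, bg, bio, predictor_names=["annual_mean_temp"])
        assert model.linear_coefficient("annual_mean_temp") > 0
        s = suitability_at_points(model, pres, bio)
        sb = suitability_at_points(model, bg, bio)
        assert np.all(s > sb.max())

    def test_too_few_presences_rejected(self, small_bioclim, small_background):
        geom = small_bioclim.geometry
        pres = _points(geom, [(20, 20), (21, 21)], "pr")
        with pytest.raises(ValueError, match="at least 5"):
            fit_sdm(pres, small_background, small_bioclim)

    def test_duplicating_presences_leaves_fit_unchanged(self, small_bioclim, small_background, small_occurrences):
        m1 = fit_sdm(small_occurrences, small_background, small_bioclim)
        dup = OccurrenceSet(
            np.concatenate([small_occurrences.ids, np.char.add(small_occurrences.ids.astype(str), "_b")]),
            np.concatenate([small_occurrences.x, small_occurrences.x]),
            np.concatenate([small_occurrences.y, small_occurrences.y]),
            small_occurrences.geometry_ref,
        )
        m2 = fit_sdm(dup, small_background, small_bioclim)
        assert np.allclose(m1.coefficients, m2.coefficients, atol=1e-5)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-5)

    def test_increasing_ridge_weight_shrinks_coefficients(self, small_bioclim, small_background, small_occurrences):
        norms = []
        for w in (0.01, 0.1, 1.0, 10.0, 100.0):
            m = fit_sdm(small_occurrences, small_background, small_bioclim, reg_weight=w)
            norms.append(np.linalg.norm(m.coefficients))
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_constant_predictor_dropped_with_zero_coefficient(self, small_background, small_occurrences, small_bioclim):
        geom = small_bioclim.geometry
        layers = {n: small_bioclim[n] for n in BIOCLIM_NAMES}
        layers["annual_precip"] = Grid(geom, np.full((geom.n_rows, geom.n_cols), 42.0), small_bioclim.mask.copy())
        bio = BioclimSet(geom, layers)
        model = fit_sdm(small_occurrences, small_background, bio)
        assert model.linear_coefficient("annual_precip") == 0.0

    def test_all_zero_coefficients_predict_half(self, small_bioclim):
        geom = small_bioclim.geometry
        n_feat = 12
        model = SDMModel(
            backend_id="ridge_logistic",
            feature_names=list(BIOCLIM_NAMES) + [f"{n}^2" for n in BIOCLIM_NAMES],
            coefficients=np.zeros(n_feat),
            intercept=0.0,
            linear_means=np.zeros(6),
            linear_stds=np.ones(6),
            feature_means=np.zeros(n_feat),
            feature_stds=np.ones(n_feat),
            regularization_weight=1.0,
            n_presence=10,
            n_background=10,
        )
        suit = predict_suitability(model, small_bioclim)
        assert np.allclose(suit.unmasked(), 0.5)

    def test_prediction_matches_logistic_formula(self, small_bioclim, small_background, small_occurrences):
        model = fit_sdm(small_occurrences, small_background, small_bioclim)
        suit = predict_suitability(model, small_bioclim)
        rng = np.random.default_rng(2)
        rows, cols = np.nonzero(~small_bioclim.mask)
        pick = rng.choice(len(rows), 10, replace=False)
        for r, c in zip(rows[pick], cols[pick]):
            raw = np.array([[small_bioclim[n].values[r, c] for n in BIOCLIM_NAMES]])
            z1 = (raw - model.linear_means) / model.linear_stds
            feats = np.concatenate([z1, z1**2], axis=1)
            z = (feats - model.feature_means) / model.feature_stds
            eta = (z @ model.coefficients + model.intercept).item()
            assert suit.values[r, c] == pytest.approx(1.0 / (1.0 + np.exp(-eta)), abs=1e-9)

    def test_prediction_masked_where_predictors_masked(self, small_bioclim, small_background, small_occurrences):
        model = fit_sdm(small_occurrences, small_background, small_bioclim)
        suit = predict_suitability(model, small_bioclim)
        assert np.array_equal(suit.mask, small_bioclim.mask)

    def test_missing_predictor_layer_named(self, small_bioclim, small_background, small_occurrences):
        model = fit_sdm(small_occurrences, small_background, small_bioclim)
        partial = {n: small_bioclim[n] for n in BIOCLIM_NAMES if n != "annual_precip"}
        with pytest.raises(ValueError):
            BioclimSet(small_bioclim.geometry, partial)

    def test_model_json_round_trip(self, small_bioclim, small_background, small_occurrences):
        model = fit_sdm(small_occurrences, small_background, small_bioclim)
        model2 = SDMModel.from_dict(model.to_dict())
        a = predict_suitability(model, small_bioclim)
        b = predict_suitability(model2, small_bioclim)
        assert np.allclose(a.values, b.values, atol=1e-12)

    def test_training_auc_on_generating_species(self, default_bioclim, default_region_mask):
        from sklearn.metrics import roc_auc_score

        occ = q.generate_occurrences(q.DEFAULT_NICHE, default_bioclim, 300, rng_seed=3)
        bg = sample_background(default_region_mask, 5000, 3)
        model = fit_sdm(occ, bg, default_bioclim)
        sp = suitability_at_points(model, occ, default_bioclim)
        sb = suitability_at_points(model, bg, default_bioclim)
        y = np.r_[np.ones(len(sp)), np.zeros(len(sb))]
        assert roc_auc_score(y, np.r_[sp, sb]) >= 0.9


class TestThresholds:
    def _model_with_suits(self, geom, suits_by_rowcol):
        """A trivial 1-feature model whose suitability is the bio1 layer itself (identity via logit)."""
        vals = np.zeros((geom.n_rows, geom.n_cols))
        for (r, c), s in suits_by_rowcol.items():
            vals[r, c] = np.log(s / (1 - s))  # logit, so logistic(eta)=s with unit scaling
        bio = _bioclim_from({"annual_mean_temp": vals}, geom)
        model = SDMModel(
            backend_id="ridge_logistic",
            feature_names=["annual_mean_temp", "annual_mean_temp^2"],
            coefficients=np.array([1.0, 0.0]),
            intercept=0.0,
            linear_means=np.zeros(1),
            linear_stds=np.ones(1),
            feature_means=np.zeros(2),
            feature_stds=np.ones(2),
            regularization_weight=0.0,
            n_presence=2,
            n_background=2,
        )
        return model, bio

    def test_max_sens_plus_spec_brute_force_example(self):
        geom = GridGeometry(2, 2, 0.0, 2000.0, 1000.0)
        model, bio = self._model_with_suits(
            geom, {(0, 0): 0.9, (0, 1): 0.8, (1, 0): 0.1, (1, 1): 0.2}
        )
        pres = _points(geom, [(0, 0), (0, 1)], "pr")
        bg = _points(geom, [(1, 0), (1, 1)], "bg")
        t = compute_threshold(model, pres, bg, bio, ThresholdRule("max_sens_plus_spec"))
        assert t == pytest.approx(0.8, abs=1e-9)

    def test_fixed_value_passthrough(self, small_bioclim, small_background, small_occurrences):
        model = fit_sdm(small_occurrences, small_background, small_bioclim)
        assert compute_threshold(model, small_occurrences, small_background, small_bioclim,
                                 ThresholdRule("fixed_value", 0.5)) == 0.5

    def test_presence_percentile_nearest_rank(self):
        geom = GridGeometry(2, 10, 0.0, 2000.0, 1000.0)
        suits = {(0, c): 0.1 * (c + 1) - 1e-4 for c in range(10)}  # ~deciles 0.1..1.0
        model, bio = self._model_with_suits(geom, suits)
        pres = _points(geom, [(0, c) for c in range(10)], "pr")
        bg = _points(geom, [(1, 0)], "bg")
        t = compute_threshold(model, pres, bg, bio, ThresholdRule("training_presence_percentile", 10))
        # nearest-rank: ceil(0.10 * 10) = 1st smallest
        sp = suitability_at_points(model, pres, bio)
        assert t == pytest.approx(np.sort(sp)[0], abs=1e-12)

    def test_degenerate_suitabilities_fall_back(self):
        geom = GridGeometry(2, 2, 0.0, 2000.0, 1000.0)
        model, bio = self._model_with_suits(geom, {(0, 0): 0.3, (0, 1): 0.3, (1, 0): 0.3, (1, 1): 0.3})
        pres = _points(geom, [(0, 0), (0, 1)], "pr")
        bg = _points(geom, [(1, 0), (1, 1)], "bg")
        assert compute_threshold(model, pres, bg, bio, ThresholdRule("max_sens_plus_spec")) == 0.5

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            ThresholdRule("fixed_value", 1.5)
        with pytest.raises(ValueError):
            ThresholdRule("no_such_rule")


class TestThresholdMap:
    def test_uniform_above_threshold(self):
        geom = GridGeometry(2, 2, 0.0, 2000.0, 1000.0)
        g = Grid(geom, np.full((2, 2), 0.7))
        assert np.all(threshold_map(g, 0.5).values == 1.0)

    def test_boundary_equality_counts_as_presence(self):
        geom = GridGeometry(1, 2, 0.0, 1000.0, 1000.0)
        g = Grid(geom, np.array([[0.5, 0.4999]]))
        out = threshold_map(g, 0.5)
        assert out.values[0, 0] == 1.0 and out.values[0, 1] == 0.0

    def test_masked_cells_stay_masked(self):
        geom = GridGeometry(2, 2, 0.0, 2000.0, 1000.0)
        mask = np.array([[True, False], [False, False]])
        g = Grid(geom, np.full((2, 2), 0.9), mask)
        assert np.array_equal(threshold_map(g, 0.5).mask, mask)

    def test_threshold_bounds_enforced(self):
        geom = GridGeometry(1, 1, 0.0, 1000.0, 1000.0)
        g = Grid(geom, np.array([[0.5]]))
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                threshold_map(g, bad)


class TestOccurrenceLoading:
    def test_points_on_masked_cells_dropped(self):
        import pandas as pd

        geom = GridGeometry(2, 2, 0.0, 2000.0, 1000.0)
        mask = np.array([[True, False], [False, False]])
        region = Grid(geom, np.zeros((2, 2)), mask)
        df = pd.DataFrame({
            "id": ["a", "b", "c"],
            "x": [500.0, 1500.0, 9999.0],  # a on masked cell, c outside
            "y": [1500.0, 1500.0, 500.0],
        })
        occ = OccurrenceSet.from_dataframe(df, region_mask=region)
        assert list(occ.ids) == ["b"]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            OccurrenceSet(np.array(["a", "a"]), np.array([0.0, 1.0]), np.array([0.0, 1.0]))
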