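"""Covariate harmonization, ROI selection, z-scoring and laterality."""

import numpy as np
import pandas as pd
import pytest

from zsustain.harmonize import (
    SingularDesignError,
    apply_harmonization,
    cohens_d,
    combine_hemispheres,
    fit_covariate_model,
    laterality_index,
    select_rois,
    to_zscores,
)
from zsustain.schema import RegionSchema, SchemaError, default_schema
from zsustain.synthetic import default_settings, generate_cohort


@pytest.fixture(scope="module")
def small_schema() -> RegionSchema:
    return RegionSchema(
        regions=("pons", "thalamus", "parietal"),
        groups=("brainstem", "subcortical", "cortical"),
        paired=frozenset({"thalamus", "parietal"}),
    )


def _make_controls(n, rng, age_slope=0.0, field_offset=0.0, noise=0.0):
    """Combined-volume control table with controllable covariate effects."""
    age = rng.uniform(50, 80, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    tiv = rng.normal(1.4e6, 1e5, n)
    field = np.where(rng.random(n) < 0.5, "3T", "1.5T")
    manu = np.where(rng.random(n) < 0.5, "Siemens", "GE")
    base = {"pons": 1000.0, "thalamus": 800.0, "parietal": 5000.0}
    df = pd.DataFrame(
        {
            "subject_id": [f"c{i}" for i in range(n)],
            "scan_id": [f"c{i}_v0" for i in range(n)],
            "visit": 0,
            "group": "control",
            "pathology": "none",
            "age_at_scan": age,
            "sex": sex,
            "tiv": tiv,
            "field_strength": field,
            "manufacturer": manu,
        }
    )
    for r, m in base.items():
        df[r] = (
            m
            + age_slope * (age - 60.0)
            + field_offset * (field == "3T")
            + (rng.normal(0, noise, n) if noise else 0.0)
        )
    return df


class TestFitCovariateModel:
    def test_recovers_exact_age_slope(self, small_schema):
        # volume = 1000 - 2*(age-60), no noise -> age coefficient -2 exactly
        rng = np.random.default_rng(0)
        controls = _make_controls(60, rng, age_slope=-2.0)
        model = fit_covariate_model(controls, small_schema)
        assert model.coefficients.loc["age_at_scan", "pons"] == pytest.approx(-2.0, abs=1e-8)

    def test_zero_effects_leave_volumes_unchanged(self, small_schema):
        rng = np.random.default_rng(1)
        controls = _make_controls(50, rng, noise=5.0)
        # constant-mean volumes: adjustment must be a no-op up to noise fitting
        model = fit_covariate_model(controls, small_schema)
        adj = apply_harmonization(controls, model, small_schema)
        # fitted effects are pure noise; adjusted stays close to raw
        resid = adj["pons"] - controls["pons"]
        assert np.abs(resid).max() < 5.0

    def test_single_level_categorical_raises_named_error(self, small_schema):
        rng = np.random.default_rng(2)
        controls = _make_controls(40, rng)
        controls["manufacturer"] = "Siemens"
        with pytest.raises(SingularDesignError, match="manufacturer"):
            fit_covariate_model(controls, small_schema)

    def test_missing_covariate_rejected(self, small_schema):
        rng = np.random.default_rng(3)
        controls = _make_controls(40, rng)
        controls.loc[3, "tiv"] = np.nan
        with pytest.raises(SchemaError, match="tiv"):
            fit_covariate_model(controls, small_schema)

    def test_residuals_orthogonal_to_covariates(self, small_schema):
        rng = np.random.default_rng(4)
        controls = _make_controls(80, rng, age_slope=-3.0, field_offset=40.0, noise=20.0)
        model = fit_covariate_model(controls, small_schema)
        adj = apply_harmonization(controls, model, small_schema)
        resid = adj["pons"] - adj["pons"].mean()
        for cov in [
            controls["age_at_scan"],
            controls["tiv"],
            (controls["field_strength"] == "3T").astype(float),
            (controls["sex"] == "F").astype(float),
        ]:
            assert abs(np.corrcoef(resid, cov)[0, 1]) < 1e-6


class TestApplyHarmonization:
    def test_removes_modeled_age_effect(self, small_schema):
        rng = np.random.default_rng(5)
        controls = _make_controls(60, rng, age_slope=-2.0)
        model = fit_covariate_model(controls, small_schema)
        scan = controls.iloc[[0]].copy()
        older = scan.copy()
        older["age_at_scan"] += 10.0
        older[["pons", "thalamus", "parietal"]] -= 20.0  # the modeled -2/y effect
        a1 = apply_harmonization(scan, model, small_schema)
        a2 = apply_harmonization(older, model, small_schema)
        assert a1["pons"].iloc[0] == pytest.approx(a2["pons"].iloc[0], abs=1e-8)

    def test_scan_at_covariate_means_is_unchanged(self, small_schema):
        rng = np.random.default_rng(6)
        controls = _make_controls(200, rng, age_slope=-2.0, field_offset=30.0, noise=10.0)
        model = fit_covariate_model(controls, small_schema)
        adj = apply_harmonization(controls, model, small_schema)
        # adjustment preserves the control grand mean per region
        for r in small_schema.regions:
            assert adj[r].mean() == pytest.approx(controls[r].mean(), rel=1e-10)

    def test_unseen_level_rejected(self, small_schema):
        rng = np.random.default_rng(7)
        controls = _make_controls(40, rng)
        model = fit_covariate_model(controls, small_schema)
        weird = controls.iloc[[0]].copy()
        weird["manufacturer"] = "Philips"
        with pytest.raises(SchemaError, match="Philips"):
            apply_harmonization(weird, model, small_schema)


class TestCombineHemispheres:
    def test_sums_pairs_and_passes_midline(self, small_schema):
        df = pd.DataFrame(
            {"pons": [7.0], "thalamus_L": [10.0], "thalamus_R": [12.0],
             "parietal_L": [1.0], "parietal_R": [2.0]}
        )
        out = combine_hemispheres(df, small_schema)
        assert out["thalamus"].iloc[0] == 22.0
        assert out["pons"].iloc[0] == 7.0
        assert out[list(small_schema.regions)].to_numpy().sum() == pytest.approx(
            df.to_numpy().sum()
        )

    def test_missing_side_raises(self, small_schema):
        df = pd.DataFrame({"pons": [7.0], "thalamus_L": [10.0],
                           "parietal_L": [1.0], "parietal_R": [2.0]})
        with pytest.raises(SchemaError, match="thalamus"):
            combine_hemispheres(df, small_schema)


class TestCohensD:
    def test_identical_groups_zero(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])  # zero pooled SD
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_difference_unit_sd(self):
        # means 10 and 11, both SD exactly 1, equal n -> d = 1
        assert cohens_d([9.0, 10.0, 11.0], [10.0, 11.0, 12.0]) == pytest.approx(1.0, abs=1e-12)

    def test_hand_evaluated_pooled_formula(self):
        # cases (8,9,10), controls (10,11,12): means 9, 11; each var 1 -> d = 2
        assert cohens_d([8.0, 9.0, 10.0], [10.0, 11.0, 12.0]) == pytest.approx(2.0)

    def test_sign_positive_when_cases_smaller(self):
        assert cohens_d([1.0, 2.0], [5.0, 6.0]) > 0


class TestSelectRois:
    def _cohort_with_injected_effects(self, affected, d_target=1.5, seed=9):
        schema = default_schema()
        rng = np.random.default_rng(seed)
        n_ctrl, n_case = 150, 120
        rows = {}
        for r in schema.regions:
            ctrl = rng.normal(1000, 50, n_ctrl)
            shift = d_target * 50 if r in affected else 0.0
            case = rng.normal(1000 - shift, 50, n_case)
            rows[r] = np.concatenate([ctrl, case])
        df = pd.DataFrame(rows)
        df.insert(0, "group", ["control"] * n_ctrl + ["case"] * n_case)
        df.insert(0, "visit", 0)
        return df, schema

    def test_threshold_zero_keeps_all_regions(self):
        df, schema = self._cohort_with_injected_effects(set())
        selected, d = select_rois(df, schema, threshold=0.0)
        assert selected == list(schema.regions)
        assert len(d) == 24

    def test_injected_regions_selected_exactly(self):
        affected = {"pons", "midbrain", "parietal", "thalamus"}
        df, schema = self._cohort_with_injected_effects(affected)
        selected, _ = select_rois(df, schema, threshold=0.6)
        assert set(selected) == affected

    def test_monotone_in_threshold(self):
        affected = {"pons", "midbrain", "parietal"}
        df, schema = self._cohort_with_injected_effects(affected, d_target=0.9)
        prev = None
        for th in (0.0, 0.3, 0.6, 0.9, 1.2):
            sel, _ = select_rois(df, schema, threshold=th)
            if prev is not None:
                assert set(sel) <= set(prev)
            prev = sel


class TestToZscores:
    def test_control_zscores_standardized_in_sample(self, small_schema):
        rng = np.random.default_rng(10)
        controls = _make_controls(100, rng, age_slope=-2.0, noise=25.0)
        model = fit_covariate_model(controls, small_schema)
        adj = apply_harmonization(controls, model, small_schema)
        z = to_zscores(adj, model, list(small_schema.regions))
        for r in small_schema.regions:
            assert z[r].mean() == pytest.approx(0.0, abs=1e-8)
            assert z[r].std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_one_sd_below_mean_maps_to_plus_one(self, small_schema):
        rng = np.random.default_rng(11)
        controls = _make_controls(100, rng, noise=25.0)
        model = fit_covariate_model(controls, small_schema)
        adj = apply_harmonization(controls, model, small_schema)
        scan = adj.iloc[[0]].copy()
        for r in small_schema.regions:
            scan[r] = model.control_mean[r] - model.control_sd[r]
        # bypass re-adjustment: z computed directly from adjusted values
        z = to_zscores(scan, model, list(small_schema.regions))
        for r in small_schema.regions:
            assert z[r].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_rank_order_preserved_and_flipped(self, small_schema):
        rng = np.random.default_rng(12)
        controls = _make_controls(50, rng, noise=25.0)
        model = fit_covariate_model(controls, small_schema)
        adj = apply_harmonization(controls, model, small_schema)
        z = to_zscores(adj, model, ["pons"])
        assert np.array_equal(
            np.argsort(adj["pons"].to_numpy()), np.argsort(-z["pons"].to_numpy())
        )


class TestLateralityIndex:
    def test_hand_computed_value(self, small_schema):
        # left sum 510, right sum 490, total 1000 -> LI = 2.0
        scan = pd.Series(
            {"pons": 0.0, "thalamus_L": 300.0, "thalamus_R": 200.0,
             "parietal_L": 210.0, "parietal_R": 290.0}
        )
        assert laterality_index(scan, small_schema) == pytest.approx(2.0)

    def test_symmetric_scan_is_zero_and_scale_invariant(self, small_schema):
        scan = pd.Series(
            {"pons": 100.0, "thalamus_L": 50.0, "thalamus_R": 50.0,
             "parietal_L": 80.0, "parietal_R": 80.0}
        )
        assert laterality_index(scan, small_schema) == 0.0
        asym = pd.Series(
            {"pons": 100.0, "thalamus_L": 60.0, "thalamus_R": 50.0,
             "parietal_L": 80.0, "parietal_R": 80.0}
        )
        li1 = laterality_index(asym, small_schema)
        li2 = laterality_index(asym * 2.0, small_schema)
        assert li1 > 0
        assert li1 == pytest.approx(li2)


def test_default_cohort_roundtrip_standardizes_controls():
    """Controls pushed through the full harmonization are mean 0, SD 1 per ROI."""
    settings = default_settings(n_controls=120, n_cases=40, seed=21)
    scans, _ = generate_cohort(settings)
    schema = settings.schema
    combined = combine_hemispheres(scans, schema)
    controls = combined[combined["group"] == "control"]
    model = fit_covariate_model(controls, schema)
    adj = apply_harmonization(combined, model, schema)
    z = to_zscores(adj, model, list(schema.regions))
    zc = z[z["group"] == "control"]
    for r in schema.regions:
        assert zc[r].mean() == pytest.approx(0.0, abs=1e-8)
        assert zc[r].std(ddof=1) == pytest.approx(1.0, abs=1e-8)
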