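"""Table assembly, apq11 imputation, aging correction, scaling and PCA."""

import math

import numpy as np
import pandas as pd
import pytest

from bulbarvoice.features import FEATURE_COLUMNS
from bulbarvoice.preprocess import (
    biplot_export,
    build_table,
    fit_age_correction,
    impute_apq11,
    pca_svd,
    preprocess_pipeline,
    remove_age_effects,
    select_pcs,
    standardize,
)
from bulbarvoice.synth import CohortSpec, latent_feature_table

VOWELS = ["a", "e", "i", "o", "u"]


def toy_table(n_subjects=12, seed=0, age_slope=None, group_offsets=None):
    """Small feature table with controllable structure."""
    rng = np.random.default_rng(seed)
    rows = []
    groups = ["C", "B", "NB"]
    for i in range(n_subjects):
        group = groups[i % 3]
        age = float(rng.uniform(30, 80))
        for vowel in VOWELS:
            row = {"subject_id": f"S{i:02d}", "vowel": vowel, "sex": "male",
                   "age_years": age, "group": group}
            for j, col in enumerate(FEATURE_COLUMNS):
                base = rng.normal(10.0 + j, 1.0)
                if age_slope is not None:
                    base += age_slope * age
                if group_offsets is not None:
                    base += group_offsets[group]
                row[col] = base
            rows.append(row)
    return pd.DataFrame(rows)


class TestBuildTable:
    def _parts(self):
        table = toy_table(6)
        features = table.drop(columns=["sex", "age_years", "group"])
        metadata = (table[["subject_id", "group", "sex", "age_years"]]
                    .drop_duplicates("subject_id").rename(columns={"age_years": "age"}))
        return features, metadata

    def test_join_counts(self):
        features, metadata = self._parts()
        joined = build_table(features, metadata)
        assert joined.shape[0] == 6 * 5
        assert list(joined.columns[:5]) == ["subject_id", "vowel", "sex", "age_years", "group"]

    def test_orphan_rows_error(self):
        features, metadata = self._parts()
        with pytest.raises(ValueError, match="unknown subjects"):
            build_table(features, metadata[metadata["subject_id"] != "S00"])

    def test_duplicate_utterance_error(self):
        features, metadata = self._parts()
        dup = pd.concat([features, features.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError, match="duplicated"):
            build_table(dup, metadata)


class TestImputeApq11:
    def test_mean_of_other_vowels(self):
        table = toy_table(3)
        col = "shimmer_apq11_pct"
        table.loc[table.index[:5], col] = [2.0, 4.0, math.nan, 4.0, 2.0]
        out = impute_apq11(table)
        assert out.loc[table.index[2], col] == pytest.approx(3.0)

    def test_idempotent_without_missing(self):
        table = toy_table(3)
        assert impute_apq11(table).equals(table)

    def test_other_columns_never_imputed(self):
        table = toy_table(3)
        table.loc[table.index[0], "jitter_rap_pct"] = math.nan
        out = impute_apq11(table)
        assert math.isnan(out.loc[table.index[0], "jitter_rap_pct"])

    def test_all_vowels_undefined_errors(self):
        table = toy_table(3)
        col = "shimmer_apq11_pct"
        table.loc[table["subject_id"] == "S00", col] = math.nan
        with pytest.raises(ValueError, match="every vowel"):
            impute_apq11(table)


class TestAgeCorrection:
    def test_exact_slope_on_noiseless_line(self):
        table = toy_table(9)
        ages = table["age_years"].to_numpy()
        for col in FEATURE_COLUMNS:
            table[col] = 2.0 * ages + 5.0
        model = fit_age_correction(table)
        assert np.allclose(model.slopes.to_numpy(), 2.0)

    def test_slope_fitted_on_controls_only(self):
        table = toy_table(9)
        ages = table["age_years"].to_numpy()
        # Controls follow slope 1; patients follow slope 10 -> fitted slope
        # must stay 1.
        for col in FEATURE_COLUMNS:
            table[col] = np.where(table["group"] == "C", ages, 10.0 * ages)
        model = fit_age_correction(table)
        assert np.allclose(model.slopes.to_numpy(), 1.0)

    def test_degenerate_ages_error(self):
        table = toy_table(9)
        table["age_years"] = 50.0
        with pytest.raises(ValueError, match="degenerate"):
            fit_age_correction(table)

    def test_group_offset_recovered_exactly(self):
        offsets = {"C": 0.0, "B": 7.0, "NB": 3.0}
        table = toy_table(9)
        ages = table["age_years"].to_numpy()
        for col in FEATURE_COLUMNS:
            table[col] = 2.0 * ages + table["group"].map(offsets).to_numpy()
        model = fit_age_correction(table)
        corrected = remove_age_effects(table, model)
        assert np.allclose(corrected[FEATURE_COLUMNS[0]],
                           table["group"].map(offsets).to_numpy(), atol=1e-8)

    def test_controls_decorrelated_from_age_at_n200(self):
        # 40 control subjects x 5 vowels = 200 control rows with injected
        # linear aging; after correction each feature's correlation with
        # age among controls must vanish.
        spec = CohortSpec(n_control=40, n_bulbar=5, n_nonbulbar=5, seed=17)
        feats, subjects = latent_feature_table(spec)
        table = build_table(feats, subjects)
        model = fit_age_correction(table)
        corrected = remove_age_effects(table, model)
        controls = corrected[corrected["group"] == "C"]
        assert controls.shape[0] == 200
        ages = controls["age_years"].to_numpy()
        for col in FEATURE_COLUMNS:
            r = np.corrcoef(ages, controls[col].to_numpy())[0, 1]
            assert abs(r) < 0.05, col


class TestStandardize:
    def test_hand_computed_column(self):
        # Column [1, 2, 3]: mean 2, SD 1 (n-1 denominator) -> [-1, 0, 1].
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, params = standardize(table, feature_columns=["x"])
        assert np.allclose(out["x"].to_numpy(), [-1.0, 0.0, 1.0])
        assert params.means["x"] == pytest.approx(2.0)
        assert params.sds["x"] == pytest.approx(1.0)

    def test_columns_have_zero_mean_unit_sd(self):
        out, _ = standardize(toy_table(9))
        for col in FEATURE_COLUMNS:
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_idempotent_up_to_tolerance(self):
        once, _ = standardize(toy_table(9))
        twice, _ = standardize(once)
        assert np.allclose(once[FEATURE_COLUMNS], twice[FEATURE_COLUMNS], atol=1e-12)

    def test_constant_column_error_names_it(self):
        table = toy_table(3)
        table[FEATURE_COLUMNS[2]] = 1.0
        with pytest.raises(ValueError, match=FEATURE_COLUMNS[2]):
            standardize(table)


class TestPCA:
    def test_variance_shares_of_diagonal_covariance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(4000)],
            "vowel": "a", "sex": "male", "age_years": 50.0, "group": "C",
            "f1": rng.normal(0.0, 2.0, 4000),
            "f2": rng.normal(0.0, 1.0, 4000),
        })
        model = pca_svd(df, feature_columns=["f1", "f2"])
        assert model.explained_variance_ratio[0] == pytest.approx(0.8, abs=0.02)

    def test_variance_conservation_and_orthogonality(self):
        table, _ = standardize(toy_table(12, seed=3))
        model = pca_svd(table)
        total = sum(np.var(table[c], ddof=1) for c in FEATURE_COLUMNS)
        assert float(np.sum(model.s ** 2)) == pytest.approx(total, abs=1e-10)
        pcs = model.scores[[f"PC{j+1}" for j in range(15)]].to_numpy()
        corr = np.corrcoef(pcs[:, :10], rowvar=False)
        off = corr - np.diag(np.diag(corr))
        assert np.max(np.abs(off)) < 1e-10

    def test_reconstruction_identity(self):
        table, _ = standardize(toy_table(12, seed=3))
        model = pca_svd(table)
        n = model.u.shape[0]
        x = table[FEATURE_COLUMNS].to_numpy()
        recon = (model.u * model.s) @ model.v.T * np.sqrt(n - 1)
        assert np.allclose(recon, x, atol=1e-10)

    def test_select_pcs_bounds_and_losslessness(self):
        table, _ = standardize(toy_table(12, seed=3))
        model = pca_svd(table)
        assert select_pcs(model, 8).filter(like="PC").shape[1] == 8
        full = select_pcs(model, 15)
        assert np.allclose(
            full.filter(like="PC").to_numpy() @ model.v.T,
            table[FEATURE_COLUMNS].to_numpy(), atol=1e-10)
        with pytest.raises(ValueError):
            select_pcs(model, 0)
        with pytest.raises(ValueError):
            select_pcs(model, 16)

    def test_loading_sign_convention(self):
        table, _ = standardize(toy_table(12, seed=3))
        model = pca_svd(table)
        for j in range(model.v.shape[1]):
            col = model.v[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_biplot_export_consistency(self):
        table, _ = standardize(toy_table(12, seed=3))
        model = pca_svd(table)
        out = biplot_export(model)
        assert list(out["loadings"]["feature"]) == FEATURE_COLUMNS
        assert np.allclose(out["variance"]["variance_share"],
                           model.explained_variance_ratio[:2])


class TestPipelineOrder:
    def test_full_pipeline_runs_in_mandated_order(self):
        # With injected aging, correcting after standardization is not the
        # same as the mandated impute -> age-correct -> standardize -> PCA.
        table = toy_table(12, seed=5, age_slope=0.5)
        result = preprocess_pipeline(table, n_pcs=8)
        # Mandated order: control features decorrelated from age.
        controls = result.table[result.table["group"] == "C"]
        ages = controls["age_years"].to_numpy()
        r_ok = np.corrcoef(ages, controls[FEATURE_COLUMNS[0]].to_numpy())[0, 1]
        assert abs(r_ok) < 0.2
        # Permuted order: standardize first, then age-correct -> residual
        # correlation structure differs from the mandated pipeline.
        std_first, _ = standardize(table)
        model = fit_age_correction(std_first)
        permuted = remove_age_effects(std_first, model)
        assert not np.allclose(result.table[FEATURE_COLUMNS].to_numpy(),
                               permuted[FEATURE_COLUMNS].to_numpy())

    def test_subject_level_mode_aggregates_vowels(self):
        table = toy_table(12, seed=6)
        result = preprocess_pipeline(table, n_pcs=4, subject_level=True)
        assert result.selected.shape[0] == 12
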