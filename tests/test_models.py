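"""Classifier suite, CV mechanics, thresholds, metrics and paired tests."""

import math

import numpy as np
import pandas as pd
import pytest

from bulbarvoice import models as mdl


def blob_dataset(n_per_class=60, sep=6.0, dim=4, seed=0):
    """Two Gaussian blobs ``sep`` SDs apart along the first axis."""
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0.0, 1.0, (n_per_class, dim))
    x1 = rng.normal(0.0, 1.0, (n_per_class, dim))
    x1[:, 0] += sep
    x = np.vstack([x0, x1])
    y = np.repeat([0, 1], n_per_class)
    return x, y


def scores_frame(x, y):
    df = pd.DataFrame(x, columns=[f"PC{j+1}" for j in range(x.shape[1])])
    df.insert(0, "group", np.where(y == 1, "B", "C"))
    df.insert(0, "subject_id", [f"S{i}" for i in range(len(y))])
    return df


class TestMakeBinaryDataset:
    def _scores(self):
        rng = np.random.default_rng(1)
        groups = ["C"] * 18 + ["B"] * 14 + ["NB"] * 31
        df = pd.DataFrame({"subject_id": [f"S{i}" for i in range(63)],
                           "group": groups,
                           "PC1": rng.normal(size=63), "PC2": rng.normal(size=63)})
        return df

    def test_two_group_filtering(self):
        x, y, meta = mdl.make_binary_dataset(self._scores(), "C_vs_B")
        assert x.shape == (32, 2)
        assert y.sum() == 14
        assert set(meta["group"]) == {"C", "B"}

    def test_c_vs_als_keeps_all_rows(self):
        x, y, _ = mdl.make_binary_dataset(self._scores(), "C_vs_ALS")
        assert x.shape[0] == 63
        assert y.sum() == 45

    def test_b_vs_nb_excludes_controls(self):
        _, y, meta = mdl.make_binary_dataset(self._scores(), "B_vs_NB")
        assert "C" not in set(meta["group"])
        assert y.sum() == 14

    def test_empty_class_error(self):
        df = self._scores()
        df = df[df["group"] != "B"]
        with pytest.raises(ValueError, match="zero rows"):
            mdl.make_binary_dataset(df, "C_vs_B")


class TestUpsample:
    def test_minority_raised_to_majority(self):
        x = np.arange(15.0).reshape(15, 1)
        y = np.array([0] * 5 + [1] * 10)
        xb, yb = mdl.upsample(x, y, seed=0)
        assert (yb == 0).sum() == (yb == 1).sum() == 10
        # Every original row is retained.
        assert set(x.ravel()) <= set(xb.ravel())

    def test_balanced_input_unchanged(self):
        x = np.arange(10.0).reshape(10, 1)
        y = np.repeat([0, 1], 5)
        xb, yb = mdl.upsample(x, y, seed=3)
        assert sorted(xb.ravel()) == sorted(x.ravel())

    def test_seeded_determinism(self):
        x = np.arange(12.0).reshape(12, 1)
        y = np.array([0] * 3 + [1] * 9)
        a = mdl.upsample(x, y, seed=11)
        b = mdl.upsample(x, y, seed=11)
        assert np.array_equal(a[0], b[0])

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="two classes"):
            mdl.upsample(np.zeros((4, 1)), np.zeros(4, dtype=int), seed=0)


class TestThresholdAndMetrics:
    def test_boundary_probability_is_positive(self):
        assert mdl.apply_threshold(np.array([0.95]), 0.95).tolist() == [1]
        assert mdl.apply_threshold(np.array([0.50]), 0.50).tolist() == [1]
        assert mdl.apply_threshold(np.array([0.60]), 0.95).tolist() == [0]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            mdl.apply_threshold(np.array([1.2]), 0.5)

    def test_hand_computed_confusion_metrics(self):
        m = mdl.confusion_metrics(mdl.ConfusionCounts(tp=9, fn=1, tn=8, fp=2))
        assert m == pytest.approx((85.0, 90.0, 80.0))

    def test_all_correct(self):
        m = mdl.confusion_metrics(mdl.ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert m == (100.0, 100.0, 100.0)

    def test_empty_positive_class_undefined_sensitivity(self):
        m = mdl.confusion_metrics(mdl.ConfusionCounts(tp=0, fn=0, tn=5, fp=0))
        assert math.isnan(m.sensitivity) and m.specificity == 100.0

    def test_accuracy_is_prevalence_weighted_combination(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tp, fn, tn, fp = rng.integers(1, 20, 4)
            c = mdl.ConfusionCounts(int(tp), int(fn), int(tn), int(fp))
            m = mdl.confusion_metrics(c)
            prev = (c.tp + c.fn) / c.total
            assert m.accuracy == pytest.approx(
                prev * m.sensitivity + (1 - prev) * m.specificity)


class TestModelFits:
    def test_every_model_separates_distant_blobs(self):
        x, y = blob_dataset(sep=6.0)
        for name in mdl.MODEL_NAMES:
            scorer = mdl.fit_model(name, x, y, seed=0)
            pred = (scorer.predict_proba_positive(x) >= 0.5).astype(int)
            assert np.mean(pred == y) == 1.0, name

    def test_label_shuffle_scores_at_chance(self):
        x, y = blob_dataset(n_per_class=50, sep=6.0, seed=3)
        rng = np.random.default_rng(4)
        y_shuffled = rng.permutation(y)
        scheme = mdl.CVScheme(k=5, trials=2, seed=5)
        res = mdl.repeated_kfold_evaluate(x, y_shuffled, "LDA", scheme, 0.5)
        assert abs(res.accuracy_pct - 50.0) < 15.0

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            mdl.fit_model("GBM", *blob_dataset(10), seed=0)

    def test_single_class_training_rejected(self):
        x, _ = blob_dataset(10)
        with pytest.raises(ValueError, match="single class"):
            mdl.fit_model("LDA", x, np.zeros(x.shape[0], dtype=int), seed=0)


class TestFoldMechanics:
    def test_partition_integrity(self):
        scheme = mdl.CVScheme(k=10, trials=10, seed=8)
        folds = mdl._fold_indices(47, scheme)
        assert len(folds) == 100
        for trial in range(10):
            tested = np.concatenate([t for tr, _, t in folds if tr == trial])
            assert sorted(tested.tolist()) == list(range(47))
        for _, train, test in folds:
            assert not set(train) & set(test)
            assert len(train) + len(test) == 47

    def test_exactly_100_fold_evaluations(self):
        x, y = blob_dataset(n_per_class=40, sep=3.0, seed=6)
        res = mdl.repeated_kfold_evaluate(x, y, "NaB", mdl.CVScheme(seed=1), 0.5)
        assert res.fold_accuracy.size == 100

    def test_seeded_rerun_is_identical(self):
        x, y = blob_dataset(n_per_class=30, sep=2.0, seed=7)
        a = mdl.repeated_kfold_evaluate(x, y, "LR", mdl.CVScheme(seed=2), 0.5)
        b = mdl.repeated_kfold_evaluate(x, y, "LR", mdl.CVScheme(seed=2), 0.5)
        assert np.array_equal(a.fold_accuracy, b.fold_accuracy)

    def test_threshold_monotonicity_on_shared_scorer(self):
        x, y = blob_dataset(n_per_class=40, sep=2.0, seed=9)
        out = mdl.evaluate_models(x, y, ["LR"], mdl.CVScheme(seed=3), [0.5, 0.95])
        lo, hi = out[("LR", 0.5)], out[("LR", 0.95)]
        # Per fold: raising the threshold cannot raise sensitivity
        # nor lower specificity.
        sens_ok = np.isnan(hi.fold_sensitivity) | np.isnan(lo.fold_sensitivity) | (
            hi.fold_sensitivity <= lo.fold_sensitivity + 1e-9)
        spec_ok = np.isnan(hi.fold_specificity) | np.isnan(lo.fold_specificity) | (
            hi.fold_specificity >= lo.fold_specificity - 1e-9)
        assert sens_ok.all() and spec_ok.all()


class TestSubjectGroupedFolds:
    def _subject_structured_null(self, n_subjects=30, dim=8, seed=20):
        """Rows with strong speaker identity but labels independent of the
        features: five near-identical utterances per subject (tight
        clusters in feature space), subject labels assigned at random."""
        rng = np.random.default_rng(seed)
        latents = rng.normal(0.0, 1.0, (n_subjects, dim))
        labels = rng.permutation(np.repeat([0, 1], n_subjects // 2))
        x = np.vstack([latents[i] + rng.normal(0.0, 0.05, (5, dim))
                       for i in range(n_subjects)])
        return x, np.repeat(labels, 5), np.repeat(np.arange(n_subjects), 5)

    def test_utterance_folds_memorize_speakers_but_grouped_folds_do_not(self):
        x, y, g = self._subject_structured_null()
        scheme_utt = mdl.CVScheme(k=5, trials=2, seed=6)
        scheme_grp = mdl.CVScheme(k=5, trials=2, seed=6, subject_grouped=True)
        acc_utt = mdl.evaluate_models(x, y, ["LDA"], scheme_utt, [0.5])[
            ("LDA", 0.5)].accuracy_pct
        acc_grp = mdl.evaluate_models(x, y, ["LDA"], scheme_grp, [0.5],
                                      groups=g)[("LDA", 0.5)].accuracy_pct
        # No label signal exists, yet utterance folds score above chance by
        # interpolating the speaker clusters; grouped folds stay at chance.
        assert acc_utt > 60.0
        assert acc_utt > acc_grp + 5.0
        assert abs(acc_grp - 50.0) < 15.0

    def test_grouped_folds_never_split_a_subject(self):
        _, _, g = self._subject_structured_null()
        scheme = mdl.CVScheme(k=5, trials=3, seed=1, subject_grouped=True)
        for _, train, test in mdl._fold_indices(g.size, scheme, groups=g):
            assert not set(g[train]) & set(g[test])
            assert len(train) + len(test) == g.size


class TestCompareModels:
    def test_identical_models_not_significant(self):
        acc = np.full(100, 88.0)
        out = mdl.compare_models({"A": acc, "B": acc.copy()})
        row = out.iloc[0]
        assert row["p_bonferroni"] == 1.0 and row["degenerate"]
        assert not row["significant"]

    def test_handicapped_model_detected(self):
        rng = np.random.default_rng(10)
        good = 90.0 + rng.normal(0, 3, 100)
        bad = 70.0 + rng.normal(0, 3, 100)
        same = good + rng.normal(0, 0.5, 100)
        out = mdl.compare_models({"good": good, "bad": bad, "same": same})
        gb = out[(out.model_a == "good") & (out.model_b == "bad")].iloc[0]
        assert gb["significant"]
        gs = out[(out.model_a == "good") & (out.model_b == "same")].iloc[0]
        assert not gs["significant"]

    def test_bonferroni_family_is_all_pairs(self):
        rng = np.random.default_rng(11)
        accs = {m: 80 + rng.normal(0, 5, 100) for m in mdl.MODEL_NAMES}
        out = mdl.compare_models(accs)
        assert out.shape[0] == 15
        assert np.allclose(out["p_bonferroni"],
                           np.minimum(out["p_raw"] * 15, 1.0))


class TestResultsReport:
    def test_missing_cells_error(self):
        with pytest.raises(ValueError, match="missing grid cells"):
            mdl.results_report({})

    def test_complete_grid_has_144_cells(self):
        x, y = blob_dataset(n_per_class=30, sep=4.0, seed=12)
        df = scores_frame(x, y)
        df.loc[df.index[:20], "group"] = "NB"  # make three groups
        grid = mdl.evaluate_grid(df, model_names=["NaB", "LDA"],
                                 scheme=mdl.CVScheme(k=5, trials=2, seed=4))
        tables = mdl.results_report(grid, model_names=["NaB", "LDA"])
        cells = sum(t.shape[0] * 4 for t in tables.values())
        assert cells == 2 * 2 * 4 * 3
        # One-decimal formatting, as in the published tables.
        val = tables[0.5].iloc[0]["C_vs_B"]
        assert val == round(val, 1)
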