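import numpy as np
import pandas as pd
import pytest

from kinemetrix.modeling import (
    CLASSIFIER_NAMES,
    CVConfig,
    CVReport,
    fit_classifier,
    lasso_select,
    loso_splits,
    run_cv,
    standardize,
)

SMALL_GRIDS = {
    "lda": {}, "lr": {}, "svm": {}, "rf": {"n_estimators": [50]},
    "ab": {"n_estimators": [25]}, "knn": {}, "gnb": {},
}


def make_table(n_subjects=10, rows_per_subject=6, n_features=10, effect=2.0, seed=0,
               informative=(0, 1)):
    """Subject-grouped two-class table; `informative` columns carry the effect
    at the subject level."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        label = "high" if i >= n_subjects // 2 else "low"
        subject_shift = rng.normal(0, 0.5, n_features)
        for k in range(rows_per_subject):
            x = rng.normal(0, 1, n_features) + subject_shift
            if label == "high":
                for j in informative:
                    x[j] += effect
            row = {"segment_id": f"s{i}_r{k}", "subject_id": f"s{i}",
                   "med_state": "off", "modality": "body", "label": label}
            row.update({f"f{j}": x[j] for j in range(n_features)})
            rows.append(row)
    return pd.DataFrame(rows)


class TestLosoSplits:
    def test_one_fold_per_subject(self):
        table = make_table(n_subjects=5)
        folds = list(loso_splits(table))
        assert len(folds) == 5

    def test_partition_property(self):
        table = make_table(n_subjects=5, rows_per_subject=4)
        folds = list(loso_splits(table))
        all_test = np.concatenate([te for _, _, te in folds])
        assert sorted(all_test) == list(range(len(table)))
        for held, tr, te in folds:
            assert len(te) == 4
            assert not set(table.loc[tr, "subject_id"]) & {held}

    def test_subject_with_both_labels_held_out_together(self):
        table = make_table(n_subjects=4)
        # give subject s0 rows in both medication states and labels
        extra = table[table.subject_id == "s0"].copy()
        extra["med_state"] = "on"
        extra["label"] = "high"
        extra["segment_id"] += "_on"
        table = pd.concat([table, extra], ignore_index=True)
        for held, tr, te in loso_splits(table):
            if held == "s0":
                assert set(table.loc[te, "label"]) == {"low", "high"}
            assert "s0" not in set(table.loc[tr, "subject_id"]) or held != "s0"

    def test_single_subject_errors(self):
        with pytest.raises(ValueError, match="2 distinct subjects"):
            list(loso_splits(make_table(n_subjects=1)))


class TestStandardize:
    def test_example_value(self):
        train = np.array([[8.0], [12.0]])  # mean 10, std 2
        test = np.array([[14.0]])
        _, scaled_test, _ = standardize(train, test)
        assert scaled_test[0, 0] == pytest.approx(2.0)

    def test_train_mean_zero_std_one(self):
        rng = np.random.default_rng(0)
        train = rng.normal(3, 5, (50, 4))
        scaled, _, _ = standardize(train, train[:5])
        np.testing.assert_allclose(scaled.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(scaled.std(axis=0), 1, atol=1e-10)

    def test_constant_column_flagged(self):
        train = np.column_stack([np.ones(10), np.arange(10.0)])
        scaled, _, record = standardize(train, train)
        assert record["degenerate"] == [0]
        np.testing.assert_allclose(scaled[:, 0], 0)

    def test_test_statistics_not_used(self):
        rng = np.random.default_rng(1)
        train = rng.normal(0, 1, (40, 3))
        test = rng.normal(5, 1, (10, 3))  # asymmetric: shifted test set
        _, scaled_test, _ = standardize(train, test)
        assert np.abs(scaled_test.mean(axis=0)).min() > 1.0


class TestLassoSelect:
    cfg = CVConfig()

    def _harness(self, seed=0, shuffle=False, duplicate=False):
        rng = np.random.default_rng(seed)
        n, n_subj = 200, 20
        X = rng.normal(0, 1, (n, 10))
        if duplicate:
            X[:, 2] = X[:, 0]
        y = X[:, 0] - X[:, 1] + rng.normal(0, 0.1, n)
        y = (y > np.median(y)).astype(float)
        if shuffle:
            y = rng.permutation(y)
        groups = np.repeat([f"g{i}" for i in range(n_subj)], n // n_subj)
        names = [f"x{j}" for j in range(10)]
        return X, y, groups, names

    def test_recovers_informative_features(self):
        # oracle: OLS on {x0, x1} explains most of the signal by construction
        X, y, groups, names = self._harness(seed=3)
        beta, *_ = np.linalg.lstsq(X[:, :2], y - y.mean(), rcond=None)
        resid = (y - y.mean()) - X[:, :2] @ beta
        assert 1 - resid.var() / y.var() > 0.5
        selected = lasso_select(X, y, groups, names, self.cfg, seed=0)
        assert {"x0", "x1"} <= set(selected)
        assert len(selected) <= 5

    def test_duplicated_informative_feature(self):
        X, y, groups, names = self._harness(seed=4, duplicate=True)
        selected = lasso_select(X, y, groups, names, self.cfg, seed=0)
        assert {"x0", "x2"} & set(selected)  # at least one copy survives

    def test_null_labels_select_little(self):
        sizes = []
        for seed in range(20):
            X, y, groups, names = self._harness(seed=seed, shuffle=True)
            sizes.append(len(lasso_select(X, y, groups, names, self.cfg, seed=0)))
        assert np.median(sizes) <= 2

    def test_single_class_raises(self):
        X, y, groups, names = self._harness()
        with pytest.raises(ValueError, match="single-class"):
            lasso_select(X, np.zeros_like(y), groups, names, self.cfg, seed=0)


class TestFitClassifier:
    def _clouds(self, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(-2, 1, (60, 3)), rng.normal(2, 1, (60, 3))])
        y = np.repeat([0.0, 1.0], 60)
        groups = np.tile(np.repeat([f"g{i}" for i in range(6)], 10), 2)
        return X, y, groups

    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_separated_clouds_high_accuracy(self, name):
        X, y, groups = self._clouds()
        cfg = CVConfig(grids=SMALL_GRIDS)
        model, _ = fit_classifier(name, X, y, groups, cfg, seed=0)
        assert (model.predict(X) == y).mean() >= 0.95

    def test_deterministic_hyperparameters(self):
        X, y, groups = self._clouds()
        cfg = CVConfig()
        _, p1 = fit_classifier("lr", X, y, groups, cfg, seed=5)
        _, p2 = fit_classifier("lr", X, y, groups, cfg, seed=5)
        assert p1 == p2

    def test_unknown_name(self):
        X, y, groups = self._clouds()
        with pytest.raises(ValueError, match="unknown classifier"):
            fit_classifier("mlp", X, y, groups, CVConfig(), seed=0)


class TestRunCV:
    def test_report_shape_and_leakage_free(self):
        table = make_table(n_subjects=8, rows_per_subject=4, effect=2.5)
        cfg = CVConfig(n_repeats=2, classifiers=("lr", "gnb"), grids=SMALL_GRIDS)
        report = run_cv(table, cfg)
        assert len(report.metrics) == 2 * 2  # repeats x classifiers
        assert report.n_iterations == 8 * 2
        assert ((report.metrics["accuracy"] >= 0) & (report.metrics["accuracy"] <= 1)).all()
        assert ((report.metrics["auc"] >= 0) & (report.metrics["auc"] <= 1)).all()

    def test_informative_effect_high_auc(self):
        table = make_table(n_subjects=10, rows_per_subject=6, effect=3.0)
        cfg = CVConfig(n_repeats=1, classifiers=("lr",), grids=SMALL_GRIDS)
        report = run_cv(table, cfg)
        assert report.metrics["auc"].mean() >= 0.9

    def test_null_effect_chance_auc(self):
        table = make_table(n_subjects=12, rows_per_subject=6, effect=0.0, seed=9)
        cfg = CVConfig(n_repeats=2, classifiers=("lr",), grids=SMALL_GRIDS)
        report = run_cv(table, cfg)
        assert 0.3 <= report.metrics["auc"].mean() <= 0.7

    def test_selection_counts_bounded(self):
        table = make_table(n_subjects=6, rows_per_subject=4)
        cfg = CVConfig(n_repeats=2, classifiers=("lr",), grids=SMALL_GRIDS)
        report = run_cv(table, cfg)
        assert max(report.selection_counts.values()) <= report.n_iterations

    def test_deterministic_serialization(self, tmp_path):
        table = make_table(n_subjects=6, rows_per_subject=4)
        cfg = CVConfig(n_repeats=1, classifiers=("lr", "rf"), grids=SMALL_GRIDS)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        run_cv(table, cfg).to_json(p1)
        run_cv(table, cfg).to_json(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_auc_invariant_to_monotone_score_transform(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        s = rng.normal(0, 1, 100)
        assert roc_auc_score(y, s) == pytest.approx(roc_auc_score(y, np.tanh(s) * 3 + 1))

    def test_report_round_trip(self, tmp_path):
        table = make_table(n_subjects=6, rows_per_subject=4)
        cfg = CVConfig(n_repeats=1, classifiers=("lr",), grids=SMALL_GRIDS)
        report = run_cv(table, cfg)
        path = tmp_path / "report.json"
        report.to_json(path)
        back = CVReport.from_json(path)
        pd.testing.assert_frame_equal(back.metrics, report.metrics)
        assert back.selection_counts == report.selection_counts
        assert back.n_iterations == report.n_iterations
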