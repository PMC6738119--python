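"""Feature screening, native KNN, cross-validation and sequential selection."""

import json

import numpy as np
import pandas as pd
import pytest

from invigor import (
    GeneratorConfig,
    SurrogateModelArtifact,
    apply_surrogate,
    build_feature_matrix,
    cohort_rates,
    compute_sm_invigor,
    cross_validate,
    generate_cohort,
    knn_predict,
    make_feature_selection_problem,
    power_law,
    screen_features,
    sequential_select,
)
from invigor.errors import DataError
from invigor.surrogate import _knn_votes


def _artifact(train, labels01, k, features=("f",)):
    train = np.atleast_2d(np.asarray(train, dtype=float).T).T
    return SurrogateModelArtifact(
        algorithm="knn",
        selected_features=list(features),
        k=k,
        feature_means=np.zeros(train.shape[1]),
        feature_scales=np.ones(train.shape[1]),
        training_values=train,
        training_labels=np.asarray(labels01, dtype=int),
        cv_accuracy=np.nan,
        resubstitution_accuracy=np.nan,
        seed_ledger={},
    )


class TestScreening:
    def test_hand_welch_t_test(self):
        # fast {4,5,6} vs slow {1,2,3}: |t| = 3.674, df = 4, p = 0.0214
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})
        y = ["slow", "slow", "slow", "fast", "fast", "fast"]
        res = screen_features(X, y, threshold_p=0.2)
        row = res.table.iloc[0]
        assert abs(row["t_statistic"]) == pytest.approx(3.674, abs=1e-3)
        assert row["p_value"] == pytest.approx(0.0214, abs=1e-3)
        assert row["admitted"]

    def test_identical_distributions_not_admitted(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        y = ["slow", "slow", "slow", "fast", "fast", "fast"]
        res = screen_features(X, y, threshold_p=0.2)
        assert res.table.iloc[0]["t_statistic"] == 0.0
        assert res.table.iloc[0]["p_value"] == 1.0
        assert not res.table.iloc[0]["admitted"]

    def test_threshold_one_admits_every_testable_feature(self):
        X, y = make_feature_selection_problem(60, seed=3)
        res = screen_features(X, y, threshold_p=1.0)
        assert res.table["admitted"].all()

    def test_zero_variance_feature_excluded_with_diagnostic(self):
        X = pd.DataFrame({"flat": [2.0] * 8, "ok": np.arange(8.0)})
        y = ["slow"] * 4 + ["fast"] * 4
        res = screen_features(X, y)
        assert "flat" in res.excluded
        assert list(res.table["feature"]) == ["ok"]


class TestKnn:
    def test_single_neighbour_hand_example(self):
        model = _artifact([0.0, 1.0, 10.0], [0, 0, 1], k=1)
        labels, _ = knn_predict(model, [[9.0]])
        assert labels[0] == "fast"

    def test_three_neighbour_majority_overrules_nearest(self):
        model = _artifact([0.0, 1.0, 10.0], [0, 0, 1], k=3)
        labels, votes = knn_predict(model, [[9.0]])
        assert labels[0] == "slow"
        assert votes[0] == 1

    def test_query_on_training_point_returns_its_label(self):
        model = _artifact([0.0, 1.0, 10.0], [0, 0, 1], k=1)
        assert knn_predict(model, [[10.0]])[0][0] == "fast"

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(21)
        train = rng.normal(size=(60, 3))
        y01 = (rng.random(60) < 0.5).astype(int)
        queries = rng.normal(size=(200, 3))
        for k in (1, 5, 9):
            pred, _ = _knn_votes(train, y01, queries, k)
            for qi in range(0, 200, 17):
                d = np.sqrt(((train - queries[qi]) ** 2).sum(axis=1))
                nearest = np.argsort(d, kind="stable")[:k]
                assert pred[qi] == int(y01[nearest].sum() > k / 2)

    def test_fewer_training_points_than_k_raises(self):
        model = _artifact([0.0, 1.0], [0, 1], k=5)
        with pytest.raises(DataError):
            knn_predict(model, [[0.5]])


class TestCrossValidate:
    def test_separable_clusters_reach_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-5, 0.3, (40, 2)), rng.normal(5, 0.3, (40, 2))])
        y = np.array(["slow"] * 40 + ["fast"] * 40, dtype=object)
        acc, _ = cross_validate(X, y, k=3, seed=1)
        assert acc == 1.0

    def test_same_seed_reproduces_per_repeat_accuracies(self):
        X, y = make_feature_selection_problem(80, seed=5)
        _, a1 = cross_validate(X[["signal_1", "signal_2"]], y, k=5, seed=9)
        _, a2 = cross_validate(X[["signal_1", "signal_2"]], y, k=5, seed=9)
        assert np.array_equal(a1, a2)

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 3))
        y = np.array(["slow", "fast"] * 100, dtype=object)
        acc, _ = cross_validate(X, y, k=7, repeats=20, seed=2)
        assert 0.42 < acc < 0.58

    def test_invariant_to_feature_order_and_affine_rescaling(self):
        X, y = make_feature_selection_problem(100, seed=6)
        cols = ["signal_1", "signal_2", "signal_3"]
        acc1, _ = cross_validate(X[cols], y, k=5, seed=3)
        acc2, _ = cross_validate(X[cols[::-1]], y, k=5, seed=3)
        rescaled = X[cols].copy()
        rescaled["signal_2"] = rescaled["signal_2"] * 250.0 - 14.0
        acc3, _ = cross_validate(rescaled, y, k=5, seed=3)
        assert acc1 == acc2 == acc3

    def test_class_smaller_than_fold_count_raises(self):
        X = np.zeros((10, 1))
        y = np.array(["fast"] * 8 + ["slow"] * 2, dtype=object)
        with pytest.raises(DataError):
            cross_validate(X, y, k=1, folds=5)


class TestSequentialSelect:
    def test_single_admitted_feature_limits_trace(self):
        rng = np.random.default_rng(1)
        sig = rng.normal(size=120)
        X = pd.DataFrame({"sig": sig, "noise": rng.normal(size=120)})
        y = np.where(sig > 0, "fast", "slow").astype(object)
        # only 'sig' passes a strict threshold
        artifact, trace = sequential_select(X, y, threshold_p=1e-6, seed=0)
        assert set(trace["n_features"]) == {1}
        assert artifact.selected_features == ["sig"]

    def test_equal_accuracy_prefers_smaller_feature_set(self):
        rng = np.random.default_rng(2)
        sig = np.concatenate([rng.normal(-4, 0.3, 60), rng.normal(4, 0.3, 60)])
        X = pd.DataFrame({"a": sig, "b": sig.copy()})  # duplicate information
        y = np.where(sig > 0, "fast", "slow").astype(object)
        artifact, trace = sequential_select(X, y, threshold_p=1.0, seed=0)
        best = trace["cv_accuracy"].max()
        assert len(artifact.selected_features) == 1
        assert artifact.cv_accuracy == best == 1.0

    def test_budget_smaller_than_zoo_raises(self):
        X, y = make_feature_selection_problem(60, seed=0)
        with pytest.raises(DataError, match="budget"):
            sequential_select(X, y, zoo=("knn", "naive_bayes"), budget=1)

    def test_trace_and_artifact_reproducible_from_seed(self):
        X, y = make_feature_selection_problem(100, seed=4)
        a1, t1 = sequential_select(X, y, seed=11)
        a2, t2 = sequential_select(X, y, seed=11)
        assert t1.equals(t2)
        assert a1.content_hash() == a2.content_hash()

    def test_comparator_zoo_members_recorded_in_trace(self):
        X, y = make_feature_selection_problem(80, seed=8)
        artifact, trace = sequential_select(
            X, y, zoo=("knn", "naive_bayes"), repeats=3, seed=1
        )
        assert {"knn", "naive_bayes"} <= set(trace["algorithm"])
        assert artifact.algorithm == "knn"


class TestArtifact:
    def test_json_round_trip_is_bit_identical(self):
        X, y = make_feature_selection_problem(80, seed=2)
        artifact, _ = sequential_select(X, y, seed=5)
        clone = SurrogateModelArtifact.from_json(artifact.to_json())
        assert clone.to_json() == artifact.to_json()
        assert clone.content_hash() == artifact.content_hash()

    def test_save_and_load(self, tmp_path):
        X, y = make_feature_selection_problem(80, seed=2)
        artifact, _ = sequential_select(X, y, seed=5)
        path = artifact.save(tmp_path / "model.json")
        assert SurrogateModelArtifact.load(path).to_json() == artifact.to_json()


@pytest.fixture(scope="module")
def trained():
    cohort, _ = generate_cohort(GeneratorConfig(n=200, seed=31))
    out = compute_sm_invigor(cohort, "sphere", power_law(0.5), 0.045)
    X, y, _ = build_feature_matrix(cohort, labels=out["rates"]["label"].to_numpy())
    artifact, _ = sequential_select(X, y, seed=3)
    return cohort, artifact


class TestApplySurrogate:
    def test_training_cohort_reproduces_resubstitution_accuracy(self, trained):
        cohort, artifact = trained
        result = apply_surrogate(artifact, cohort)
        rates = cohort_rates(cohort, "sphere", power_law(0.5))
        sm = np.where(rates["rate"] > 0.045, "fast", "slow")
        labelled = result["labels"].notna()
        acc = (result["labels"][labelled].to_numpy() == sm[labelled]).mean()
        assert acc == pytest.approx(artifact.resubstitution_accuracy, abs=1e-12)

    def test_missing_feature_column_error_names_it(self, trained):
        cohort, artifact = trained
        broken = cohort.copy()
        broken.df = broken.df.drop(columns=["ki67_percent"])
        if "ki67_percent" not in artifact.selected_features:
            pytest.skip("winning feature set does not use ki67")
        with pytest.raises(KeyError, match="ki67_percent"):
            apply_surrogate(artifact, broken)

    def test_cohort_without_survival_gives_labels_only(self, trained):
        cohort, artifact = trained
        stripped = cohort.copy()
        stripped.df["bcss_months"] = np.nan
        result = apply_surrogate(artifact, stripped)
        assert result["report"] is None
        assert result["labels"].notna().sum() > 0

    def test_predicted_groups_separate_survival_on_fresh_cohort(self, trained):
        _, artifact = trained
        validation, _ = generate_cohort(GeneratorConfig(n=1200, seed=77))
        result = apply_surrogate(artifact, validation)
        assert result["report"]["logrank"]["p_value"] < 0.05
        km = result["report"]
        assert km["km_fast"]["survival_at_120m"] < km["km_slow"]["survival_at_120m"]


class TestEndToEndRecovery:
    def test_informative_cohort_beats_majority_class(self):
        from scipy import stats

        hits = 0
        for seed in range(5):
            cohort, truth = generate_cohort(GeneratorConfig(n=200, seed=60 + seed))
            y = truth["true_group"].to_numpy(dtype=object)
            X, yy, _ = build_feature_matrix(cohort, labels=y)
            artifact, _ = sequential_select(X, yy, seed=seed)
            n = len(yy)
            maj = max(np.mean(yy == "fast"), np.mean(yy == "slow"))
            k_correct = int(round(artifact.cv_accuracy * n))
            p = stats.binomtest(k_correct, n, maj, alternative="greater").pvalue
            hits += p < 0.01
        assert hits >= 4
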