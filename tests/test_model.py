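"""Training, evaluation, selection and persistence of completeness models."""

import numpy as np
import pytest

from plastidcheck.kegg_modules import ModuleCoverageVector
from plastidcheck.model import (
    ALGORITHMS,
    EvaluationReport,
    FeatureOrderError,
    ModelArtifactError,
    evaluate_model,
    load_model,
    predict_batch,
    predict_completeness,
    save_model,
    select_best_model,
    split_train_test,
    train_model,
)
from plastidcheck.simulator import (
    LabeledDataset,
    LabeledExample,
    make_training_grid,
    synthesize_reference_profiles,
)


@pytest.fixture(scope="module")
def small_grid(catalog):
    refs = [p for p, _ in synthesize_reference_profiles(12, "plastid_like", catalog, 21)]
    return make_training_grid(refs, catalog, seed=21)


@pytest.fixture(scope="module")
def trained(small_grid):
    train, test = split_train_test(small_grid, 0.9, seed=5)
    res = train_model(train, "gradient_boost", n_folds=5, seed=5)
    return res, train, test


class TestSplit:
    def test_genome_level_partition(self, small_grid):
        train, test = split_train_test(small_grid, 0.9, seed=1)
        tr, te = set(train.source_genome_ids), set(test.source_genome_ids)
        assert tr.isdisjoint(te)
        assert tr | te == set(small_grid.source_genome_ids)
        assert len(train) + len(test) == len(small_grid)

    def test_ten_genomes_split_nine_one(self, catalog):
        refs = [p for p, _ in synthesize_reference_profiles(10, "plastid_like", catalog, 2)]
        ds = make_training_grid(refs, catalog, fractions=[1.0], seed=2)
        train, test = split_train_test(ds, 0.9, seed=3)
        assert len(train.source_genome_ids) == 9
        assert len(test.source_genome_ids) == 1

    def test_degenerate_fractions_rejected(self, small_grid):
        for bad in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                split_train_test(small_grid, bad, seed=0)

    def test_deterministic(self, small_grid):
        a = split_train_test(small_grid, 0.9, seed=9)
        b = split_train_test(small_grid, 0.9, seed=9)
        assert a[0].source_genome_ids == b[0].source_genome_ids


class TestTraining:
    def test_fold_count_and_cv_summary(self, trained):
        res, _, _ = trained
        assert len(res.fold_models) == 5
        assert len(res.cv_summary) == 5
        assert all("median_difference" in row for row in res.cv_summary)

    def test_three_supported_algorithms(self):
        assert ALGORITHMS == ("ada_boost", "gradient_boost", "random_forest")

    def test_unknown_algorithm_rejected(self, small_grid):
        train, _ = split_train_test(small_grid, 0.9, seed=5)
        with pytest.raises(ValueError):
            train_model(train, "svm", seed=0)

    def test_too_few_genomes_for_folds(self, catalog):
        refs = [p for p, _ in synthesize_reference_profiles(3, "plastid_like", catalog, 2)]
        ds = make_training_grid(refs, catalog, fractions=[1.0, 0.5], seed=2)
        with pytest.raises(ValueError):
            train_model(ds, "gradient_boost", n_folds=5, seed=0)

    def test_identical_seed_identical_predictions(self, small_grid):
        train, test = split_train_test(small_grid, 0.9, seed=5)
        X = test.feature_matrix()
        a = train_model(train, "random_forest", seed=13)
        b = train_model(train, "random_forest", seed=13)
        assert np.array_equal(predict_batch(a.final_model, X), predict_batch(b.final_model, X))


class TestPrediction:
    def test_extreme_vectors(self, trained):
        res, train, _ = trained
        order = train.module_order
        lo = predict_completeness(
            res.final_model, ModuleCoverageVector("z", order, (0.0,) * len(order))
        )
        hi = predict_completeness(
            res.final_model, ModuleCoverageVector("o", order, (1.0,) * len(order))
        )
        assert lo <= 15.0
        assert hi >= 90.0

    def test_clamped_to_percent_range(self, trained):
        res, _, test = trained
        preds = predict_batch(res.final_model, test.feature_matrix())
        assert preds.min() >= 0.0 and preds.max() <= 100.0

    def test_feature_order_mismatch_raises(self, trained):
        res, train, _ = trained
        wrong = tuple(reversed(train.module_order))
        vec = ModuleCoverageVector("x", wrong, (0.5,) * len(wrong))
        with pytest.raises(FeatureOrderError):
            predict_completeness(res.final_model, vec)


def _report(median_difference, pearson_r=0.9):
    return EvaluationReport(
        per_level={}, linear_fit=None, pearson_r=pearson_r, pearson_p=None,
        mse=0.0, median_difference=median_difference, n=10,
    )


class TestEvaluation:
    def test_perfect_predictor_statistics(self, trained):
        res, train, _ = trained

        class Identity:
            def predict(self, X):
                return train.labels()[: len(X)]

        model = res.final_model
        perfect = type(model)(
            model.algorithm, model.feature_order, Identity(), 0, {}
        )
        rep = evaluate_model(perfect, train)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.linear_fit["slope"] == pytest.approx(1.0)
        assert rep.linear_fit["intercept"] == pytest.approx(0.0, abs=1e-9)
        assert rep.median_difference == pytest.approx(0.0)
        assert rep.mse == pytest.approx(0.0)

    def test_constant_predictor_flagged(self, trained):
        res, train, _ = trained

        class Constant:
            def predict(self, X):
                return np.full(len(X), 50.0)

        model = res.final_model
        const = type(model)(model.algorithm, model.feature_order, Constant(), 0, {})
        rep = evaluate_model(const, train)
        assert rep.pearson_r is None
        assert rep.linear_fit is None

    def test_per_level_keys_match_grid(self, trained):
        res, _, test = trained
        rep = evaluate_model(res.final_model, test)
        assert set(rep.per_level) == set(test.labels())

    def test_single_genome_level_sd_zero_when_one_prediction(self, trained):
        res, _, test = trained
        one = LabeledDataset([test.examples[0]], {})
        rep = evaluate_model(res.final_model, one)
        (med, sd), = rep.per_level.values()
        assert sd == 0.0

    def test_empty_test_set_rejected(self, trained):
        res, _, _ = trained
        with pytest.raises(ValueError):
            evaluate_model(res.final_model, LabeledDataset([], {}))


class TestSelection:
    def test_smallest_median_discrepancy_wins(self):
        reports = {
            "ada_boost": _report(-2.12),
            "gradient_boost": _report(0.37),
            "random_forest": _report(-7.5),
        }
        assert select_best_model(reports) == "gradient_boost"

    def test_single_candidate(self):
        assert select_best_model({"random_forest": _report(3.0)}) == "random_forest"

    def test_tie_broken_by_pearson(self):
        reports = {
            "ada_boost": _report(1.0, pearson_r=0.99),
            "gradient_boost": _report(-1.0, pearson_r=0.90),
        }
        assert select_best_model(reports) == "ada_boost"

    def test_full_tie_falls_back_to_name_order(self):
        reports = {
            "random_forest": _report(1.0, pearson_r=0.9),
            "ada_boost": _report(1.0, pearson_r=0.9),
        }
        assert select_best_model(reports) == "ada_boost"


class TestPersistence:
    def test_round_trip_bit_exact(self, trained, tmp_path):
        res, _, test = trained
        path = tmp_path / "model.joblib"
        save_model(res.final_model, path)
        back = load_model(path)
        X = test.feature_matrix()[:100]
        assert np.array_equal(predict_batch(back, X), predict_batch(res.final_model, X))
        assert back.algorithm == res.final_model.algorithm
        assert back.feature_order == res.final_model.feature_order

    def test_catalog_mismatch_on_load(self, trained, tmp_path):
        res, _, _ = trained
        path = tmp_path / "model.joblib"
        save_model(res.final_model, path)
        with pytest.raises(ModelArtifactError, match="catalog"):
            load_model(path, expected_feature_order=["MX99999"])

    def test_non_model_file_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "junk.joblib"
        joblib.dump({"something": 1}, path)
        with pytest.raises(ModelArtifactError):
            load_model(path)
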