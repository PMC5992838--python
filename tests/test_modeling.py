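import itertools

import numpy as np
import pytest
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from psnpipe import (ModelConfig, TopoFeatureSet, ValidationError,
                     compare_models, compute_metrics, crossvalidate,
                     stratified_split, train_predict, weighted_vote)
from psnpipe.modeling import svm_grid_search


def feature_set(values, family="centrality"):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    return TopoFeatureSet([f"p{i:03d}" for i in range(values.shape[0])],
                          [f"f{j}" for j in range(values.shape[1])],
                          values, family)


def separable(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    x = y * 10.0 + rng.normal(0, 0.1, n)
    return feature_set(x), y


class TestStratifiedSplit:
    def test_per_class_arithmetic(self):
        ids = [f"p{i}" for i in range(100)]
        labels = np.r_[np.ones(60, dtype=int), np.zeros(40, dtype=int)]
        split = stratified_split(ids, labels, 0.5, rng_seed=0)
        train_labels = labels[[ids.index(p) for p in split.train]]
        assert train_labels.sum() == 30
        assert len(split.train) == 50

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(30)]
        labels = np.array([0, 1] * 15)
        a = stratified_split(ids, labels, 0.5, rng_seed=7)
        b = stratified_split(ids, labels, 0.5, rng_seed=7)
        assert a.train == b.train and a.test == b.test

    def test_odd_class_ceil_rule(self):
        ids = [f"p{i}" for i in range(11)]
        labels = np.r_[np.zeros(5, dtype=int), np.ones(6, dtype=int)]
        split = stratified_split(ids, labels, 0.5, rng_seed=0)
        # ceil(0.5*5) + ceil(0.5*6) = 3 + 3
        assert len(split.train) == 6

    def test_singleton_class_errors(self):
        with pytest.raises(ValidationError):
            stratified_split(["a", "b", "c"], np.array([0, 0, 1]), 0.5, 0)


class TestCrossvalidate:
    def test_fold_count_is_repeats_times_folds(self):
        fs, y = separable(40)
        _, _, baccs = crossvalidate(fs, y, ModelConfig("LDA"), repeats=10,
                                    folds=5)
        assert len(baccs) == 50

    def test_perfectly_separable_feature(self):
        fs, y = separable(40)
        mean, _, _ = crossvalidate(fs, y, ModelConfig("LDA"), repeats=2)
        assert mean == pytest.approx(1.0)

    def test_null_features_score_at_chance(self):
        rng = np.random.default_rng(2)
        n = 500
        fs = feature_set(rng.normal(size=(n, 20)))
        y = rng.integers(0, 2, n)
        mean, _, _ = crossvalidate(fs, y, ModelConfig("LDA", rng_seed=2),
                                   repeats=3)
        assert 0.45 <= mean <= 0.55


class TestTrainPredict:
    def test_train_equals_test_is_perfect_on_separable(self):
        fs, y = separable(40)
        ids = fs.patient_ids
        split_all = stratified_split(ids, y, 0.5, 0)
        split = type(split_all)(train=list(ids), test=list(ids),
                                stratified=False, rng_seed=0)
        _, rep = train_predict(fs, y, split, ModelConfig("LDA"),
                               cv_estimate=False)
        assert rep.acc == 1.0

    def test_constant_features_chance_level(self):
        fs = feature_set(np.ones((60, 3)))
        y = np.array([0, 1] * 30)
        split = stratified_split(fs.patient_ids, y, 0.5, 1)
        _, rep = train_predict(fs, y, split, ModelConfig("RF", n_trees=50),
                               cv_estimate=False)
        assert rep.bacc == pytest.approx(0.5, abs=0.1)

    def test_scores_in_unit_interval(self):
        fs, y = separable(40, seed=3)
        split = stratified_split(fs.patient_ids, y, 0.5, 2)
        for algo in ("LDA", "RF", "SVM"):
            cfg = ModelConfig(algo, n_trees=50, optimize=False)
            scores, _ = train_predict(fs, y, split, cfg, cv_estimate=False)
            vals = np.array(list(scores.values()))
            assert ((vals >= 0) & (vals <= 1)).all()
            assert set(scores) == set(split.test)


class TestSVMGrid:
    def test_choice_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        n = 40
        y = np.array([0, 1] * (n // 2))
        x = np.column_stack([y + rng.normal(0, 0.8, n),
                             rng.normal(size=n)])
        config = ModelConfig("SVM", svm_kernel="radial", rng_seed=5)
        picked = svm_grid_search(x, y, config)

        # independent exhaustive scan with the same fold protocol
        from sklearn.model_selection import StratifiedKFold
        powers = config.svm_grid_powers
        cv = StratifiedKFold(5, shuffle=True, random_state=config.rng_seed)
        splits = list(cv.split(x, y))
        best, best_score = None, -np.inf
        for p_c, p_g in itertools.product(powers, powers):
            C, gamma = 2.0 ** (2 * p_c), 2.0 ** (2 * p_g)
            baccs = []
            for tr, va in splits:
                sc = StandardScaler().fit(x[tr])
                est = SVC(kernel="rbf", C=C, gamma=gamma, random_state=5)
                est.fit(sc.transform(x[tr]), y[tr])
                pred = est.predict(sc.transform(x[va]))
                baccs.append(compute_metrics(y[va], pred).bacc)
            score = np.mean(baccs)
            if score > best_score + 1e-12:
                best, best_score = (C, gamma), score
        assert picked == best
        grid_values = {2.0 ** (2 * p) for p in powers}
        assert picked[0] in grid_values and picked[1] in grid_values


class TestComputeMetrics:
    def test_perfect_prediction(self):
        rep = compute_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert rep.acc == rep.bacc == rep.mcc == 1.0

    def test_degenerate_all_positive_predictor(self):
        y = np.r_[np.ones(30, dtype=int), np.zeros(70, dtype=int)]
        rep = compute_metrics(y, np.ones(100, dtype=int))
        assert rep.bacc == pytest.approx(0.5)
        assert rep.mcc == 0.0

    def test_hand_computed_confusion(self):
        # TP=3 FP=1 FN=2 TN=4
        y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 1, 0, 0, 0, 0]
        rep = compute_metrics(y_true, y_pred)
        assert (rep.tp, rep.fp, rep.fn, rep.tn) == (3, 1, 2, 4)
        assert rep.acc == pytest.approx(0.7)
        assert rep.bacc == pytest.approx(0.7)
        assert rep.mcc == pytest.approx(0.4082, abs=1e-3)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            compute_metrics([], [])


class TestWeightedVote:
    def test_single_model_identity(self):
        scores = {"a": 0.2, "b": 0.9}
        consensus, pred = weighted_vote([scores], [0.7])
        assert consensus == scores
        assert pred == {"a": 0, "b": 1}

    def test_tie_at_threshold_counts_positive(self):
        consensus, pred = weighted_vote([{"x": 1.0}, {"x": 0.0}], [0.5, 0.5])
        assert consensus["x"] == pytest.approx(0.5)
        assert pred["x"] == 1

    def test_weights_normalized(self):
        sets = [{"a": 0.1}, {"a": 0.5}, {"a": 0.9}]
        perfs = [2.0, 3.0, 5.0]
        consensus, _ = weighted_vote(sets, perfs)
        expected = (2 * 0.1 + 3 * 0.5 + 5 * 0.9) / 10
        assert consensus["a"] == pytest.approx(expected)

    def test_dominant_model_wins(self):
        a = {"x": 0.95, "y": 0.05}
        b = {"x": 0.1, "y": 0.9}
        consensus, pred = weighted_vote([a, b], [1.0, 1e-9])
        assert pred == {"x": 1, "y": 0}

    def test_zero_performances_error(self):
        with pytest.raises(ValidationError):
            weighted_vote([{"a": 0.5}], [0.0])


class TestCompareModels:
    def test_identical_groups_not_significant(self):
        rep = compare_models({"a": [0.9, 0.91, 0.92], "b": [0.9, 0.91, 0.92]})
        assert rep.delta_bacc[("a", "b")] == 0.0
        assert rep.p_values[("a", "b")] == pytest.approx(1.0)
        assert not rep.significant[("a", "b")]

    def test_separated_groups_significant(self):
        rep = compare_models({"good": [0.9, 0.91, 0.92],
                              "bad": [0.5, 0.51, 0.52]})
        assert rep.delta_bacc[("good", "bad")] == pytest.approx(0.40)
        assert rep.significant[("good", "bad")]

    def test_three_groups_tukey_pairs(self):
        rng = np.random.default_rng(0)
        rep = compare_models({g: list(rng.normal(mu, 0.01, 5))
                              for g, mu in [("a", 0.5), ("b", 0.7), ("c", 0.9)]})
        assert len(rep.p_values) == 3
        assert rep.anova_p is not None


class TestLeakageAudit:
    def test_test_only_information_cannot_help(self):
        """A feature informative only on the held-out rows must not lift
        performance: all fit-time statistics come from training rows."""
        rng = np.random.default_rng(8)
        n = 200
        y = np.array([0, 1] * (n // 2))
        x = rng.normal(size=(n, 5))
        ids = [f"p{i:03d}" for i in range(n)]
        split = stratified_split(ids, y, 0.5, rng_seed=0)
        test_rows = [ids.index(p) for p in split.test]
        x[test_rows, 0] = y[test_rows] * 50.0   # blatant test-only signal
        fs = TopoFeatureSet(ids, [f"f{j}" for j in range(5)], x, "centrality")
        _, rep = train_predict(fs, y, split, ModelConfig("LDA"),
                               cv_estimate=False)
        assert rep.bacc < 0.65
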