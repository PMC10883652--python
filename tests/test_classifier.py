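"""BM zero replacement, forest ensembles, RFE and model selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from occubiome.classifier import (
    BmParams,
    bm_replace,
    load_model,
    predict,
    rfe,
    save_model,
    select_best_model,
    stratified_split,
    train_forest_ensemble,
)
from occubiome.tables import FeatureTable, TableError


class TestBmReplace:
    def test_no_zeros_is_plain_closure(self):
        table = FeatureTable(pd.DataFrame({"s": [2, 3, 5]}, index=list("abc")))
        out = bm_replace(table)
        np.testing.assert_allclose(out.values["s"], [0.2, 0.3, 0.5], atol=1e-15)

    def test_sq_prior_hand_example(self):
        # counts (0, 9, 1): n=10, s=sqrt(10); zero -> (1/3)*s/(n+s)
        table = FeatureTable(pd.DataFrame({"s": [0, 9, 1]}, index=list("abc")))
        out = bm_replace(table).values["s"].to_numpy()
        s = math.sqrt(10)
        expected_zero = (1 / 3) * s / (10 + s)
        assert out[0] == pytest.approx(expected_zero, abs=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        # "proportionally reduced": the 9:1 ratio survives exactly
        assert out[1] / out[2] == pytest.approx(9.0, abs=1e-12)
        np.testing.assert_allclose(out[1:], [0.82792408, 0.09199156], atol=1e-7)

    def test_all_zero_sample_rejected(self):
        table = FeatureTable(pd.DataFrame({"s": [0, 0]}, index=["a", "b"]))
        with pytest.raises(TableError):
            bm_replace(table)

    @pytest.mark.parametrize("prior", ["SQ", "GBM", "Bayes-Laplace"])
    @given(seed=st.integers(min_value=0, max_value=2000))
    def test_rows_sum_to_one_positive_ratios_preserved(self, prior, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(8, 5))
        counts[rng.integers(0, 8), :] += 1  # avoid all-zero samples
        if (counts.sum(axis=0) == 0).any():
            counts[0, :] += 1
        table = FeatureTable(
            pd.DataFrame(counts, index=[f"f{i}" for i in range(8)], columns=list("abcde"))
        )
        out = bm_replace(table, BmParams(prior)).values.to_numpy()
        assert (out > 0).all()
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-12)
        for j in range(counts.shape[1]):
            nz = counts[:, j] > 0
            if nz.sum() >= 2:
                orig = counts[nz, j] / counts[nz, j].sum()
                repl = out[nz, j] / out[nz, j].sum()
                np.testing.assert_allclose(repl, orig, atol=1e-12)


def _separable_data(rng, n=24, m=6):
    y = np.array(["laborer", "student"] * (n // 2))
    X = rng.normal(size=(n, m))
    X[:, 0] = np.where(y == "laborer", 5.0, -5.0) + rng.normal(0, 0.1, n)
    cols = [f"f{i}" for i in range(m)]
    return pd.DataFrame(X, columns=cols), y


class TestForestEnsemble:
    def test_perfect_feature_learned_and_ranked_first(self, rng):
        Xtr, ytr = _separable_data(rng)
        Xte, yte = _separable_data(rng)
        res = train_forest_ensemble(Xtr, ytr, Xte, yte, n_forests=10, trees_per_forest=5, seed=0)
        assert res.train_accuracy == 1.0
        assert res.test_accuracy == 1.0
        assert res.ranking.loc["f0", "rank"] == 1

    def test_random_labels_near_chance(self, rng):
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(30, 5)), columns=[f"f{i}" for i in range(5)])
            y = r.permutation(["a", "b"] * 15)
            Xte = pd.DataFrame(r.normal(size=(30, 5)), columns=X.columns)
            yte = r.permutation(["a", "b"] * 15)
            res = train_forest_ensemble(X, y, Xte, yte, n_forests=10, trees_per_forest=5, seed=seed)
            accs.append(res.test_accuracy)
        assert 0.3 <= float(np.mean(accs)) <= 0.7

    def test_deterministic_for_fixed_seed(self, rng):
        Xtr, ytr = _separable_data(rng)
        Xte, yte = _separable_data(rng)
        r1 = train_forest_ensemble(Xtr, ytr, Xte, yte, n_forests=1, trees_per_forest=3, seed=11)
        r2 = train_forest_ensemble(Xtr, ytr, Xte, yte, n_forests=1, trees_per_forest=3, seed=11)
        pd.testing.assert_frame_equal(r1.ranking, r2.ranking)
        assert r1.train_accuracy == r2.train_accuracy
        assert r1.test_accuracy == r2.test_accuracy

    def test_single_class_labels_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            train_forest_ensemble(X, ["a"] * 10, X, ["a"] * 10, seed=0)


class TestRfe:
    def test_trace_structure(self, rng):
        Xtr, ytr = _separable_data(rng, m=5)
        Xte, yte = _separable_data(rng, m=5)
        trace = rfe(Xtr, ytr, Xte, yte, n_forests=5, trees_per_forest=3, seed=2)
        assert len(trace.steps) == 5
        seen = set()
        for k, step in enumerate(trace.steps):
            assert len(step.features) == 5 - k
            assert not (set(step.features) & seen)  # eliminated never reappear
            seen.add(step.eliminated)

    def test_single_feature_trace(self, rng):
        Xtr, ytr = _separable_data(rng, m=1)
        Xte, yte = _separable_data(rng, m=1)
        trace = rfe(Xtr, ytr, Xte, yte, n_forests=3, trees_per_forest=3, seed=0)
        assert len(trace.steps) == 1
        assert trace.steps[0].features == ("f0",)

    def test_informative_feature_survives(self, rng):
        survived = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            Xtr, ytr = _separable_data(r, m=3)
            Xte, yte = _separable_data(r, m=3)
            trace = rfe(Xtr, ytr, Xte, yte, n_forests=10, trees_per_forest=3, seed=seed)
            if trace.steps[-1].features == ("f0",):
                survived += 1
        assert survived >= 9

    def test_end_to_end_reproducibility(self, rng):
        Xtr, ytr = _separable_data(rng, m=4)
        Xte, yte = _separable_data(rng, m=4)
        t1 = rfe(Xtr, ytr, Xte, yte, n_forests=4, trees_per_forest=3, seed=6)
        t2 = rfe(Xtr, ytr, Xte, yte, n_forests=4, trees_per_forest=3, seed=6)
        assert t1.steps == t2.steps


class TestSelectBestModel:
    def _trace_and_data(self, rng):
        Xtr, ytr = _separable_data(rng, m=4)
        Xte, yte = _separable_data(rng, m=4)
        trace = rfe(Xtr, ytr, Xte, yte, n_forests=5, trees_per_forest=3, seed=4)
        return trace, Xtr, ytr, Xte, yte

    def test_minimum_features_among_equal_accuracy(self, rng):
        trace, *data = self._trace_and_data(rng)
        model = select_best_model(trace, *data)
        best = max(
            (s.test_accuracy, s.train_accuracy, -len(s.features)) for s in trace.steps
        )
        assert (model.test_accuracy, model.train_accuracy, -len(model.features)) == best

    def test_refit_reproduces_trace_accuracies(self, rng):
        trace, *data = self._trace_and_data(rng)
        model = select_best_model(trace, *data)
        step = trace.steps[model.step_index]
        assert model.train_accuracy == step.train_accuracy
        assert model.test_accuracy == step.test_accuracy

    def test_prediction_consistency_and_errors(self, rng):
        trace, Xtr, ytr, Xte, yte = self._trace_and_data(rng)
        model = select_best_model(trace, Xtr, ytr, Xte, yte)
        preds = predict(model, Xtr)
        assert (preds.to_numpy() == ytr).mean() == model.train_accuracy
        # permuted sample order permutes predictions
        perm = Xtr.iloc[::-1]
        np.testing.assert_array_equal(predict(model, perm).to_numpy(), preds.to_numpy()[::-1])
        # missing feature is named
        with pytest.raises(TableError, match=model.features[0]):
            predict(model, Xtr.drop(columns=[model.features[0]]))

    def test_serialization_round_trip(self, rng, tmp_path):
        trace, Xtr, ytr, Xte, yte = self._trace_and_data(rng)
        model = select_best_model(trace, Xtr, ytr, Xte, yte)
        save_model(model, tmp_path / "model")
        loaded = load_model(tmp_path / "model")
        assert loaded.features == model.features
        np.testing.assert_array_equal(
            predict(loaded, Xtr).to_numpy(), predict(model, Xtr).to_numpy()
        )


class TestStratifiedSplit:
    def test_sizes_and_stratification(self):
        ids = [f"s{i}" for i in range(40)]
        labels = ["a"] * 20 + ["b"] * 20
        train, test = stratified_split(ids, labels, 12, seed=0)
        assert len(train) == 28 and len(test) == 12
        test_labels = [labels[ids.index(s)] for s in test]
        assert test_labels.count("a") == 6 and test_labels.count("b") == 6
        assert not set(train) & set(test)

    def test_deterministic(self):
        ids = [f"s{i}" for i in range(20)]
        labels = ["a", "b"] * 10
        assert stratified_split(ids, labels, 6, seed=5) == stratified_split(ids, labels, 6, seed=5)
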