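"""Random-forest voting, evaluation metrics and feature selection."""

import math

import numpy as np
import pandas as pd
import pytest

import nucmorph as nm


def _separable_table(n=100, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["normal"] * (n // 2) + ["HCC"] * (n // 2))
    x0 = np.where(y == "HCC", 3.0, -3.0) + rng.normal(0, 0.3, n)
    x1 = rng.normal(0, 1, n)
    return nm.FeatureTable(pd.DataFrame({"x0": x0, "x1": x1}), y)


def _planted_table(n=200, n_signal=4, n_noise=4, shift=1.5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["normal"] * (n // 2) + ["HCC"] * (n // 2))
    cls = (y == "HCC").astype(float)
    cols = {f"sig_{j}": rng.normal(0, 1, n) + shift * cls
            for j in range(n_signal)}
    cols.update({f"noise_{j}": rng.normal(0, 1, n) for j in range(n_noise)})
    return nm.FeatureTable(pd.DataFrame(cols), y)


class TestTrainClassifier:
    def test_separable_data_training_accuracy_one(self):
        t = _separable_table()
        ens = nm.train_classifier(t, n_trees=100, seed=0)
        assert nm.evaluate(ens.predict(t.features), t.labels).ACC == 1.0

    def test_same_seed_identical_predictions(self):
        t = _separable_table(seed=1)
        held = _separable_table(seed=2)
        p1 = nm.train_classifier(t, n_trees=50, seed=5).predict(held.features)
        p2 = nm.train_classifier(t, n_trees=50, seed=5).predict(held.features)
        assert (p1 == p2).all()

    def test_single_class_raises(self):
        t = _separable_table()
        bad = nm.FeatureTable(t.features, np.array(["HCC"] * len(t)))
        with pytest.raises(ValueError, match="single class"):
            nm.train_classifier(bad)

    def test_majority_vote_equals_sklearn_prediction(self):
        """The ensemble decision is the brute-force majority over trees."""
        t = _separable_table(seed=3)
        held = _planted_table(seed=4, shift=0.4)  # hard data: split votes
        ens = nm.train_classifier(t, n_trees=101, seed=0)
        X = held.features[["sig_0", "sig_1"]].to_numpy()
        votes = ens.tree_votes(X)
        manual = []
        for col in votes.T:
            vals, counts = np.unique(col, return_counts=True)
            manual.append(vals[counts.argmax()] if counts.max() * 2 > len(col)
                          else None)
        vote_pred = ens.vote_predict(X)
        for m, v in zip(manual, vote_pred):
            if m is not None:  # odd tree count: no ties expected
                assert m == v
        assert (vote_pred == ens.predict(X)).mean() >= 0.99

    def test_label_shuffle_gives_chance_accuracy(self):
        """Permutation null: 10-fold CV ACC within [0.4, 0.6] for >= 95%
        of shuffles."""
        t = _planted_table(n=200, shift=1.5, seed=0)
        rng = np.random.default_rng(0)
        ok = 0
        for _ in range(20):
            sh = nm.FeatureTable(t.features, rng.permutation(t.labels))
            acc = nm.cross_validate(sh, folds=10, seed=1, n_trees=50)["ACC"]
            ok += 0.4 <= acc <= 0.6
        assert ok >= 19


class TestEvaluate:
    def test_confusion_rate_formulas(self):
        pred = np.array(["HCC"] * 90 + ["normal"] * 10 +  # true HCC
                        ["normal"] * 80 + ["HCC"] * 20)   # true normal
        lab = np.array(["HCC"] * 100 + ["normal"] * 100)
        m = nm.evaluate(pred, lab)
        assert (m.TP, m.FN, m.TN, m.FP) == (90, 10, 80, 20)
        assert m.ACC == pytest.approx(0.85)
        assert m.SEN == pytest.approx(0.90)
        assert m.SPE == pytest.approx(0.80)

    def test_all_correct(self):
        lab = np.array(["HCC", "normal", "HCC"])
        m = nm.evaluate(lab, lab)
        assert (m.ACC, m.SEN, m.SPE) == (1.0, 1.0, 1.0)

    def test_accuracy_is_prevalence_weighted_sen_spe(self, rng):
        pred = np.where(rng.random(300) < 0.5, "HCC", "normal")
        lab = np.where(rng.random(300) < 0.3, "HCC", "normal")
        m = nm.evaluate(pred, lab)
        prev = (m.TP + m.FN) / 300
        assert m.ACC == pytest.approx(prev * m.SEN + (1 - prev) * m.SPE)

    def test_zero_denominator_flagged_not_silent(self):
        m = nm.evaluate(np.array(["normal"]), np.array(["normal"]))
        assert m.SEN is None and m.SPE == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            nm.evaluate(np.array([]), np.array([]))


class TestCrossValidate:
    def test_separable_data_near_perfect(self):
        res = nm.cross_validate(_separable_table(n=120), folds=10, seed=0,
                                n_trees=100)
        assert res["ACC"] >= 0.99

    def test_same_seed_identical_results(self):
        t = _planted_table(seed=6)
        a = nm.cross_validate(t, folds=5, seed=3, n_trees=50)
        b = nm.cross_validate(t, folds=5, seed=3, n_trees=50)
        assert a["ACC"] == b["ACC"]
        assert [m.TP for m in a["folds"]] == [m.TP for m in b["folds"]]

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError, match="folds"):
            nm.cross_validate(_separable_table(n=10), folds=10)


class TestPaperSplit:
    def test_full_scale_bookkeeping(self):
        labels = np.array(["normal"] * 4860 + ["HCC"] * 4860)
        train, test = nm.paper_split(labels, seed=0)
        assert len(train) == 5200 and len(test) == 4520
        assert len(train) + len(test) == 9720
        for idx, per_class in ((train, 2600), (test, 2260)):
            vals, counts = np.unique(labels[idx], return_counts=True)
            assert dict(zip(vals, counts)) == {"HCC": per_class,
                                               "normal": per_class}
        assert len(np.intersect1d(train, test)) == 0

    def test_insufficient_samples_raise(self):
        labels = np.array(["normal"] * 100 + ["HCC"] * 100)
        with pytest.raises(ValueError, match="needs"):
            nm.paper_split(labels)


class TestRankLibraryNuclei:
    def test_informative_column_ranks_first(self):
        t = _planted_table(n=200, n_signal=1, n_noise=1, shift=2.5, seed=0)
        ranked = nm.rank_library_nuclei(t, folds=5, seed=0, n_trees=25)
        assert ranked["column"].iloc[0] == "sig_0"

    def test_identical_columns_keep_input_order(self):
        rng = np.random.default_rng(0)
        y = np.array(["normal"] * 30 + ["HCC"] * 30)
        col = rng.normal(0, 1, 60)
        t = nm.FeatureTable(pd.DataFrame({f"c{j}": col for j in range(5)}), y)
        ranked = nm.rank_library_nuclei(t, folds=3, seed=0, n_trees=5)
        assert list(ranked["column"]) == [f"c{j}" for j in range(5)]

    def test_one_rank_per_column(self):
        rng = np.random.default_rng(1)
        y = np.array(["normal"] * 20 + ["HCC"] * 20)
        t = nm.FeatureTable(
            pd.DataFrame(rng.normal(0, 1, (40, 160)),
                         columns=[f"JI.lib_{j:04d}" for j in range(160)]), y)
        ranked = nm.rank_library_nuclei(t, folds=2, seed=0, n_trees=4)
        assert len(ranked) == 160
        assert set(ranked["column"]) == set(t.features.columns)


class TestGrowLibrarySubset:
    def test_curve_has_expected_length(self):
        rng = np.random.default_rng(2)
        y = np.array(["normal"] * 20 + ["HCC"] * 20)
        t = nm.FeatureTable(
            pd.DataFrame(rng.normal(0, 1, (40, 160)),
                         columns=[f"c{j}" for j in range(160)]), y)
        ranked = pd.DataFrame({"column": list(t.features.columns),
                               "acc": np.zeros(160)})
        g = nm.grow_library_subset(ranked, t, start=30, step=10, folds=2,
                                   n_trees=4)
        assert len(g["curve"]) == 14  # 30, 40, ..., 160

    def test_start_beyond_ids_raises(self):
        t = _planted_table()
        ranked = pd.DataFrame({"column": list(t.features.columns),
                               "acc": np.zeros(8)})
        with pytest.raises(ValueError, match="exceeds"):
            nm.grow_library_subset(ranked, t, start=100)

    def test_flat_signal_gives_flat_curve(self):
        """Identically informative columns: curve flat within CV noise."""
        rng = np.random.default_rng(3)
        y = np.array(["normal"] * 60 + ["HCC"] * 60)
        cls = (y == "HCC").astype(float)
        base = rng.normal(0, 1, 120) + 2.0 * cls
        cols = {f"c{j}": base + rng.normal(0, 0.05, 120) for j in range(20)}
        t = nm.FeatureTable(pd.DataFrame(cols), y)
        ranked = nm.rank_library_nuclei(t, folds=5, seed=0, n_trees=20)
        g = nm.grow_library_subset(ranked, t, start=5, step=5, folds=5,
                                   seed=0, n_trees=50)
        assert g["curve"]["acc"].max() - g["curve"]["acc"].min() <= 0.05


@pytest.fixture(scope="module")
def bf_table():
    rng = np.random.default_rng(4)
    y = np.array(["normal"] * 30 + ["HCC"] * 30)
    cls = (y == "HCC").astype(float)
    cols = {}
    from itertools import combinations
    for (i, j, k) in combinations(range(12), 3):
        informative = {i, j, k} <= {0, 1, 2, 3}
        shift = 2.0 if informative else 0.0
        cols[f"bf.{i}.{j}.{k}"] = rng.normal(0, 1, 60) + shift * cls
    return nm.FeatureTable(pd.DataFrame(cols), y)


class TestBoundaryPointSelection:
    def test_select_top_counts(self, bf_table):
        ranked = list(range(12))
        assert nm.select_top_landmarks(bf_table, ranked, 8).features.shape[1] == 56
        assert nm.select_top_landmarks(bf_table, ranked, 12).features.shape[1] == 220
        assert nm.select_top_landmarks(bf_table, ranked, 5).features.shape[1] == 10
        with pytest.raises(ValueError):
            nm.select_top_landmarks(bf_table, ranked, 2)

    def test_informative_vertices_rank_first(self, bf_table):
        res = nm.rank_boundary_points(bf_table, k=12, folds=3, seed=0,
                                      n_trees=10, top_fraction=0.05)
        assert set(res["ranked_points"][:4]) == {0, 1, 2, 3}
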