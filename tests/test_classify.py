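import numpy as np
import pytest

from eegapm import (
    ConfusionTotals, FeatureMatrix, channel_contributions, crossval_10fold,
    feature_sweep, knn_baseline, metrics, train_ffnn,
)
from eegapm.nca import FeatureWeights


def blobs(n_per_class=50, sep=10.0, seed=0, p=2):
    rng = np.random.default_rng(seed)
    Xr = rng.standard_normal((n_per_class, p)) + sep
    Xn = rng.standard_normal((n_per_class, p))
    X = np.vstack([Xr, Xn])
    y = np.array(["R"] * n_per_class + ["NR"] * n_per_class)
    return X, y


class TestMetrics:
    def test_perfect_classifier(self):
        rep = metrics(ConfusionTotals(10, 10, 0, 0))
        assert (rep.acc, rep.sen, rep.spe) == (100.0, 100.0, 100.0)

    def test_hand_worked_counts(self):
        rep = metrics(ConfusionTotals(98, 97, 3, 2))
        assert rep.acc == pytest.approx(97.5)
        assert rep.sen == pytest.approx(98.0)
        assert rep.spe == pytest.approx(97.0)

    def test_all_negative_predictor(self):
        rep = metrics(ConfusionTotals(0, 10, 0, 10))
        assert (rep.acc, rep.sen, rep.spe) == (50.0, 0.0, 100.0)

    def test_undefined_sensitivity_is_nan_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            rep = metrics(ConfusionTotals(0, 10, 5, 0))
        assert np.isnan(rep.sen)
        assert any("SEN" in r.message for r in caplog.records)

    def test_empty_totals_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionTotals())

    def test_acc_identity_with_sen_spe(self):
        c = ConfusionTotals(40, 35, 15, 10)
        rep = metrics(c)
        n_pos, n_neg = c.ttp + c.tfn, c.ttn + c.tfp
        recon = (rep.sen * n_pos + rep.spe * n_neg) / c.total
        assert rep.acc == pytest.approx(recon)


class TestFFNN:
    def test_separable_blobs_learned_perfectly(self):
        X, y = blobs(sep=10.0, seed=1)
        model = train_ffnn(X, y, seed=1)
        assert (model.predict(X) == y).mean() == 1.0

    def test_xor_with_ten_hidden_units(self):
        rng = np.random.default_rng(3)
        corners = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        X = np.tile(corners, (25, 1)) + 0.05 * rng.standard_normal((100, 2))
        y = np.array(["NR", "R", "R", "NR"] * 25)
        model = train_ffnn(X, y, hidden_units=10, seed=3)
        assert (model.predict(X) == y).mean() >= 0.99

    def test_scores_row_normalized(self, rng):
        X, y = blobs(sep=2.0, seed=2)
        model = train_ffnn(X, y, seed=2)
        proba = model.predict_proba(rng.standard_normal((7, 2)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(ValueError):
            train_ffnn(rng.standard_normal((10, 2)), ["R"] * 10)


class TestCrossval:
    def test_partition_property_100_rows_10_folds(self):
        X, y = blobs(n_per_class=50, sep=10.0)
        totals = crossval_10fold(X, y, seed=0)
        assert totals.total == 100
        assert len(totals.per_fold) == 10
        assert all(sum(f.values()) == 10 for f in totals.per_fold)

    def test_separable_set_has_no_errors(self):
        X, y = blobs(n_per_class=50, sep=10.0)
        totals = crossval_10fold(X, y, seed=0)
        assert totals.tfp == 0 and totals.tfn == 0

    def test_label_permutation_gives_chance_accuracy(self):
        """With labels shuffled independently of iid features, pooled CV
        accuracy over 5 seeds averages near 50%."""
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((100, 5))
            y = rng.permutation(np.array(["R", "NR"] * 50))
            totals = crossval_10fold(X, y, seed=seed)
            accs.append(metrics(totals).acc)
        assert abs(np.mean(accs) - 50.0) <= 8.0

    def test_subject_grouping_keeps_subjects_intact(self):
        X, y = blobs(n_per_class=40, sep=3.0)
        subjects = np.array([f"s{i // 10}" for i in range(80)])
        totals = crossval_10fold(
            X, y, subject_ids=subjects, k_folds=4, grouping="subject", seed=0
        )
        assert totals.total == 80

    def test_fewer_rows_than_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            crossval_10fold(rng.standard_normal((5, 2)),
                            ["R", "NR", "R", "NR", "R"], k_folds=10)


class TestKNN:
    def test_nearest_training_point_decides(self):
        X = np.array([[0.0], [10.0]])
        y = np.array(["R", "NR"])
        from eegapm.classify import _knn_model

        model = _knn_model(X, y, k_neighbors=1)
        assert model.predict([[1.0]])[0] == "R"
        assert model.predict([[9.0]])[0] == "NR"

    def test_separable_blobs_perfect(self):
        X, y = blobs(n_per_class=30, sep=10.0)
        rep = knn_baseline(X, y, k_neighbors=3, k_folds=5)
        assert rep.acc == 100.0

    def test_tiny_instance_matches_exhaustive_distance_oracle(self):
        from eegapm.classify import _knn_model

        rng = np.random.default_rng(5)
        X = rng.standard_normal((8, 3))
        y = np.array(["R", "NR"] * 4)
        model = _knn_model(X, y, k_neighbors=1)
        # oracle in standardized space (the model standardizes internally)
        Xs = (X - X.mean(0)) / X.std(0)
        queries = rng.standard_normal((10, 3))
        qs = (queries - X.mean(0)) / X.std(0)
        for q_raw, q in zip(queries, qs):
            nearest = np.argmin(((Xs - q) ** 2).sum(axis=1))
            assert model.predict([q_raw])[0] == y[nearest]


class TestSweep:
    def weights_for(self, fm, order):
        p = fm.n_features
        w = np.zeros(p)
        w[np.array(order)] = np.linspace(1.0, 0.5, len(order))
        return FeatureWeights(
            w=w, ranking=np.array(order), lam=0.0, seed=0,
            feature_names=fm.feature_names,
        )

    def test_informative_top_features_help(self):
        rng = np.random.default_rng(4)
        n = 100
        y = np.array(["R", "NR"] * (n // 2))
        X = rng.standard_normal((n, 6))
        # three informative features, ranked on top
        for j in range(3):
            X[:, j] += 1.5 * (y == "R")
        fm = FeatureMatrix(X, [f"f{i}" for i in range(6)], y)
        w = self.weights_for(fm, [0, 1, 2, 3, 4, 5])
        sweep = feature_sweep(fm, w, [1, 3], k_folds=5, seed=0)
        assert sweep["acc"][1] >= sweep["acc"][0]

    def test_smallest_k_wins_ties(self):
        X, y = blobs(n_per_class=25, sep=10.0, p=4)
        fm = FeatureMatrix(X, [f"f{i}" for i in range(4)], y)
        w = self.weights_for(fm, [0, 1, 2, 3])
        sweep = feature_sweep(fm, w, [1, 2, 4], k_folds=5, seed=0)
        # all ks separate perfectly -> constant curve -> smallest k chosen
        assert len(set(sweep["acc"])) == 1
        assert sweep["best_k"] == 1

    def test_full_k_equals_plain_crossval(self):
        X, y = blobs(n_per_class=20, sep=2.0, p=4)
        fm = FeatureMatrix(X, [f"f{i}" for i in range(4)], y)
        w = self.weights_for(fm, [0, 1, 2, 3])
        sweep = feature_sweep(fm, w, [4], k_folds=5, seed=0)
        sub = fm.values[:, w.ranking[:4]]
        totals = crossval_10fold(sub, y, k_folds=5, seed=0)
        assert sweep["acc"][0] == metrics(totals).acc


class TestChannelContributions:
    def weights(self, names, w):
        order = np.lexsort((np.arange(len(w)), -np.asarray(w)))
        return FeatureWeights(
            w=np.asarray(w, float), ranking=order, lam=0.0, seed=0,
            feature_names=names,
        )

    def test_top5_in_one_channel(self):
        from eegapm import feature_names
        from eegapm.preprocess import CHANNELS_1020

        names = feature_names()
        w = np.zeros(608)
        fz_cols = [i for i, n in enumerate(names) if n.startswith("chFz_")]
        w[fz_cols[:5]] = [5, 4, 3, 2, 1]
        counts = channel_contributions(self.weights(names, w), k=5)
        assert counts == {"Fz": 5}

    def test_k_full_gives_32_per_channel(self):
        from eegapm import feature_names

        names = feature_names()
        counts = channel_contributions(
            self.weights(names, np.arange(608.0)), k=608
        )
        assert all(v == 32 for v in counts.values())
        assert len(counts) == 19

    def test_k1_one_channel_count_one(self):
        from eegapm import feature_names

        names = feature_names()
        counts = channel_contributions(
            self.weights(names, np.arange(608.0)), k=1
        )
        assert sum(counts.values()) == 1 and len(counts) == 1
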