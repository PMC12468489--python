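import numpy as np
import pytest

from eegapm import FeatureMatrix, nca_fit, select_top
from eegapm.nca import FeatureWeights, nca_gradient, nca_objective


def toy_matrix(values, labels, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    return FeatureMatrix(values, names, np.asarray(labels))


def objective_bruteforce(v, X, y, lam):
    """Direct double-loop evaluation of the regularized NCA objective."""
    n, p = X.shape
    w = np.asarray(v) ** 2
    F = 0.0
    for i in range(n):
        d = np.array([
            np.sum(w * np.abs(X[i] - X[k])) if k != i else np.inf
            for k in range(n)
        ])
        e = np.exp(-(d - d[np.isfinite(d)].min()))
        e[i] = 0.0
        pij = e / e.sum()
        F += sum(pij[j] for j in range(n) if j != i and y[j] == y[i])
    return F - lam * np.sum(w)


class TestObjective:
    def test_matches_bruteforce_on_6_points(self, rng):
        X = rng.standard_normal((6, 3))
        y = np.array(["R", "R", "R", "NR", "NR", "NR"])
        for _ in range(5):
            v = rng.standard_normal(3)
            fast = nca_objective(v, X, y, lam=0.2)
            slow = objective_bruteforce(v, X, y, lam=0.2)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.array(["R"] * 5 + ["NR"] * 5)
        v = rng.standard_normal(4)
        lam = 0.3
        g = nca_gradient(v, X, y, lam)
        h = 1e-6
        fd = np.empty(4)
        for f in range(4):
            vp, vm = v.copy(), v.copy()
            vp[f] += h
            vm[f] -= h
            fd[f] = (nca_objective(vp, X, y, lam)
                     - nca_objective(vm, X, y, lam)) / (2 * h)
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-4


class TestFit:
    def test_class_indicator_feature_dominates(self):
        rng = np.random.default_rng(7)
        y = np.array(["R"] * 20 + ["NR"] * 20)
        X = rng.standard_normal((40, 5))
        X[:, 0] = (y == "R").astype(float) + 0.01 * rng.standard_normal(40)
        w = nca_fit(toy_matrix(X, y), lam=0.5, seed=7)
        assert np.all(w.w[0] > w.w[1:])
        assert w.ranking[0] == 0

    def test_single_class_returns_near_zero_weights(self, rng, caplog):
        X = rng.standard_normal((20, 4))
        with caplog.at_level("WARNING"):
            w = nca_fit(toy_matrix(X, ["R"] * 20), lam=0.1, seed=0)
        assert w.w.max() < 1e-3
        assert any("single-class" in r.message for r in caplog.records)

    def test_weights_nonnegative_and_ranking_valid(self, rng):
        X = rng.standard_normal((30, 8))
        y = np.array(["R", "NR"] * 15)
        w = nca_fit(toy_matrix(X, y), seed=1)
        assert np.all(w.w >= 0)
        assert sorted(w.ranking.tolist()) == list(range(8))
        # ranking sorts weights in descending order
        assert np.all(np.diff(w.w[w.ranking]) <= 1e-15)

    def test_objective_nondecreasing_over_iterations(self, rng):
        X = rng.standard_normal((30, 6))
        y = np.array(["R", "NR"] * 15)
        w = nca_fit(toy_matrix(X, y), seed=3)
        hist = np.array(w.objective_history)
        assert len(hist) >= 2
        assert np.all(np.diff(hist) >= -1e-9)

    def test_duplicated_noise_feature_weight_symmetry(self):
        """A pure-noise feature and its exact copy get matching weights."""
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            y = np.array(["R"] * 15 + ["NR"] * 15)
            signal = (y == "R") + 0.1 * rng.standard_normal(30)
            noise = rng.standard_normal(30)
            X = np.column_stack([signal, noise, noise.copy()])
            w = nca_fit(toy_matrix(X, y), seed=seed)
            assert abs(w.w[1] - w.w[2]) < 1e-2, f"seed {seed}"

    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.standard_normal((20, 5))
        y = np.array(["R", "NR"] * 10)
        a = nca_fit(toy_matrix(X, y), seed=11)
        b = nca_fit(toy_matrix(X, y), seed=11)
        np.testing.assert_array_equal(a.w, b.w)

    def test_negative_lambda_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            nca_fit(toy_matrix(X, ["R", "NR"] * 5), lam=-1.0)


class TestSelectTop:
    def crafted(self):
        fm = toy_matrix(np.arange(12.0).reshape(4, 3), ["R", "NR"] * 2,
                        names=["a", "b", "c"])
        w = FeatureWeights(
            w=np.array([0.1, 0.9, 0.5]),
            ranking=np.array([1, 2, 0]),
            lam=0.0, seed=0, feature_names=["a", "b", "c"],
        )
        return fm, w

    def test_k2_picks_columns_in_rank_order(self):
        fm, w = self.crafted()
        out = select_top(fm, w, 2)
        assert out.feature_names == ["b", "c"]
        np.testing.assert_array_equal(out.values, fm.values[:, [1, 2]])

    def test_k_full_is_column_permutation(self):
        fm, w = self.crafted()
        out = select_top(fm, w, 3)
        assert sorted(out.feature_names) == ["a", "b", "c"]
        assert out.values.shape == fm.values.shape

    def test_k1_single_best_column(self):
        fm, w = self.crafted()
        out = select_top(fm, w, 1)
        assert out.feature_names == ["b"]

    def test_k_out_of_range_rejected(self):
        fm, w = self.crafted()
        for k in (0, 4):
            with pytest.raises(ValueError):
                select_top(fm, w, k)
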