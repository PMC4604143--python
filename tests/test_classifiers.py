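import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beatclass.classifiers import (
    ConditioningError,
    FuzzyPercentileClassifier,
    KMeansBeatClassifier,
    PooledLdaClassifier,
    TreeBeatClassifier,
    best_split,
    fuzzy_confidence,
    impurity,
    kmeans_fit,
    kmeans_predict,
    lda_fit,
    lda_predict,
    fuzzy_fit,
    fuzzy_predict,
    tree_grow,
    tree_predict,
    tree_prune,
    _encode_labels,
    _se_ppv,
)

SVB, VB = "SVB", "VB"


class TestImpurity:
    @pytest.mark.parametrize("criterion", ["deviance", "gini"])
    def test_pure_node_zero(self, criterion):
        assert impurity([1.0, 0.0], criterion, n=10) == 0.0

    def test_gini_values(self):
        assert impurity([0.5, 0.5], "gini") == pytest.approx(0.5)
        assert impurity([0.3, 0.7], "gini") == pytest.approx(0.42)

    def test_deviance_closed_form(self):
        # 2 * 10 * ln 2
        assert impurity([0.5, 0.5], "deviance", n=10) == pytest.approx(13.8629, abs=1e-4)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.integers(1, 500))
    def test_deviance_is_2n_entropy(self, p1, n):
        p = [p1, 1.0 - p1]
        nz = [q for q in p if q > 0]
        entropy = -sum(q * np.log(q) for q in nz)
        assert impurity(p, "deviance", n) == pytest.approx(2 * n * entropy, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0))
    def test_two_class_gini_identity(self, p1):
        # 1 - p1^2 - p2^2 == 2 p1 (1 - p1): Gini as second-order entropy
        assert impurity([p1, 1 - p1], "gini") == pytest.approx(2 * p1 * (1 - p1), abs=1e-12)

    def test_invalid_proportions(self):
        with pytest.raises(ValueError):
            impurity([0.6, 0.6], "gini")


def exhaustive_split_oracle(X, y, criterion, priors=(0.5, 0.5)):
    """Brute-force best split: every feature, every midpoint, direct impurity."""
    y01 = _encode_labels(y)
    totals = np.bincount(y01, minlength=2).astype(float)
    w = np.asarray(priors) / np.maximum(totals, 1.0)

    def node_terms(mask):
        m0 = w[0] * np.sum(y01[mask] == 0)
        m1 = w[1] * np.sum(y01[mask] == 1)
        m = m0 + m1
        if m == 0:
            return 0.0, 0.0, np.array([0.5, 0.5])
        return m, m0, np.array([m0 / m, m1 / m])

    m_p, _, p_parent = node_terms(np.ones(len(y01), bool))
    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2
            left = X[:, f] < thr
            mL, _, pL = node_terms(left)
            mR, _, pR = node_terms(~left)
            if criterion == "twoing":
                g = (mL / m_p) * (mR / m_p) / 4 * (
                    abs(pL[0] - pR[0]) + abs(pL[1] - pR[1])
                ) ** 2
            elif criterion == "gini":
                g = (impurity(p_parent, "gini")
                     - mL / m_p * impurity(pL, "gini")
                     - mR / m_p * impurity(pR, "gini"))
            else:
                g = (impurity(p_parent, "deviance", 1) * m_p
                     - impurity(pL, "deviance", 1) * mL
                     - impurity(pR, "deviance", 1) * mR)
            key = (g, -f, -thr)
            if best is None or key > best[0]:
                best = (key, f, thr, g)
    if best is None:
        return None
    return best[1], best[2], best[3]


class TestBestSplit:
    def test_separable_1d(self):
        X = np.array([[1.0], [2.0], [5.0], [6.0]])
        y = [SVB, SVB, VB, VB]
        f, thr, _ = best_split(X, y)
        assert f == 0 and thr == pytest.approx(3.5)

    def test_identical_rows_no_split(self):
        X = np.ones((6, 2))
        assert best_split(X, [SVB, VB] * 3) is None

    def test_twoing_separated_value(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = [SVB, SVB, VB, VB]
        f, thr, g = best_split(X, y, criterion="twoing")
        assert g == pytest.approx(0.25)  # (0.25/4) * (1+1)^2

    @pytest.mark.parametrize("criterion", ["deviance", "gini", "twoing"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_oracle(self, criterion, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        X = rng.integers(0, 6, size=(n, 3)).astype(float)
        y = np.where(rng.random(n) < 0.5, SVB, VB)
        if len(np.unique(_encode_labels(y))) < 2:
            y[0] = SVB if y[0] == VB else VB
        ours = best_split(X, y, criterion=criterion)
        oracle = exhaustive_split_oracle(X, y, criterion)
        if ours is None:
            assert oracle is None or oracle[2] <= 1e-12
        else:
            assert ours[0] == oracle[0]
            assert ours[1] == pytest.approx(oracle[1])
            assert ours[2] == pytest.approx(oracle[2], abs=1e-9)

    def test_sklearn_entropy_tree_agrees_at_root(self):
        # independent oracle: sklearn's entropy-criterion root split
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(5)
        X = rng.normal(size=(120, 4))
        y01 = (X[:, 2] + 0.3 * rng.normal(size=120) > 0).astype(int)
        y = np.where(y01 == 1, VB, SVB)
        f, thr, _ = best_split(X, y, criterion="deviance")
        sk = DecisionTreeClassifier(criterion="entropy", max_depth=1, random_state=0)
        sk.fit(X, y01)
        assert f == sk.tree_.feature[0]
        assert thr == pytest.approx(sk.tree_.threshold[0], abs=1e-7)


class TestTree:
    def test_pure_set_single_leaf(self):
        X = np.arange(12.0).reshape(-1, 1)
        tree = tree_grow(X, [SVB] * 12)
        assert tree.n_decision_nodes == 0
        assert tree_predict(tree, np.array([3.0])) == SVB

    def test_separable_depth_one(self):
        X = np.r_[np.linspace(0, 2, 10), np.linspace(5, 7, 10)].reshape(-1, 1)
        y = [SVB] * 10 + [VB] * 10
        tree = tree_grow(X, y)
        assert tree.n_decision_nodes == 1
        assert tree_predict(tree, np.array([1.5])) == SVB
        assert tree_predict(tree, np.array([5.5])) == VB
        assert np.all(tree_predict(tree, X) == np.array(y))

    def test_xor_pattern_solved(self):
        corners = [(0, 0, SVB), (1, 1, SVB), (0, 1, VB), (1, 0, VB)]
        X, y = [], []
        for cx, cy, lab in corners:
            X += [(cx, cy)] * 12
            y += [lab] * 12
        X = np.asarray(X, dtype=float)
        tree = tree_grow(X, y)
        assert tree.n_decision_nodes >= 3
        assert np.all(tree_predict(tree, X) == np.array(y))

    def test_resubstitution_pure_leaves(self, small_table):
        X, y, _ = small_table
        sub = slice(0, 200)
        tree = tree_grow(X[sub, :30], y[sub], min_impure=2)
        assert np.mean(tree_predict(tree, X[sub, :30]) == y[sub]) == 1.0


class TestPruning:
    def _fixture_tree(self, rng):
        X = rng.normal(size=(200, 3))
        score = X[:, 0] + 0.5 * X[:, 1] + 0.3 * rng.normal(size=200)
        y = np.where(score > 0, VB, SVB)
        return tree_grow(X, y, min_impure=10), X, y

    def test_terminal_cases(self, rng):
        tree, X, y = self._fixture_tree(rng)
        one = tree_prune(tree, 1)
        assert one.n_decision_nodes == 1
        stump = tree_prune(tree, 0)
        assert stump.n_decision_nodes == 0
        # root proportions are prior-reweighted: with equal priors the root
        # is an exact tie regardless of counts, and ties resolve to VB
        preds = {tree_predict(stump, x) for x in X[:10]}
        assert preds == {"VB"}

    def test_error_nondecreasing_along_sequence(self, rng):
        tree, X, y = self._fixture_tree(rng)
        y01 = _encode_labels(y)
        errors = []
        for target in range(tree.n_decision_nodes, -1, -1):
            pruned = tree_prune(tree, target)
            errors.append(np.mean(pruned.predict01(X) != y01))
        assert all(b >= a - 1e-12 for a, b in zip(errors, errors[1:]))

    def test_first_prune_is_min_error_increase(self, rng):
        tree, X, y = self._fixture_tree(rng)
        full = tree.n_decision_nodes
        pruned = tree_prune(tree, full - 1)
        chosen = pruned.prune_sequence[0]["node"]

        # brute force: collapse each internal node in turn, measure error
        y01 = _encode_labels(y)
        base_err = np.sum(tree.predict01(X) != y01)
        increases = {}
        for i in range(len(tree.nodes)):
            if tree.nodes[i].is_leaf or i not in tree._live_nodes():
                continue
            trial = tree_prune(tree, full)  # deep copy, no pruning
            nd = trial.nodes[i]
            nd.feature = nd.threshold = nd.left = nd.right = None
            increases[i] = np.sum(trial.predict01(X) != y01) - base_err
        assert increases[chosen] == min(increases.values())

    def test_prune_preserves_predictions_at_full_size(self, rng):
        tree, X, y = self._fixture_tree(rng)
        same = tree_prune(tree, tree.n_decision_nodes)
        assert np.array_equal(same.predict01(X), tree.predict01(X))


class TestKMeans:
    def test_two_points_two_clusters(self):
        X = np.array([[0.0], [10.0]])
        model = kmeans_fit(X, [SVB, VB], k=2, seed=0)
        assert sorted(model.centroids_.ravel()) == [0.0, 10.0]

    def test_two_blob_centroids_vs_all_partitions(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = [SVB, SVB, VB, VB]
        model = kmeans_fit(X, y, k=2, seed=0)
        assert sorted(model.centroids_.ravel()) == [0.5, 10.5]
        # all-partitions oracle: the kept solution's criterion is maximal
        y01 = _encode_labels(y)
        best_crit = -1.0
        for assign in itertools.product([0, 1], repeat=4):
            if len(set(assign)) < 2:
                continue
            assign = np.array(assign)
            labels = np.zeros(2, dtype=int)
            for j in (0, 1):
                members = assign == j
                labels[j] = 1 if np.sum(y01[members]) * 2 >= members.sum() else 0
            se, ppv = _se_ppv(y01, labels[assign])
            if se is not None and ppv is not None:
                best_crit = max(best_crit, (se + ppv) / 2)
        assert model.replicate_score_ == pytest.approx(best_crit)

    def test_majority_labeling(self):
        X = np.array([[0.0], [0.1], [0.2], [0.3], [9.0]])
        y = [SVB, SVB, SVB, VB, VB]
        model = kmeans_fit(X, y, k=2, seed=0)
        assert kmeans_predict(model, np.array([0.15])) == SVB
        assert kmeans_predict(model, np.array([8.0])) == VB

    def test_k_exceeding_distinct_rows_rejected(self):
        X = np.array([[1.0], [1.0], [2.0]])
        with pytest.raises(ValueError):
            kmeans_fit(X, [SVB, SVB, VB], k=3)

    def test_nearest_centroid_prediction_bruteforce(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.where(rng.random(40) < 0.5, SVB, VB)
        model = kmeans_fit(X, y, k=4, seed=1)
        probes = rng.normal(size=(5, 3))
        for x in probes:
            d = np.linalg.norm(model.centroids_ - x, axis=1)
            expected = model.centroid_labels_[int(np.argmin(d))]
            assert kmeans_predict(model, x) == ("VB" if expected == 1 else "SVB")

    def test_replicate_determinism(self, small_table):
        X, y, _ = small_table
        a = KMeansBeatClassifier(k=3, random_state=5).fit(X[:, [116]], y)
        b = KMeansBeatClassifier(k=3, random_state=5).fit(X[:, [116]], y)
        assert np.array_equal(a.centroids_, b.centroids_)

    def test_json_round_trip(self, small_table):
        X, y, _ = small_table
        model = KMeansBeatClassifier(k=3, random_state=0).fit(X[:, :5], y)
        back = KMeansBeatClassifier.from_json(model.to_json())
        assert back.to_json() == model.to_json()
        assert np.array_equal(back.predict(X[:20, :5]), model.predict(X[:20, :5]))


class TestFuzzy:
    def test_median_confidence_is_one(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0], [20.0], [30.0]])
        y = [SVB] * 3 + [VB] * 3
        model = fuzzy_fit(X, y)
        assert fuzzy_confidence(model, 0, 2.0, SVB) == pytest.approx(1.0)
        assert fuzzy_confidence(model, 0, 20.0, VB) == pytest.approx(1.0)

    def test_below_minimum_zero(self):
        X = np.array([[1.0], [2.0], [3.0], [10.0], [20.0], [30.0]])
        model = fuzzy_fit(X, [SVB] * 3 + [VB] * 3)
        assert fuzzy_confidence(model, 0, 0.0, SVB) == 0.0

    def test_75th_percentile_half(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [100.0], [100.0]])
        model = fuzzy_fit(X, [SVB] * 4 + [VB] * 2)
        # x between 3rd and 4th of 4 values: F = 0.75 -> 1 - |2*0.75-1| = 0.5
        assert fuzzy_confidence(model, 0, 3.5, SVB) == pytest.approx(0.5)

    def test_extreme_constructions(self):
        rngv = np.random.default_rng(0)
        svb = rngv.normal(0, 1, size=(50, 2))
        vb = rngv.normal(100, 1, size=(50, 2))
        X = np.vstack([svb, vb])
        y = [SVB] * 50 + [VB] * 50
        model = fuzzy_fit(X, y)
        assert fuzzy_predict(model, np.median(svb, axis=0)) == SVB
        assert fuzzy_predict(model, np.median(vb, axis=0)) == VB

    def test_two_feature_hand_computed_average(self):
        X = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0],
                      [4.0, 40.0], [5.0, 50.0], [6.0, 60.0]])
        y = [SVB] * 3 + [VB] * 3
        model = fuzzy_fit(X, y)
        x = np.array([2.5, 50.0])
        # SVB: F(2.5 | {1,2,3}) = 2/3 -> conf 2/3; F(50 | {10,20,30}) = 1 -> 0
        # VB:  F(2.5 | {4,5,6}) = 0 -> 0;     F(50 | {40,50,60}) = 1/2 -> 1
        conf = model.mean_confidences(x[None, :])
        assert conf[0, 0] == pytest.approx((2 / 3 + 0.0) / 2)
        assert conf[1, 0] == pytest.approx((0.0 + 1.0) / 2)
        assert fuzzy_predict(model, x) == VB  # larger mean confidence

    def test_json_round_trip(self, small_table):
        X, y, _ = small_table
        model = fuzzy_fit(X[:, :4], y)
        back = FuzzyPercentileClassifier.from_json(model.to_json())
        assert back.to_json() == model.to_json()
        assert np.array_equal(back.predict(X[:30, :4]), model.predict(X[:30, :4]))


class TestLda:
    def _one_d_model(self, priors=(0.5, 0.5)):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 400)
        b = rng.normal(2.0, 1.0, 400)
        a = (a - a.mean()) / a.std(ddof=1)         # exact mu1=0, var 1
        b = 2.0 + (b - b.mean()) / b.std(ddof=1)   # exact mu2=2, var 1
        X = np.r_[a, b][:, None]
        y = [SVB] * 400 + [VB] * 400
        return lda_fit(X, y, priors=priors)

    def test_separated_data_aper_zero(self):
        X = np.r_[np.linspace(0, 1, 20), np.linspace(10, 11, 20)][:, None]
        model = lda_fit(X, [SVB] * 20 + [VB] * 20, priors=(0.5, 0.5))
        assert model.aper_ == 0.0

    def test_one_d_coefficient(self):
        model = self._one_d_model()
        assert model.a_hat_[0] == pytest.approx(-2.0, abs=1e-9)

    def test_equal_prior_decision(self):
        model = self._one_d_model(priors=(0.5, 0.5))
        # y = 0.5: lambda = (0.5 - 1) * (-2) = 1 > 0 -> SVB (class 1)
        assert lda_predict(model, np.array([0.5])) == SVB
        # midpoint: lambda = 0, equality -> class 2 (VB)
        assert lda_predict(model, np.array([1.0])) == VB

    def test_prior_threshold_flips_decision(self):
        model = self._one_d_model(priors=(0.3, 0.7))
        # ln(7/3) ~ 0.847: lambda(0.5) = 1 > 0.847 -> SVB;
        # lambda(0.6) = 0.8 < 0.847 -> VB
        assert lda_predict(model, np.array([0.5])) == SVB
        assert lda_predict(model, np.array([0.6])) == VB

    def test_collinear_columns_raise_conditioning_error(self, rng):
        col = rng.normal(size=100)
        X = np.c_[col, col]
        y = np.where(rng.random(100) < 0.5, SVB, VB)
        with pytest.raises(ConditioningError):
            lda_fit(X, y)

    def test_boundary_recovery_two_gaussians(self):
        # empirical boundary of a symmetric 1-D problem sits at the
        # midpoint of the class means, within 3 standard errors
        rng = np.random.default_rng(3)
        n = 2000
        a = rng.normal(0.0, 1.0, n)
        b = rng.normal(2.0, 1.0, n)
        model = lda_fit(np.r_[a, b][:, None], [SVB] * n + [VB] * n,
                        priors=(0.5, 0.5))
        # boundary: lambda(y) = 0 -> y* = (mu1 + mu2)/2
        boundary = 0.5 * (model.mu1_[0] + model.mu2_[0])
        se = 1.0 / np.sqrt(n)  # std error of each mean estimate
        assert abs(boundary - 1.0) < 3 * se * np.sqrt(2)

    def test_sklearn_agreement(self, rng):
        # independent oracle: sklearn's LDA with the same priors
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack([rng.normal(0, 1, (500, 3)), rng.normal(1.5, 1, (500, 3))])
        y = np.array([SVB] * 500 + [VB] * 500)
        ours = lda_fit(X, y, priors=(0.3, 0.7))
        sk = LinearDiscriminantAnalysis(priors=[0.3, 0.7]).fit(X, y)
        agree = np.mean(ours.predict(X) == sk.predict(X))
        assert agree >= 0.99

    def test_json_round_trip(self, small_table):
        X, y, _ = small_table
        model = lda_fit(X[:, [5, 17, 116]], y)
        back = PooledLdaClassifier.from_json(model.to_json())
        assert back.to_json() == model.to_json()
        assert np.array_equal(back.predict(X[:40, [5, 17, 116]]),
                              model.predict(X[:40, [5, 17, 116]]))


class TestPredictorPurity:
    def test_all_predictors_deterministic(self, small_table):
        X, y, _ = small_table
        cols = [5, 17, 116]
        models = [
            kmeans_fit(X[:, cols], y, k=3, seed=0),
            fuzzy_fit(X[:, cols], y),
            lda_fit(X[:, cols], y),
            TreeBeatClassifier().fit(X[:, cols], y),
        ]
        for m in models:
            a = m.predict(X[:50, cols])
            b = m.predict(X[:50, cols])
            assert np.array_equal(a, b)
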