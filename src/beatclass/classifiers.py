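"""Second-stage SVB/VB classifiers.

Four trainable binary classifiers decide the beats Stage 1 did not
fast-track: a k-means cluster model with nearest-centroid prediction, a
fuzzy classifier scoring percentile rank in the class-conditional feature
distributions, linear discriminant analysis with a pooled covariance and
class priors, and a classification tree with deviance / Gini / twoing
splitting and misclassification-cost pruning.  All four are implemented
here directly (they are the point of the package) as scikit-learn-style
estimators; module-level ``*_fit`` / ``*_predict`` functions are thin
wrappers.  Class conventions throughout: class 1 = SVB (negative), class
2 = VB (positive); label ties resolve to VB, favouring ventricular
sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

CLASSES = np.array(["SVB", "VB"])
#: reciprocal-condition floor below which a pooled covariance is "badly scaled"
RCOND_FLOOR = 1e-12


class ConditioningError(ValueError):
    """Pooled covariance is singular or badly scaled (rcond < 1e-12)."""


def _encode_labels(y) -> np.ndarray:
    y = np.asarray(y)
    out = np.empty(len(y), dtype=int)
    svb = (y == "SVB") | (y == 0)
    vb = (y == "VB") | (y == 1)
    if not np.all(svb | vb):
        raise ValueError("labels must be 'SVB'/'VB' (or 0/1)")
    out[svb] = 0
    out[vb] = 1
    return out


def _validate_X(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X


def _se_ppv(y_true01: np.ndarray, y_pred01: np.ndarray) -> tuple[float | None, float | None]:
    """Resubstitution sensitivity and positive predictivity, VB positive."""
    tp = int(np.sum((y_true01 == 1) & (y_pred01 == 1)))
    fn = int(np.sum((y_true01 == 1) & (y_pred01 == 0)))
    fp = int(np.sum((y_true01 == 0) & (y_pred01 == 1)))
    se = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    return se, ppv


# ===========================================================================
# Classification tree


def impurity(p, criterion: str = "deviance", n: int = 1) -> float:
    """Node impurity for a class-proportion vector.

    deviance: i_D = 2n * (-sum p_j ln p_j), with 0*ln(0) = 0 (natural log,
    so i_D = 2n * entropy); gini: 1 - sum p_j^2. The twoing rule is a
    property of a split, not a node — see ``best_split``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be nonnegative and sum to 1")
    if n < 1:
        raise ValueError("node size must be >= 1")
    if criterion == "deviance":
        nz = p[p > 0]
        return float(2.0 * n * -np.sum(nz * np.log(nz)))
    if criterion == "gini":
        return float(1.0 - np.sum(p**2))
    raise ValueError(f"unknown criterion {criterion!r}")


def _class_weights(priors, class_totals) -> np.ndarray:
    """Per-row weight that rescales the root class masses to the priors."""
    totals = np.maximum(np.asarray(class_totals, dtype=float), 1.0)
    return np.asarray(priors, dtype=float) / totals


def best_split(
    X,
    y,
    criterion: str = "deviance",
    priors=(0.5, 0.5),
    class_totals=None,
):
    """Exhaustive best univariate split of a node.

    Candidates are the midpoints between adjacent distinct sorted values of
    every feature. Class proportions are prior-reweighted against
    ``class_totals`` (the root class counts; defaults to this node's own).
    Deviance/Gini maximize the impurity decrease (parent minus size-
    weighted children); twoing maximizes
    i_T = (p_L p_R / 4) (sum_j |p_jL - p_jR|)^2.
    Ties break to the lowest feature index, then the lowest threshold.
    Returns (feature, threshold, goodness) or None when no split exists.
    """
    X = _validate_X(X)
    y01 = _encode_labels(y)
    if class_totals is None:
        class_totals = np.bincount(y01, minlength=2)
    w = _class_weights(priors, class_totals)
    rw = w[y01]  # per-row weight
    n0 = float(np.sum(rw[y01 == 0]))
    n1 = float(np.sum(rw[y01 == 1]))
    m_parent = n0 + n1
    if m_parent <= 0 or min(np.bincount(y01, minlength=2)) == 0:
        return None

    best = None  # (goodness, feature, threshold)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        xs = col[order]
        ws = rw[order]
        w1 = np.where(y01[order] == 1, ws, 0.0)
        cuts = np.nonzero(xs[:-1] < xs[1:])[0]
        if cuts.size == 0:
            continue
        cum_w = np.cumsum(ws)
        cum_w1 = np.cumsum(w1)
        mL = cum_w[cuts]
        m1L = cum_w1[cuts]
        m0L = mL - m1L
        mR = m_parent - mL
        m1R = n1 - m1L
        m0R = n0 - m0L
        thresholds = (xs[cuts] + xs[cuts + 1]) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            if criterion == "twoing":
                pL = mL / m_parent
                pR = mR / m_parent
                d0 = np.abs(m0L / mL - m0R / mR)
                d1 = np.abs(m1L / mL - m1R / mR)
                goodness = pL * pR / 4.0 * (d0 + d1) ** 2
            elif criterion == "gini":
                gL = 1.0 - (m0L / mL) ** 2 - (m1L / mL) ** 2
                gR = 1.0 - (m0R / mR) ** 2 - (m1R / mR) ** 2
                p0, p1 = n0 / m_parent, n1 / m_parent
                g_parent = 1.0 - p0**2 - p1**2
                goodness = g_parent - (mL / m_parent) * gL - (mR / m_parent) * gR
            elif criterion == "deviance":
                def dev(m0, m1, m):
                    out = np.zeros_like(m)
                    for mc in (m0, m1):
                        frac = np.where(mc > 0, mc / m, 1.0)
                        out -= 2.0 * mc * np.log(frac)
                    return out
                parent = float(dev(np.array([n0]), np.array([n1]), np.array([m_parent]))[0])
                goodness = parent - dev(m0L, m1L, mL) - dev(m0R, m1R, mR)
            else:
                raise ValueError(f"unknown criterion {criterion!r}")
        k = int(np.argmax(goodness))  # first max -> lowest threshold
        g = float(goodness[k])
        if best is None or g > best[0] + 1e-12:
            best = (g, j, float(thresholds[k]))
    if best is None:
        return None
    return best[1], best[2], best[0]


@dataclass
class TreeNode:
    counts: np.ndarray              # raw class counts of training rows here
    proportions: np.ndarray         # prior-reweighted class proportions
    predicted: int                  # 0 = SVB, 1 = VB
    feature: int | None = None
    threshold: float | None = None
    left: int | None = None
    right: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class TreeModel:
    nodes: list[TreeNode]
    criterion: str
    priors: tuple[float, float]
    min_impure: int
    class_totals: np.ndarray
    prune_sequence: list[dict] = field(default_factory=list)

    @property
    def n_decision_nodes(self) -> int:
        return sum(1 for i in self._live_nodes() if not self.nodes[i].is_leaf)

    def _live_nodes(self) -> list[int]:
        live = []
        stack = [0]
        while stack:
            i = stack.pop()
            live.append(i)
            nd = self.nodes[i]
            if not nd.is_leaf:
                stack.extend([nd.left, nd.right])
        return live

    def predict01(self, X) -> np.ndarray:
        X = _validate_X(X)
        out = np.empty(len(X), dtype=int)
        for r, x in enumerate(X):
            i = 0
            while not self.nodes[i].is_leaf:
                nd = self.nodes[i]
                i = nd.left if x[nd.feature] < nd.threshold else nd.right
            out[r] = self.nodes[i].predicted
        return out

    def to_json(self) -> str:
        doc = {
            "version": 1,
            "criterion": self.criterion,
            "priors": list(self.priors),
            "min_impure": self.min_impure,
            "class_totals": self.class_totals.tolist(),
            "nodes": [
                {
                    "counts": nd.counts.tolist(),
                    "proportions": nd.proportions.tolist(),
                    "predicted": nd.predicted,
                    "feature": nd.feature,
                    "threshold": nd.threshold,
                    "left": nd.left,
                    "right": nd.right,
                }
                for nd in self.nodes
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        doc = json.loads(text)
        nodes = [
            TreeNode(
                counts=np.asarray(nd["counts"]),
                proportions=np.asarray(nd["proportions"]),
                predicted=nd["predicted"], feature=nd["feature"],
                threshold=nd["threshold"], left=nd["left"], right=nd["right"],
            )
            for nd in doc["nodes"]
        ]
        return cls(nodes=nodes, criterion=doc["criterion"],
                   priors=tuple(doc["priors"]), min_impure=doc["min_impure"],
                   class_totals=np.asarray(doc["class_totals"]))


def _node_proportions(counts, priors, class_totals) -> np.ndarray:
    w = _class_weights(priors, class_totals)
    mass = w * counts
    total = mass.sum()
    return mass / total if total > 0 else np.array([0.5, 0.5])


def _predicted_class(proportions) -> int:
    # tie -> VB (index 1)
    return 1 if proportions[1] >= proportions[0] else 0


def tree_grow(
    X, y, criterion: str = "deviance", priors=(0.5, 0.5), min_impure: int = 10
) -> TreeModel:
    """Grow a binary classification tree by recursive exhaustive splitting.

    A node is terminal when it is pure, has fewer than ``min_impure`` rows,
    or admits no split (all rows identical). Node class is the majority
    under prior-reweighted proportions.
    """
    X = _validate_X(X)
    y01 = _encode_labels(y)
    if len(X) < 1:
        raise ValueError("need at least one training row")
    class_totals = np.bincount(y01, minlength=2)
    model = TreeModel(nodes=[], criterion=criterion, priors=tuple(priors),
                      min_impure=min_impure, class_totals=class_totals)

    def build(rows: np.ndarray) -> int:
        counts = np.bincount(y01[rows], minlength=2)
        props = _node_proportions(counts, priors, class_totals)
        idx = len(model.nodes)
        node = TreeNode(counts=counts, proportions=props,
                        predicted=_predicted_class(props))
        model.nodes.append(node)
        pure = counts[0] == 0 or counts[1] == 0
        if pure or len(rows) < min_impure:
            return idx
        split = best_split(X[rows], y01[rows], criterion=criterion,
                           priors=priors, class_totals=class_totals)
        if split is None:
            return idx
        feat, thr, _ = split
        mask = X[rows, feat] < thr
        node.feature = feat
        node.threshold = thr
        node.left = build(rows[mask])
        node.right = build(rows[~mask])
        return idx

    build(np.arange(len(X)))
    return model


def _subtree_error(model: TreeModel, i: int) -> float:
    """Resubstitution misclassifications in the subtree rooted at i."""
    nd = model.nodes[i]
    if nd.is_leaf:
        return float(nd.counts.sum() - nd.counts[nd.predicted])
    return _subtree_error(model, nd.left) + _subtree_error(model, nd.right)


def tree_prune(tree: TreeModel, target_decision_nodes: int) -> TreeModel:
    """Prune to at most ``target_decision_nodes`` internal (split) nodes.

    Iteratively collapses the internal node whose removal least increases
    the resubstitution misclassification count (MCE rule); ties break to
    the shallowest/first-created node. The returned tree carries the full
    prune sequence (collapsed node, error increment).
    """
    model = TreeModel.from_json(tree.to_json())  # deep copy
    model.prune_sequence = list(tree.prune_sequence)
    if target_decision_nodes < 0:
        raise ValueError("target must be >= 0")

    def internal_ids() -> list[int]:
        return sorted(i for i in model._live_nodes() if not model.nodes[i].is_leaf)

    while len(internal_ids()) > target_decision_nodes:
        candidates = internal_ids()
        best_i, best_inc = None, None
        for i in candidates:
            nd = model.nodes[i]
            leaf_err = float(nd.counts.sum() - nd.counts[nd.predicted])
            inc = leaf_err - _subtree_error(model, i)
            if best_inc is None or inc < best_inc - 1e-12:
                best_i, best_inc = i, inc
        nd = model.nodes[best_i]
        nd.feature = None
        nd.threshold = None
        nd.left = None
        nd.right = None
        model.prune_sequence.append(
            {"node": best_i, "error_increase": best_inc}
        )
    return model


def tree_predict(tree: TreeModel, x) -> np.ndarray | str:
    """Root-to-leaf descent: go left iff x[feature] < threshold."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pred = tree.predict01(x)
    labels = CLASSES[pred]
    return labels[0] if single else labels


class TreeBeatClassifier(ClassifierMixin, BaseEstimator):
    """Classification tree over the expanded feature vector.

    Parameters
    ----------
    criterion : {"deviance", "gini", "twoing"}
        Split-selection rule. Deviance (= 2n * entropy, natural log) is the
        default, suited to large samples.
    priors : (float, float)
        (SVB, VB) prior probabilities; reweight the class proportions in
        every node during growth (growth only, not pruning).
    min_impure : int
        Minimum size of an impure node to be split.
    prune_to : int or None
        If set, prune the grown tree down to this many decision (split)
        nodes.
    """

    def __init__(self, criterion: str = "deviance", priors=(0.5, 0.5),
                 min_impure: int = 10, prune_to: int | None = None):
        self.criterion = criterion
        self.priors = priors
        self.min_impure = min_impure
        self.prune_to = prune_to

    def fit(self, X, y):
        self.tree_ = tree_grow(X, y, criterion=self.criterion,
                               priors=self.priors, min_impure=self.min_impure)
        if self.prune_to is not None:
            self.tree_ = tree_prune(self.tree_, self.prune_to)
        self.classes_ = CLASSES.copy()
        self.n_features_in_ = _validate_X(X).shape[1]
        self.n_decision_nodes_ = len(
            [i for i in self.tree_._live_nodes() if not self.tree_.nodes[i].is_leaf]
        )
        return self

    def predict(self, X):
        return CLASSES[self.tree_.predict01(X)]

    def to_json(self) -> str:
        return json.dumps({"version": 1, "kind": "tree",
                           "tree": json.loads(self.tree_.to_json())})

    @classmethod
    def from_json(cls, text: str) -> "TreeBeatClassifier":
        doc = json.loads(text)
        tree = TreeModel.from_json(json.dumps(doc["tree"]))
        clf = cls(criterion=tree.criterion, priors=tuple(tree.priors),
                  min_impure=tree.min_impure)
        clf.tree_ = tree
        clf.classes_ = CLASSES.copy()
        return clf


# ===========================================================================
# k-means cluster classifier


class KMeansBeatClassifier(ClassifierMixin, BaseEstimator):
    """k-means clustering with nearest-centroid classification.

    Lloyd iterations from k randomly chosen distinct rows, repeated for
    ``replicates`` starts; the kept replicate maximizes the training
    criterion (Mean(Se,PPV), then Se). Each cluster is labeled by its
    majority beat class (tie -> VB); prediction returns the label of the
    nearest centroid (Euclidean distance, tie -> lowest centroid index).
    """

    def __init__(self, k: int = 2, replicates: int = 10,
                 max_iter: int = 100, random_state: int | None = 0):
        self.k = k
        self.replicates = replicates
        self.max_iter = max_iter
        self.random_state = random_state

    def _lloyd(self, X: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        assign = np.full(len(X), -1)
        for _ in range(self.max_iter):
            d = np.linalg.norm(X[:, None, :] - centroids[None, :, :], axis=2)
            new_assign = np.argmin(d, axis=1)
            for j in range(self.k):
                members = new_assign == j
                if not np.any(members):
                    # re-seed an empty cluster to the farthest row
                    far = int(np.argmax(np.min(d, axis=1)))
                    centroids[j] = X[far]
                    new_assign[far] = j
                    members = new_assign == j
                centroids[j] = X[members].mean(axis=0)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
        return centroids, assign

    def fit(self, X, y):
        X = _validate_X(X)
        y01 = _encode_labels(y)
        unique_rows = np.unique(X, axis=0)
        if self.k > len(unique_rows):
            raise ValueError(f"k={self.k} exceeds {len(unique_rows)} distinct rows")
        rng = np.random.default_rng(self.random_state)
        best = None  # (crit, se, centroids, labels, assign)
        for _ in range(self.replicates):
            seed_idx = rng.choice(len(unique_rows), size=self.k, replace=False)
            centroids, assign = self._lloyd(X, unique_rows[seed_idx].astype(float).copy())
            labels = np.empty(self.k, dtype=int)
            for j in range(self.k):
                members = assign == j
                n_svb = int(np.sum(y01[members] == 0))
                n_vb = int(np.sum(y01[members] == 1))
                labels[j] = 1 if n_vb >= n_svb else 0
            pred = labels[assign]
            se, ppv = _se_ppv(y01, pred)
            crit = (se + ppv) / 2.0 if se is not None and ppv is not None else -1.0
            key = (crit, se if se is not None else -1.0)
            if best is None or key > best[0]:
                best = (key, centroids, labels)
        (crit, _se), centroids, labels = best
        self.centroids_ = centroids
        self.centroid_labels_ = labels
        self.replicate_score_ = crit
        self.classes_ = CLASSES.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        X = _validate_X(X)
        d = np.linalg.norm(X[:, None, :] - self.centroids_[None, :, :], axis=2)
        nearest = np.argmin(d, axis=1)  # first min -> lowest index on ties
        return CLASSES[self.centroid_labels_[nearest]]

    def to_json(self) -> str:
        return json.dumps({
            "version": 1, "kind": "kmeans", "k": self.k,
            "centroids": self.centroids_.tolist(),
            "centroid_labels": self.centroid_labels_.tolist(),
            "replicate_score": self.replicate_score_,
        })

    @classmethod
    def from_json(cls, text: str) -> "KMeansBeatClassifier":
        doc = json.loads(text)
        clf = cls(k=doc["k"])
        clf.centroids_ = np.asarray(doc["centroids"])
        clf.centroid_labels_ = np.asarray(doc["centroid_labels"])
        clf.replicate_score_ = doc["replicate_score"]
        clf.classes_ = CLASSES.copy()
        return clf


# ===========================================================================
# Fuzzy percentile classifier


class FuzzyPercentileClassifier(ClassifierMixin, BaseEstimator):
    """Fuzzy membership by percentile rank in the class distributions.

    For each feature and class c, the training values define an empirical
    CDF F_c (midpoint convention at ties); the confidence that a value x
    belongs to class c is 1 - |2 F_c(x) - 1| — maximal at the class median,
    zero outside the class range. A beat is assigned to the class with the
    larger mean confidence over the selected features (tie -> VB).
    """

    def fit(self, X, y):
        X = _validate_X(X)
        y01 = _encode_labels(y)
        if np.sum(y01 == 0) == 0 or np.sum(y01 == 1) == 0:
            raise ValueError("both classes must be present")
        self.sorted_values_ = [
            [np.sort(X[y01 == c, j]) for j in range(X.shape[1])]
            for c in (0, 1)
        ]
        self.classes_ = CLASSES.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def _confidence(self, c: int, j: int, x: np.ndarray) -> np.ndarray:
        vals = self.sorted_values_[c][j]
        n = len(vals)
        lo = np.searchsorted(vals, x, side="left")
        hi = np.searchsorted(vals, x, side="right")
        cdf = (lo + 0.5 * (hi - lo)) / n
        return 1.0 - np.abs(2.0 * cdf - 1.0)

    def predict(self, X):
        X = _validate_X(X)
        conf = np.zeros((2, len(X)))
        for c in (0, 1):
            for j in range(X.shape[1]):
                conf[c] += self._confidence(c, j, X[:, j])
        conf /= X.shape[1]
        # tie -> VB: VB wins when conf_vb >= conf_svb
        return CLASSES[(conf[1] >= conf[0]).astype(int)]

    def mean_confidences(self, X) -> np.ndarray:
        """(2, n) array of per-class mean confidences (SVB row 0, VB row 1)."""
        X = _validate_X(X)
        conf = np.zeros((2, len(X)))
        for c in (0, 1):
            for j in range(X.shape[1]):
                conf[c] += self._confidence(c, j, X[:, j])
        return conf / X.shape[1]

    def to_json(self) -> str:
        return json.dumps({
            "version": 1, "kind": "fuzzy",
            "sorted_values": [
                [col.tolist() for col in per_class]
                for per_class in self.sorted_values_
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "FuzzyPercentileClassifier":
        doc = json.loads(text)
        clf = cls()
        clf.sorted_values_ = [
            [np.asarray(col) for col in per_class]
            for per_class in doc["sorted_values"]
        ]
        clf.classes_ = CLASSES.copy()
        clf.n_features_in_ = len(clf.sorted_values_[0])
        return clf


# ===========================================================================
# Linear discriminant analysis


class PooledLdaClassifier(ClassifierMixin, BaseEstimator):
    """LDA with pooled covariance and class priors.

    a_hat = Sigma^-1 (mu1 - mu2) with the pooled
    Sigma = [(n1-1) Sigma1 + (n2-1) Sigma2] / (n1 + n2 - 2); a beat y is
    assigned to class 1 (SVB) iff
    lambda(y) = [y - (mu1+mu2)/2]^T a_hat > ln(pi2/pi1), else class 2 (VB;
    equality included). Fitting records the standardized coefficients and
    the apparent error rate APER = (N - n11 - n22)/N.
    """

    def __init__(self, priors=(0.3, 0.7)):
        self.priors = priors

    def fit(self, X, y):
        X = _validate_X(X)
        y01 = _encode_labels(y)
        n1 = int(np.sum(y01 == 0))
        n2 = int(np.sum(y01 == 1))
        if n1 < 2 or n2 < 2:
            raise ValueError("each class needs at least 2 rows")
        X1, X2 = X[y01 == 0], X[y01 == 1]
        self.mu1_ = X1.mean(axis=0)
        self.mu2_ = X2.mean(axis=0)
        s1 = np.atleast_2d(np.cov(X1, rowvar=False, ddof=1))
        s2 = np.atleast_2d(np.cov(X2, rowvar=False, ddof=1))
        self.sigma_pooled_ = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
        sigma = self.sigma_pooled_
        if not np.all(np.isfinite(sigma)):
            raise ConditioningError("non-finite pooled covariance")
        try:
            cond = np.linalg.cond(sigma)
        except np.linalg.LinAlgError as err:
            raise ConditioningError("singular pooled covariance") from err
        if not np.isfinite(cond) or 1.0 / cond < RCOND_FLOOR:
            raise ConditioningError(
                f"badly scaled pooled covariance (rcond ~ {1.0 / cond:.2e})"
            )
        self.a_hat_ = np.linalg.solve(sigma, self.mu1_ - self.mu2_)
        self.std_coeffs_ = self.a_hat_ * np.sqrt(np.diag(sigma))
        self.threshold_ = float(np.log(self.priors[1] / self.priors[0]))
        pred = self._predict01(X)
        n11 = int(np.sum((y01 == 0) & (pred == 0)))
        n22 = int(np.sum((y01 == 1) & (pred == 1)))
        self.aper_ = (len(X) - n11 - n22) / len(X)
        self.classes_ = CLASSES.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = _validate_X(X)
        mid = 0.5 * (self.mu1_ + self.mu2_)
        return (X - mid) @ self.a_hat_

    def _predict01(self, X) -> np.ndarray:
        lam = self.decision_function(X)
        # class 1 (SVB) iff lambda > ln(pi2/pi1); equality -> class 2 (VB)
        return np.where(lam > self.threshold_, 0, 1)

    def predict(self, X):
        return CLASSES[self._predict01(X)]

    def to_json(self) -> str:
        return json.dumps({
            "version": 1, "kind": "lda",
            "mu1": self.mu1_.tolist(), "mu2": self.mu2_.tolist(),
            "sigma_pooled": self.sigma_pooled_.tolist(),
            "a_hat": self.a_hat_.tolist(),
            "std_coeffs": self.std_coeffs_.tolist(),
            "priors": list(self.priors), "aper": self.aper_,
        })

    @classmethod
    def from_json(cls, text: str) -> "PooledLdaClassifier":
        doc = json.loads(text)
        clf = cls(priors=tuple(doc["priors"]))
        clf.mu1_ = np.asarray(doc["mu1"])
        clf.mu2_ = np.asarray(doc["mu2"])
        clf.sigma_pooled_ = np.asarray(doc["sigma_pooled"])
        clf.a_hat_ = np.asarray(doc["a_hat"])
        clf.std_coeffs_ = np.asarray(doc["std_coeffs"])
        clf.aper_ = doc["aper"]
        clf.threshold_ = float(np.log(clf.priors[1] / clf.priors[0]))
        clf.classes_ = CLASSES.copy()
        clf.n_features_in_ = len(clf.mu1_)
        return clf


# ===========================================================================
# Thin functional wrappers


def kmeans_fit(X, y, k: int, replicates: int = 10, seed: int | None = 0) -> KMeansBeatClassifier:
    return KMeansBeatClassifier(k=k, replicates=replicates, random_state=seed).fit(X, y)


def kmeans_predict(model: KMeansBeatClassifier, x):
    out = model.predict(np.atleast_2d(np.asarray(x, dtype=float)))
    return out[0] if np.asarray(x).ndim == 1 else out


def fuzzy_fit(X, y) -> FuzzyPercentileClassifier:
    return FuzzyPercentileClassifier().fit(X, y)


def fuzzy_confidence(model: FuzzyPercentileClassifier, feature: int, x: float, cls: str) -> float:
    c = 0 if cls == "SVB" else 1
    return float(model._confidence(c, feature, np.asarray([x], dtype=float))[0])


def fuzzy_predict(model: FuzzyPercentileClassifier, x):
    out = model.predict(np.atleast_2d(np.asarray(x, dtype=float)))
    return out[0] if np.asarray(x).ndim == 1 else out


def lda_fit(X, y, priors=(0.3, 0.7)) -> PooledLdaClassifier:
    return PooledLdaClassifier(priors=priors).fit(X, y)


def lda_predict(model: PooledLdaClassifier, x):
    out = model.predict(np.atleast_2d(np.asarray(x, dtype=float)))
    return out[0] if np.asarray(x).ndim == 1 else out
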