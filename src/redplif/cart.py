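"""Prior-weighted classification trees for screening descriptor tables.

:class:`PriorDecisionTreeClassifier` is a scikit-learn-style estimator
implementing binary CART with user-set class prior probabilities, the device
that makes recursive partitioning usable on heavily imbalanced screening
data (~1.7% actives): with priors ``(π₀, π₁)`` every node uses the
prior-adjusted class proportions

    p(j|t) = π_j · n_j(t)/N_j  /  Σ_k π_k · n_k(t)/N_k

for its Gini impurity and is labelled ``argmax_j π_j · n_j(t)/N_j``.  This
is implemented exactly as weighted CART with per-class sample weights
``w_j = π_j / N_j`` (algebraically identical).  Splitting is greedy over
midpoints between consecutive distinct feature values; growth stops on
``min_split`` / ``min_leaf`` / ``max_depth`` and the grown tree is then
cost-complexity pruned with ``α = cp · R(root)``.

Model-validation helpers follow: prior grid search under an F1 floor,
y-scrambling (chance correlation), split-descriptor cross-correlation, and
a train-vs-CV overfitting check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .screening_eval import ConfusionMatrix, Metrics, confusion, metrics

__all__ = [
    "TreeNode",
    "PriorDecisionTreeClassifier",
    "GridSearchResult",
    "ValidationReport",
    "grid_search_priors",
    "y_scramble",
    "descriptor_cross_correlation",
    "overfit_check",
    "validate_model",
    "extract_xy",
]


@dataclass
class TreeNode:
    """One node of a fitted tree.

    Internal nodes split on ``x[split_variable] < threshold`` (true -> left);
    ``class_probabilities`` are the prior-weighted (p(0|t), p(1|t)), summing
    to 1, and ``node_class`` their argmax.
    """

    node_class: int
    class_probabilities: tuple[float, float]
    n_samples: int
    split_variable: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def split_variables(self) -> set[int]:
        if self.is_leaf:
            return set()
        return {self.split_variable} | self.left.split_variables() | self.right.split_variables()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"class": self.node_class,
                    "p": [round(p, 6) for p in self.class_probabilities],
                    "n": self.n_samples}
        return {"split": self.split_variable, "threshold": round(float(self.threshold), 6),
                "left": self.left.to_dict(), "right": self.right.to_dict()}


def _node_stats(w0: float, w1: float) -> tuple[int, tuple[float, float]]:
    total = w0 + w1
    p1 = w1 / total if total else 0.0
    return (1 if p1 > 0.5 else 0), (1 - p1, p1)


class PriorDecisionTreeClassifier(ClassifierMixin, BaseEstimator):
    """Binary CART with class prior probabilities.

    Parameters
    ----------
    priors : (float, float) or None
        Prior probabilities ``(π_class0, π_class1)``; they are normalized to
        sum to 1.  ``None`` uses the empirical class frequencies, which
        reduces the estimator to plain (unweighted) Gini CART.
    min_split : int
        Minimum raw sample count of a node for it to be considered for
        splitting (default 20, the conventional recursive-partitioning
        default).
    min_leaf : int
        Minimum raw sample count of each child (default 7).
    cp : float
        Complexity parameter; the grown tree is pruned with
        ``α = cp · R(root)`` (default 0.01).
    max_depth : int
        Maximum tree depth (default 30).

    Attributes
    ----------
    tree_ : TreeNode
        The fitted (pruned) tree.
    classes_ : ndarray
        Always ``[0, 1]``.
    feature_names_in_ : ndarray of str, when fitted from a DataFrame.
    """

    def __init__(self, priors=None, min_split: int = 20, min_leaf: int = 7,
                 cp: float = 0.01, max_depth: int = 30):
        self.priors = priors
        self.min_split = min_split
        self.min_leaf = min_leaf
        self.cp = cp
        self.max_depth = max_depth

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("need a binary 0/1 target with both classes present")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]

        n0, n1 = int(np.sum(y == 0)), int(np.sum(y == 1))
        if self.priors is None:
            pi0, pi1 = n0 / len(y), n1 / len(y)
        else:
            pi0, pi1 = float(self.priors[0]), float(self.priors[1])
            if pi0 <= 0 or pi1 <= 0:
                raise ValueError("priors must be positive")
            s = pi0 + pi1
            pi0, pi1 = pi0 / s, pi1 / s
        self.priors_ = (pi0, pi1)
        # per-sample weights making weighted CART == prior-adjusted CART
        w = np.where(y == 1, pi1 / n1, pi0 / n0)

        root = self._grow(X, y.astype(int), w, depth=0)
        root_risk = self._leaf_risk(y.astype(int), w)
        self.tree_ = self._prune(root, X, y.astype(int), w, alpha=self.cp * max(root_risk, 1e-15))
        return self

    @staticmethod
    def _leaf_risk(y: np.ndarray, w: np.ndarray) -> float:
        """Prior-weighted misclassification risk if this sample set is a leaf."""
        w1 = float(w[y == 1].sum())
        w0 = float(w[y == 0].sum())
        return min(w0, w1)

    def _grow(self, X: np.ndarray, y: np.ndarray, w: np.ndarray, depth: int) -> TreeNode:
        w0 = float(w[y == 0].sum())
        w1 = float(w[y == 1].sum())
        cls, probs = _node_stats(w0, w1)
        node = TreeNode(node_class=cls, class_probabilities=probs, n_samples=len(y))
        if len(y) < self.min_split or depth >= self.max_depth or w0 == 0.0 or w1 == 0.0:
            return node
        split = self._best_split(X, y, w)
        if split is None:
            return node
        var, thr = split
        mask = X[:, var] < thr
        node.split_variable = int(var)
        node.threshold = float(thr)
        node.left = self._grow(X[mask], y[mask], w[mask], depth + 1)
        node.right = self._grow(X[~mask], y[~mask], w[~mask], depth + 1)
        return node

    def _best_split(self, X: np.ndarray, y: np.ndarray, w: np.ndarray):
        """Best (variable, threshold) by weighted-Gini decrease; ties break
        toward the lowest variable index then lowest threshold."""
        total_w0 = float(w[y == 0].sum())
        total_w1 = float(w[y == 1].sum())
        total = total_w0 + total_w1
        parent_gini = total * (1.0 - (total_w0 / total) ** 2 - (total_w1 / total) ** 2)
        best = None
        best_gain = 1e-12
        n = len(y)
        for var in range(X.shape[1]):
            order = np.argsort(X[:, var], kind="stable")
            xs = X[order, var]
            ws = w[order]
            ys = y[order]
            cum_w1 = np.cumsum(ws * ys)
            cum_w = np.cumsum(ws)
            # candidate split after position i (0-based): left = first i+1 samples
            distinct = np.nonzero(np.diff(xs) > 0)[0]
            for i in distinct:
                n_left = i + 1
                if n_left < self.min_leaf or n - n_left < self.min_leaf:
                    continue
                lw, lw1 = float(cum_w[i]), float(cum_w1[i])
                lw0 = lw - lw1
                rw1 = total_w1 - lw1
                rw0 = total_w0 - lw0
                rw = rw0 + rw1
                child = 0.0
                if lw > 0:
                    child += lw * (1.0 - (lw0 / lw) ** 2 - (lw1 / lw) ** 2)
                if rw > 0:
                    child += rw * (1.0 - (rw0 / rw) ** 2 - (rw1 / rw) ** 2)
                gain = parent_gini - child
                if gain > best_gain:
                    best_gain = gain
                    best = (var, 0.5 * (xs[i] + xs[i + 1]))
        return best

    def _prune(self, node: TreeNode, X, y, w, alpha: float) -> TreeNode:
        """Bottom-up cost-complexity pruning: collapse a subtree when its risk
        reduction per extra leaf is ≤ α."""
        if node.is_leaf:
            node._risk = self._leaf_risk(y, w)
            return node
        mask = X[:, node.split_variable] < node.threshold
        node.left = self._prune(node.left, X[mask], y[mask], w[mask], alpha)
        node.right = self._prune(node.right, X[~mask], y[~mask], w[~mask], alpha)
        leaf_risk = self._leaf_risk(y, w)
        subtree_risk = node.left._risk + node.right._risk
        n_leaves = node.n_leaves()
        if leaf_risk - subtree_risk <= alpha * (n_leaves - 1) + 1e-15:
            collapsed = TreeNode(node_class=node.node_class,
                                 class_probabilities=node.class_probabilities,
                                 n_samples=node.n_samples)
            collapsed._risk = leaf_risk
            return collapsed
        node._risk = subtree_risk
        return node

    # -- prediction -------------------------------------------------------

    def _descend(self, x: np.ndarray) -> TreeNode:
        node = self.tree_
        while not node.is_leaf:
            node = node.left if x[node.split_variable] < node.threshold else node.right
        return node

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return np.array([self._descend(x).node_class for x in X], dtype=int)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_")
        X = check_array(X, dtype=float)
        return np.array([self._descend(x).class_probabilities for x in X], dtype=float)

    # -- introspection ----------------------------------------------------

    def split_variable_names(self) -> list[str]:
        """Names (``feature_names_in_`` when available, else ``V<i+1>``) of
        the variables the fitted tree splits on."""
        check_is_fitted(self, "tree_")
        idx = sorted(self.tree_.split_variables())
        if hasattr(self, "feature_names_in_"):
            return [str(self.feature_names_in_[i]) for i in idx]
        return [f"V{i + 1}" for i in idx]

    def rules(self) -> list[str]:
        """Root-to-leaf paths of the active (class-1) leaves, one "key" per
        line, e.g. ``Key #1: V295 >= 0.85 and V22 < 0.23 -> active``."""
        check_is_fitted(self, "tree_")
        names = (list(self.feature_names_in_) if hasattr(self, "feature_names_in_")
                 else [f"V{i + 1}" for i in range(self.n_features_in_)])
        keys: list[str] = []

        def walk(node: TreeNode, conds: list[str]) -> None:
            if node.is_leaf:
                if node.node_class == 1:
                    body = " and ".join(conds) if conds else "(always)"
                    keys.append(f"Key #{len(keys) + 1}: {body} -> active")
                return
            name = names[node.split_variable]
            walk(node.left, conds + [f"{name} < {node.threshold:.4g}"])
            walk(node.right, conds + [f"{name} >= {node.threshold:.4g}"])

        walk(self.tree_, [])
        return keys


# ---------------------------------------------------------------------------
# Table-level helpers and validity checks
# ---------------------------------------------------------------------------

def extract_xy(table: pd.DataFrame, features: list[str] | None = None):
    """(X, y) from an analysis table: y column + V-descriptor columns."""
    if features is None:
        features = [c for c in table.columns if c.startswith("V") and c[1:].isdigit()]
    if not features:
        raise ValueError("no descriptor (V) columns found")
    return table[features], table["y"].to_numpy(dtype=int)


def _train_metrics(clf: PriorDecisionTreeClassifier, X, y) -> Metrics:
    return metrics(confusion(y, clf.predict(X)))


@dataclass
class GridSearchResult:
    best_priors: tuple[float, float]
    classifier: PriorDecisionTreeClassifier
    metrics: Metrics
    trace: pd.DataFrame


def grid_search_priors(
    table: pd.DataFrame,
    prior_grid,
    f1_floor: float = 0.0,
    **fit_params,
) -> GridSearchResult:
    """Fit one tree per prior setting; pick the highest training BA among
    settings whose training F1 exceeds ``f1_floor``.

    Ties on BA break toward the less extreme prior (π_active closest to
    0.5).  If no setting clears the floor a ``ValueError`` carrying the full
    trace is raised.
    """
    grid = [tuple(p) for p in prior_grid]
    if not grid:
        raise ValueError("empty prior grid")
    X, y = extract_xy(table)
    rows = []
    fitted: dict[tuple[float, float], PriorDecisionTreeClassifier] = {}
    for priors in grid:
        clf = PriorDecisionTreeClassifier(priors=priors, **fit_params).fit(X, y)
        m = _train_metrics(clf, X, y)
        fitted[priors] = clf
        rows.append({"prior_inactive": priors[0], "prior_active": priors[1],
                     "BA": m.BA, "F1": m.F1, "EF": m.EF,
                     "sensitivity": m.sensitivity, "specificity": m.specificity,
                     "n_leaves": clf.tree_.n_leaves()})
    trace = pd.DataFrame(rows)
    ok = trace[trace["F1"] > f1_floor]
    if ok.empty:
        err = ValueError(f"no prior setting reached F1 > {f1_floor}")
        err.trace = trace
        raise err
    ok = ok.sort_values(
        by=["BA", "prior_active"],
        key=lambda s: -abs(s - 0.5) if s.name == "prior_active" else s,
        ascending=[False, False],
    )
    row = ok.iloc[0]
    best = (float(row["prior_inactive"]), float(row["prior_active"]))
    clf = fitted[best]
    return GridSearchResult(best_priors=best, classifier=clf,
                            metrics=_train_metrics(clf, X, y), trace=trace)


def y_scramble(table: pd.DataFrame, n_iterations: int = 20, seed: int = 0,
               **fit_params) -> np.ndarray:
    """Chance-correlation baseline: training BA after refitting on permuted
    labels, ``n_iterations`` times with a seeded generator."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be ≥ 1")
    X, y = extract_xy(table)
    Xv = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty(n_iterations)
    for i in range(n_iterations):
        ys = rng.permutation(y)
        while len(np.unique(ys)) < 2:  # cannot happen unless y is constant
            ys = rng.permutation(y)
        clf = PriorDecisionTreeClassifier(**fit_params).fit(Xv, ys)
        out[i] = metrics(confusion(ys, clf.predict(Xv))).BA
    return out


def descriptor_cross_correlation(
    table: pd.DataFrame, variables: list[str], threshold: float = 0.8
) -> tuple[pd.DataFrame, float, bool]:
    """Pearson correlations between descriptor columns (typically the fitted
    tree's split variables).

    Returns (correlation matrix, max off-diagonal |r|, flag).  Zero-variance
    columns correlate as 0 with a warning.
    """
    if len(variables) < 2:
        raise ValueError("need ≥2 variables")
    data = table[variables].to_numpy(dtype=float)
    sd = data.std(axis=0)
    if np.any(sd == 0):
        dead = [v for v, s in zip(variables, sd) if s == 0]
        warnings.warn(f"zero-variance descriptors treated as uncorrelated: {dead}")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    off = np.abs(corr - np.eye(len(variables)))
    max_r = float(off.max())
    return pd.DataFrame(corr, index=variables, columns=variables), max_r, max_r > threshold


def overfit_check(table: pd.DataFrame, k_folds: int = 5, seed: int = 0,
                  margin: float = 0.1, **fit_params) -> tuple[float, float, bool]:
    """Stratified k-fold comparison of training BA and cross-validated BA;
    flags overfitting when the gap exceeds ``margin``."""
    if k_folds < 2:
        raise ValueError("k_folds must be ≥ 2")
    X, y = extract_xy(table)
    Xv = np.asarray(X, dtype=float)
    if min(np.sum(y == 1), np.sum(y == 0)) < k_folds:
        raise ValueError("a fold would lack one class; use fewer folds")
    clf = PriorDecisionTreeClassifier(**fit_params).fit(Xv, y)
    train_ba = metrics(confusion(y, clf.predict(Xv))).BA
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    for train_idx, test_idx in skf.split(Xv, y):
        fold = PriorDecisionTreeClassifier(**fit_params).fit(Xv[train_idx], y[train_idx])
        y_pred[test_idx] = fold.predict(Xv[test_idx])
    cv_ba = metrics(confusion(y, y_pred)).BA
    return train_ba, cv_ba, (train_ba - cv_ba) > margin


@dataclass
class ValidationReport:
    """The three standard validity checks of a fitted screening tree."""

    train_BA: float
    cv_BA: float
    scrambled_BA: np.ndarray
    max_abs_descriptor_correlation: float
    overfitting: bool
    cross_correlated: bool
    chance_correlated: bool

    def summary(self) -> str:
        lines = [
            f"training BA            : {self.train_BA:.3f}",
            f"cross-validated BA     : {self.cv_BA:.3f}  (overfitting: {self.overfitting})",
            f"scrambled BA mean±sd   : {self.scrambled_BA.mean():.3f} ± {self.scrambled_BA.std():.3f}"
            f"  (chance correlation: {self.chance_correlated})",
            f"max |r| between splits : {self.max_abs_descriptor_correlation:.3f}"
            f"  (cross-correlation: {self.cross_correlated})",
        ]
        return "\n".join(lines)


def validate_model(table: pd.DataFrame, clf: PriorDecisionTreeClassifier,
                   n_scramble: int = 20, k_folds: int = 5, seed: int = 0,
                   corr_threshold: float = 0.8, overfit_margin: float = 0.1) -> ValidationReport:
    """Run all three checks (overfitting, descriptor cross-correlation,
    chance correlation) on a fitted classifier and its training table."""
    X, y = extract_xy(table)
    params = clf.get_params()
    train_ba, cv_ba, over = overfit_check(table, k_folds=k_folds, seed=seed,
                                          margin=overfit_margin, **params)
    scrambled = y_scramble(table, n_iterations=n_scramble, seed=seed, **params)
    chance = train_ba <= np.quantile(scrambled, 0.95)
    split_vars = clf.split_variable_names()
    if len(split_vars) >= 2:
        _, max_r, cross = descriptor_cross_correlation(table, split_vars, threshold=corr_threshold)
    else:
        max_r, cross = 0.0, False
    return ValidationReport(train_BA=train_ba, cv_BA=cv_ba, scrambled_BA=scrambled,
                            max_abs_descriptor_correlation=max_r,
                            overfitting=over, cross_correlated=cross,
                            chance_correlated=chance)
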