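"""Feature ranking with three supervised selectors.

All three produce a full ordering of the feature columns (best first) plus
per-feature scores; downstream evaluation consumes nested prefixes of the
top ``k`` (100 by default).  The selectors are sklearn-compatible: ``fit``
sets ``ranking_`` and ``feature_scores_``, and ``get_support``/``transform``
select the top ``k`` columns.

* ``TraceRatioSelector`` — iterative trace-ratio maximization on Fisher-style
  between/within affinity graphs (deterministic, seedless).
* ``ReliefFSelector`` — classical Relief-F weights from nearest hits/misses.
* ``ForestImportanceSelector`` — impurity importances of an
  extremely-randomized-trees ensemble.

Distance-based selectors (trace ratio, Relief-F) z-scale features
internally; the forest consumes raw features (splits are scale-invariant).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import ExtraTreesClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_X_y


@dataclass
class Ranking:
    """A selector's ordered feature indices (best first) with scores."""

    selector: str
    indices: np.ndarray
    scores: np.ndarray
    seed: int | None = None
    fold: str = ""
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.indices = np.asarray(self.indices)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("ranking indices must be unique")

    def top(self, k: int) -> np.ndarray:
        return self.indices[:k]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"selector": self.selector, "seed": self.seed,
                       "fold": self.fold,
                       "indices": self.indices.tolist(),
                       "scores": self.scores.tolist(),
                       "feature_names": self.feature_names}, fh)


def _validate_table(X, y):
    X, y = check_X_y(X, y, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present in the labeled table")
    return X, y, classes


def _zscale(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _order_by_score(scores: np.ndarray) -> np.ndarray:
    """Indices sorted by score descending; ties broken by lower index."""
    return np.lexsort((np.arange(scores.size), -scores))


class _RankingSelectorBase(SelectorMixin, BaseEstimator):
    """Shared plumbing: support mask and transform over the top-k prefix."""

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.ranking_[:self.k]] = True
        return mask

    def ranking(self, k: int | None = None) -> Ranking:
        k = self.k if k is None else k
        idx = self.ranking_[:k]
        return Ranking(selector=self._selector_name, indices=idx,
                       scores=self.feature_scores_[idx],
                       seed=getattr(self, "seed", None))


class TraceRatioSelector(_RankingSelectorBase):
    """Trace-ratio feature selection on Fisher-style affinity graphs.

    Per-feature between-class scatter ``b_i`` and within-class scatter
    ``w_i`` are the Laplacian quadratic forms of the between/within affinity
    graphs (cross-class pair weight 1/n; same-class pair weight 1/n_c).  The
    algorithm iterates ``lambda <- sum_selected b / sum_selected w`` and
    re-selects the k largest ``b_i - lambda * w_i`` until the selected set is
    stable; the final ranking orders all features by that score.  The
    objective value is monotonically non-decreasing over iterations.
    """

    _selector_name = "trace_ratio"

    def __init__(self, k: int = 100, max_iter: int = 100):
        self.k = k
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y, classes = _validate_table(X, y)
        if self.k > X.shape[1]:
            raise ValueError("k must not exceed the number of features")
        Z = _zscale(X)
        n = Z.shape[0]
        total = 2 * (n * (Z**2).sum(axis=0) - Z.sum(axis=0) ** 2) / n
        w = np.zeros(Z.shape[1])
        for c in classes:
            Zc = Z[y == c]
            nc = Zc.shape[0]
            w += 2 * ((Zc**2).sum(axis=0) - Zc.sum(axis=0) ** 2 / nc)
        # cross-class pair sum = all-pair sum minus same-class pair sums
        same = np.zeros(Z.shape[1])
        for c in classes:
            Zc = Z[y == c]
            nc = Zc.shape[0]
            same += 2 * (nc * (Zc**2).sum(axis=0) - Zc.sum(axis=0) ** 2) / n
        b = total - same

        lam = b.sum() / max(w.sum(), np.finfo(float).eps)
        selected = None
        converged = False
        for _ in range(self.max_iter):
            scores = b - lam * w
            new_sel = np.sort(_order_by_score(scores)[:self.k])
            if selected is not None and np.array_equal(new_sel, selected):
                converged = True
                break
            selected = new_sel
            denom = w[selected].sum()
            lam = b[selected].sum() / max(denom, np.finfo(float).eps)
        if not converged:
            warnings.warn("trace-ratio iteration did not converge; "
                          "returning the last iterate")
        self.lambda_ = float(lam)
        self.feature_scores_ = b - lam * w
        self.per_feature_between_ = b
        self.per_feature_within_ = w
        self.ranking_ = _order_by_score(self.feature_scores_)
        self.n_features_in_ = X.shape[1]
        return self


class ReliefFSelector(_RankingSelectorBase):
    """Relief-F feature weighting.

    For each probe instance, the per-feature (range-normalized Manhattan)
    distances to its ``n_neighbors`` nearest same-class hits are subtracted
    and the distances to the nearest misses of each other class are added,
    weighted by the class priors; weights are averaged over probes.  By
    default every sample serves as a probe, which makes the weights
    independent of the probe order.
    """

    _selector_name = "relief_f"

    def __init__(self, k: int = 100, n_neighbors: int = 10,
                 n_probes: int | None = None, seed: int = 0):
        self.k = k
        self.n_neighbors = n_neighbors
        self.n_probes = n_probes
        self.seed = seed

    def fit(self, X, y):
        X, y, classes = _validate_table(X, y)
        if self.k > X.shape[1]:
            raise ValueError("k must not exceed the number of features")
        n, d = X.shape
        counts = {c: int((y == c).sum()) for c in classes}
        if min(counts.values()) <= self.n_neighbors:
            raise ValueError(
                f"each class needs more than n_neighbors={self.n_neighbors} members")
        rng = np.random.default_rng(self.seed)
        if self.n_probes is None or self.n_probes >= n:
            probes = np.arange(n)
        else:
            probes = rng.choice(n, size=self.n_probes, replace=False)
        rng_feat = X.max(axis=0) - X.min(axis=0)
        rng_feat[rng_feat == 0] = 1.0
        Xn = X / rng_feat
        priors = {c: counts[c] / n for c in classes}

        weights = np.zeros(d)
        m = self.n_neighbors
        for i in probes:
            diffs = np.abs(Xn - Xn[i])            # (n, d) per-feature distances
            dist = diffs.sum(axis=1)
            dist[i] = np.inf
            ci = y[i]
            hits = np.where(y == ci)[0]
            hits = hits[np.argsort(dist[hits], kind="stable")[:m]]
            weights -= diffs[hits].mean(axis=0) / len(probes)
            for c in classes:
                if c == ci:
                    continue
                miss = np.where(y == c)[0]
                miss = miss[np.argsort(dist[miss], kind="stable")[:m]]
                factor = priors[c] / (1.0 - priors[ci])
                weights += factor * diffs[miss].mean(axis=0) / len(probes)
        self.feature_scores_ = weights
        self.ranking_ = _order_by_score(weights)
        self.n_features_in_ = d
        return self


class ForestImportanceSelector(_RankingSelectorBase):
    """Impurity-based importances from an extremely-randomized-trees ensemble."""

    _selector_name = "forest"

    def __init__(self, k: int = 100, n_trees: int = 100, seed: int = 0):
        self.k = k
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y):
        X, y, _ = _validate_table(X, y)
        if self.k > X.shape[1]:
            raise ValueError("k must not exceed the number of features")
        if self.n_trees < 10:
            raise ValueError("n_trees must be >= 10")
        forest = ExtraTreesClassifier(n_estimators=self.n_trees,
                                      random_state=self.seed)
        forest.fit(X, y)
        self.estimator_ = forest
        self.feature_scores_ = forest.feature_importances_
        self.ranking_ = _order_by_score(self.feature_scores_)
        self.n_features_in_ = X.shape[1]
        return self


SELECTORS = {
    "trace_ratio": TraceRatioSelector,
    "relief_f": ReliefFSelector,
    "forest": ForestImportanceSelector,
}


def _make_selector(name: str, k: int, seed: int, relief_neighbors: int = 10,
                   forest_trees: int = 100):
    if name == "trace_ratio":
        return TraceRatioSelector(k=k)
    if name == "relief_f":
        return ReliefFSelector(k=k, n_neighbors=relief_neighbors, seed=seed)
    if name == "forest":
        return ForestImportanceSelector(k=k, n_trees=forest_trees, seed=seed)
    raise KeyError(name)


def trace_ratio_rank(X, y, k: int = 100) -> Ranking:
    return TraceRatioSelector(k=k).fit(X, y).ranking()


def relief_f_rank(X, y, k: int = 100, n_neighbors: int = 10,
                  n_probes: int | None = None, seed: int = 0) -> Ranking:
    sel = ReliefFSelector(k=k, n_neighbors=n_neighbors, n_probes=n_probes,
                          seed=seed)
    return sel.fit(X, y).ranking()


def forest_importance_rank(X, y, k: int = 100, n_trees: int = 100,
                           seed: int = 0) -> Ranking:
    return ForestImportanceSelector(k=k, n_trees=n_trees, seed=seed).fit(X, y).ranking()
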