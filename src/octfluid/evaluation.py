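"""The experimental protocol: repeated stratified CV with per-fold selection.

For every repeat x fold, each selector is fitted on the training rows only;
each classifier is then trained on nested prefixes of the selector's ranking
(subset sizes 1..max_features) and its test accuracy recorded.  Analytics
summarize the records into accuracy-vs-subset-size curves, best-result
tables, a feature correlation matrix, and per-category relevance statistics
of the top-100 rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import RidgeClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features.layout import LAYOUT, FeatureLayout
from .selection import Ranking, _make_selector

CLASSIFIERS = ("lda", "ridge", "svm_linear", "svm_rbf", "knn15",
               "random_forest", "gradient_boosting")
SELECTOR_NAMES = ("trace_ratio", "relief_f", "forest")

#: classifiers whose inputs are z-scaled with training statistics
_SCALED = {"lda", "ridge", "svm_linear", "svm_rbf", "knn15"}

MILESTONE_SIZES = (1, 5, 10, 20, 30, 50, 70, 100)


@dataclass
class CVConfig:
    """Protocol parameters: 10x10 CV over top-100 nested subsets by default."""

    n_folds: int = 10
    n_repeats: int = 10
    max_features: int = 100
    selectors: tuple[str, ...] = SELECTOR_NAMES
    classifiers: tuple[str, ...] = CLASSIFIERS
    seed: int = 0
    relief_neighbors: int = 10
    forest_trees: int = 100

    def validate(self, n_features: int) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.max_features > min(510, n_features):
            raise ValueError("max_features must not exceed the feature count")
        unknown = set(self.selectors) - set(SELECTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown selectors: {sorted(unknown)}")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


def make_classifier(name: str, seed: int = 0, n_train: int | None = None):
    """Classifier with the protocol's fixed hyperparameters."""
    if name == "lda":
        return LinearDiscriminantAnalysis()
    if name == "ridge":
        return RidgeClassifier(alpha=1.0)
    if name == "svm_linear":
        return SVC(kernel="linear", C=1.0)
    if name == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if name == "knn15":
        k = 15 if n_train is None else max(1, min(15, n_train - 1))
        return KNeighborsClassifier(n_neighbors=k, weights="distance")
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


def run_cv(X, y, config: CVConfig) -> tuple[pd.DataFrame, list[Ranking]]:
    """Execute the full protocol; returns (records, per-fold rankings).

    Records: one row per (repeat, fold, selector, classifier, subset_size)
    with the test accuracy.  Selection is fitted strictly on training rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    config.validate(X.shape[1])
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    _, fold_counts = np.unique(y, return_counts=True)
    if fold_counts.min() < config.n_folds:
        raise ValueError("a fold would miss a class: too few samples for "
                         f"{config.n_folds}-fold stratification")
    splitter = RepeatedStratifiedKFold(n_splits=config.n_folds,
                                       n_repeats=config.n_repeats,
                                       random_state=config.seed)
    records = []
    rankings: list[Ranking] = []
    for split_idx, (train, test) in enumerate(splitter.split(X, y)):
        repeat, fold = divmod(split_idx, config.n_folds)
        Xtr_raw, ytr = X[train], y[train]
        Xte_raw, yte = X[test], y[test]
        mu = Xtr_raw.mean(axis=0)
        sd = Xtr_raw.std(axis=0)
        sd[sd == 0] = 1.0
        Xtr_sc = (Xtr_raw - mu) / sd
        Xte_sc = (Xte_raw - mu) / sd
        for sel_name in config.selectors:
            sel = _make_selector(sel_name, k=config.max_features,
                                 seed=config.seed + split_idx,
                                 relief_neighbors=config.relief_neighbors,
                                 forest_trees=config.forest_trees)
            sel.fit(Xtr_raw, ytr)
            ranking = sel.ranking(config.max_features)
            ranking.fold = f"r{repeat}f{fold}"
            rankings.append(ranking)
            order = ranking.indices
            for clf_name in config.classifiers:
                scaled = clf_name in _SCALED
                Xtr = Xtr_sc if scaled else Xtr_raw
                Xte = Xte_sc if scaled else Xte_raw
                for size in range(1, config.max_features + 1):
                    cols = order[:size]
                    clf = make_classifier(clf_name, seed=config.seed,
                                          n_train=len(train))
                    clf.fit(Xtr[:, cols], ytr)
                    acc = float((clf.predict(Xte[:, cols]) == yte).mean())
                    records.append((repeat, fold, sel_name, clf_name, size, acc))
    df = pd.DataFrame(records, columns=["repeat", "fold", "selector",
                                        "classifier", "subset_size", "accuracy"])
    return df, rankings


def accuracy_curves(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of accuracy per (selector, classifier, subset_size)."""
    expected = (records.groupby(["selector", "classifier"])["subset_size"]
                .nunique())
    if expected.nunique() > 1:
        raise ValueError("incomplete record set: subset sizes differ across "
                         f"configurations: {expected.to_dict()}")
    grouped = (records.groupby(["selector", "classifier", "subset_size"])
               ["accuracy"].agg(["mean", "std", "count"]).reset_index())
    n_folds = grouped["count"].max()
    missing = grouped[grouped["count"] != n_folds]
    if len(missing):
        raise ValueError("missing CV cells: "
                         + missing[["selector", "classifier", "subset_size"]]
                         .to_string(index=False))
    grouped["std"] = grouped["std"].fillna(0.0)
    return grouped.rename(columns={"mean": "mean_accuracy", "std": "sd_accuracy"})


def pairwise_correlation(X, layout: FeatureLayout = LAYOUT
                         ) -> tuple[np.ndarray, pd.DataFrame]:
    """Absolute Pearson correlations and per-category-pair means.

    Constant features get correlation 0 by convention; the self-marker
    diagonal is excluded from the category-pair means.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = X.std(axis=0)
    ok = sd > 0
    corr = np.zeros((X.shape[1], X.shape[1]))
    if ok.any():
        sub = np.corrcoef(X[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = np.abs(np.atleast_2d(sub))
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    np.fill_diagonal(corr, np.abs(np.where(ok, 1.0, 0.0)))

    if X.shape[1] != layout.n_features:
        # partial tables: no category bookkeeping possible
        return corr, pd.DataFrame(columns=["category_a", "category_b",
                                           "mean_abs_corr"])
    cats = layout.categories
    rows = []
    for ca in cats:
        a0, a1 = layout.ranges[ca]
        for cb in cats:
            b0, b1 = layout.ranges[cb]
            blockm = corr[a0:a1, b0:b1].copy()
            if ca == cb:
                np.fill_diagonal(blockm, np.nan)
            rows.append((ca, cb, float(np.nanmean(blockm))))
    means = pd.DataFrame(rows, columns=["category_a", "category_b", "mean_abs_corr"])
    return corr, means


def category_presence(rankings: list[Ranking],
                      layout: FeatureLayout = LAYOUT) -> pd.DataFrame:
    """Mean absolute and proportional presence of each category in the top-100.

    Proportional presence divides by min(100, category size) — the maximum
    number of that category's markers that could fit in a top-100 ranking.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    cats = layout.categories
    counts = {c: [] for c in cats}
    for rk in rankings:
        per = {c: 0 for c in cats}
        for idx in rk.indices:
            per[layout.category_of(int(idx))] += 1
        for c in cats:
            counts[c].append(per[c])
    rows = []
    for c in cats:
        mean_count = float(np.mean(counts[c]))
        denom = min(100, layout.category_size(c))
        rows.append((c, mean_count, mean_count / denom))
    return pd.DataFrame(rows, columns=["category", "mean_count",
                                       "proportional_presence"])


def category_score(rankings: list[Ranking],
                   layout: FeatureLayout = LAYOUT) -> pd.DataFrame:
    """Best-rank score per category over all rankings.

    With r the minimum 1-based rank any marker of the category attains,
    score = 100 * (100 - r) / 99 (rank 1 -> 100, rank 100 -> 0); categories
    absent from every top-100 score -1.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    best: dict[str, int | None] = {c: None for c in layout.categories}
    for rk in rankings:
        for pos, idx in enumerate(rk.indices, start=1):
            c = layout.category_of(int(idx))
            if best[c] is None or pos < best[c]:
                best[c] = pos
    rows = []
    for c, r in best.items():
        score = -1.0 if r is None else 100.0 * (100 - r) / 99.0
        rows.append((c, r if r is not None else -1, score))
    return pd.DataFrame(rows, columns=["category", "best_rank", "score"])


def best_results(records: pd.DataFrame) -> pd.DataFrame:
    """Best mean accuracy per (selector, classifier) with milestone columns.

    Also reports the mean and sd of successive-size accuracy differences over
    the last 50 subset sizes (the stabilization statistic); ties in the best
    size resolve to the smallest size.
    """
    curves = accuracy_curves(records)
    rows = []
    for (sel, clf), grp in curves.groupby(["selector", "classifier"]):
        grp = grp.sort_values("subset_size")
        acc = grp["mean_accuracy"].to_numpy()
        sizes = grp["subset_size"].to_numpy()
        best_i = int(np.argmax(acc))
        row = {"selector": sel, "classifier": clf,
               "best_accuracy": float(acc[best_i]),
               "best_size": int(sizes[best_i])}
        for m in MILESTONE_SIZES:
            if m in sizes:
                row[f"acc_at_{m}"] = float(acc[sizes == m][0])
        diffs = np.diff(acc)[-50:]
        row["tail_diff_mean"] = float(diffs.mean()) if diffs.size else 0.0
        row["tail_diff_sd"] = float(diffs.std()) if diffs.size else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
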