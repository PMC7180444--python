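"""CV protocol structure, leakage protection and the report analytics."""

import numpy as np
import pandas as pd
import pytest

from octfluid.evaluation import (CVConfig, accuracy_curves, best_results,
                                 category_presence, category_score,
                                 pairwise_correlation, run_cv)
from octfluid.features.layout import LAYOUT
from octfluid.phantom import planted_feature_table
from octfluid.selection import Ranking, _make_selector


@pytest.fixture(scope="module")
def small_cv():
    X, y, idx = planted_feature_table(n_samples=60, n_informative=3,
                                      n_noise=9, effect=2.0, seed=0)
    config = CVConfig(n_folds=3, n_repeats=2, max_features=4,
                      selectors=("trace_ratio", "relief_f"),
                      classifiers=("ridge", "knn15"), seed=5,
                      relief_neighbors=5)
    records, rankings = run_cv(X, y, config)
    return X, y, config, records, rankings


class TestRunCV:
    def test_record_count_is_full_grid(self, small_cv):
        _, _, config, records, rankings = small_cv
        expected = (config.n_repeats * config.n_folds * len(config.selectors)
                    * len(config.classifiers) * config.max_features)
        assert len(records) == expected
        assert len(rankings) == config.n_repeats * config.n_folds * len(config.selectors)

    def test_label_copy_feature_gives_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        y = np.arange(40) % 2
        X = rng.normal(size=(40, 5))
        X[:, 2] = y
        config = CVConfig(n_folds=2, n_repeats=1, max_features=3,
                          selectors=("trace_ratio",), classifiers=("ridge",),
                          seed=0)
        records, _ = run_cv(X, y, config)
        assert (records["accuracy"] == 1.0).all()

    def test_permuted_labels_fall_to_chance(self):
        rng = np.random.default_rng(3)
        X, y, _ = planted_feature_table(n_samples=120, seed=3)
        y_perm = rng.permutation(y)
        config = CVConfig(n_folds=4, n_repeats=1, max_features=3,
                          selectors=("forest",), classifiers=("ridge",), seed=1)
        records, _ = run_cv(X, y_perm, config)
        assert 0.4 <= records["accuracy"].mean() <= 0.6

    def test_selection_uses_only_training_rows(self, small_cv):
        """Refitting each selector on the training rows alone reproduces the
        ranking recorded by the protocol: the test fold cannot leak in."""
        from sklearn.model_selection import RepeatedStratifiedKFold

        X, y, config, _, rankings = small_cv
        splitter = RepeatedStratifiedKFold(n_splits=config.n_folds,
                                           n_repeats=config.n_repeats,
                                           random_state=config.seed)
        it = iter(rankings)
        for split_idx, (train, _) in enumerate(splitter.split(X, y)):
            for sel_name in config.selectors:
                recorded = next(it)
                sel = _make_selector(sel_name, k=config.max_features,
                                     seed=config.seed + split_idx,
                                     relief_neighbors=config.relief_neighbors)
                refit = sel.fit(X[train], y[train]).ranking(config.max_features)
                assert np.array_equal(recorded.indices, refit.indices)

    def test_missing_class_in_fold_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        y = np.array([0] * 9 + [1])
        config = CVConfig(n_folds=3, n_repeats=1, max_features=2,
                          selectors=("trace_ratio",), classifiers=("ridge",))
        with pytest.raises(ValueError, match="fold"):
            run_cv(X, y, config)

    def test_seeded_determinism(self):
        X, y, _ = planted_feature_table(n_samples=40, n_noise=6, seed=1)
        config = CVConfig(n_folds=2, n_repeats=1, max_features=2,
                          selectors=("forest",), classifiers=("ridge",), seed=9)
        r1, _ = run_cv(X, y, config)
        r2, _ = run_cv(X, y, config)
        assert r1.equals(r2)


class TestAccuracyCurves:
    def test_flat_records_give_flat_curve(self):
        records = pd.DataFrame({
            "repeat": [0, 0, 1, 1], "fold": [0, 1, 0, 1],
            "selector": "s", "classifier": "c",
            "subset_size": [1, 1, 1, 1], "accuracy": [0.8] * 4})
        curves = accuracy_curves(records)
        assert curves["mean_accuracy"].iloc[0] == 0.8
        assert curves["sd_accuracy"].iloc[0] == 0.0

    def test_hand_built_means(self):
        records = pd.DataFrame({
            "repeat": [0, 0, 0, 0], "fold": [0, 1, 0, 1],
            "selector": "s", "classifier": "c",
            "subset_size": [1, 1, 2, 2], "accuracy": [0.6, 0.8, 0.9, 0.7]})
        curves = accuracy_curves(records).set_index("subset_size")
        assert curves.loc[1, "mean_accuracy"] == pytest.approx(0.7)
        assert curves.loc[2, "mean_accuracy"] == pytest.approx(0.8)

    def test_curve_length_equals_max_features(self, small_cv):
        _, _, config, records, _ = small_cv
        curves = accuracy_curves(records)
        for _, grp in curves.groupby(["selector", "classifier"]):
            assert len(grp) == config.max_features

    def test_missing_cells_raise(self):
        records = pd.DataFrame({
            "repeat": [0, 0, 0], "fold": [0, 1, 0],
            "selector": "s", "classifier": "c",
            "subset_size": [1, 1, 2], "accuracy": [0.6, 0.8, 0.9]})
        with pytest.raises(ValueError):
            accuracy_curves(records)


class TestPairwiseCorrelation:
    def test_duplicated_feature_gives_unit_off_diagonal(self, rng):
        X = rng.normal(size=(50, 3))
        X = np.column_stack([X, X[:, 0]])
        corr, _ = pairwise_correlation(X, LAYOUT)
        assert corr[0, 3] == pytest.approx(1.0)

    def test_independent_noise_mean_below_point_one(self, rng):
        X = rng.normal(size=(1000, 20))
        corr, _ = pairwise_correlation(X, LAYOUT)
        off = corr[np.triu_indices(20, 1)]
        assert off.mean() < 0.1

    def test_hand_computed_three_feature_table(self):
        X = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 0.0], [3.0, 6.0, 5.0],
                      [4.0, 8.0, 2.0]])
        corr, _ = pairwise_correlation(X, LAYOUT)
        assert corr[0, 1] == pytest.approx(1.0)
        expected = abs(np.corrcoef(X[:, 0], X[:, 2])[0, 1])
        assert corr[0, 2] == pytest.approx(expected)

    def test_constant_feature_zero_by_convention(self, rng):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 7.0
        corr, _ = pairwise_correlation(X, LAYOUT)
        assert corr[1].sum() == 0 and corr[:, 1].sum() == 0


def _ranking_from(indices):
    return Ranking(selector="t", indices=np.asarray(indices),
                   scores=np.arange(len(indices), 0, -1, dtype=float))


class TestCategoryRelevance:
    def test_first_hundred_layout_indices_fill_gibs(self):
        presence = category_presence([_ranking_from(np.arange(100))], LAYOUT)
        row = presence.set_index("category").loc["GIBS"]
        assert row["mean_count"] == 15
        assert row["proportional_presence"] == 1.0

    def test_absent_category_scores_minus_one(self):
        presence = category_presence([_ranking_from(np.arange(100))], LAYOUT)
        assert presence.set_index("category").loc["GLRL", "mean_count"] == 0
        score = category_score([_ranking_from(np.arange(100))], LAYOUT)
        assert score.set_index("category").loc["GLRL", "score"] == -1

    def test_two_fold_average_matches_hand_arithmetic(self):
        r1 = _ranking_from(np.arange(100))          # 15 GIBS markers
        r2 = _ranking_from(np.arange(400, 500))     # 0 GIBS markers
        presence = category_presence([r1, r2], LAYOUT)
        assert presence.set_index("category").loc["GIBS", "mean_count"] == 7.5

    @pytest.mark.parametrize("rank,expected", [
        (1, 100.0), (100, 0.0), (50, 100 * 50 / 99)])
    def test_score_affine_mapping(self, rank, expected):
        indices = np.r_[np.arange(rank - 1), [509], np.arange(rank - 1, 99)]
        score = category_score([_ranking_from(indices[:100])], LAYOUT)
        assert score.set_index("category").loc["GLRL", "score"] == pytest.approx(
            expected)


class TestBestResults:
    def _records(self, accs):
        rows = []
        for size, acc in enumerate(accs, start=1):
            rows.append((0, 0, "s", "c", size, acc))
        return pd.DataFrame(rows, columns=["repeat", "fold", "selector",
                                           "classifier", "subset_size",
                                           "accuracy"])

    def test_monotone_curve_peaks_at_max_size(self):
        best = best_results(self._records([0.5, 0.6, 0.7]))
        assert best.loc[0, "best_size"] == 3

    def test_flat_curve_ties_to_smallest_size(self):
        best = best_results(self._records([0.7, 0.7, 0.7]))
        assert best.loc[0, "best_size"] == 1

    def test_hand_built_curve(self):
        best = best_results(self._records([0.7, 0.9, 0.8]))
        assert best.loc[0, "best_accuracy"] == pytest.approx(0.9)
        assert best.loc[0, "best_size"] == 2
        assert best.loc[0, "acc_at_1"] == pytest.approx(0.7)


def test_nested_subsets_are_prefixes(small_cv):
    """The size-k feature set is by construction a prefix of size k+1."""
    _, _, config, _, rankings = small_cv
    for rk in rankings:
        for k in range(1, config.max_features):
            assert np.array_equal(rk.top(k), rk.top(k + 1)[:k])
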