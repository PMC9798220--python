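"""Edge features, selection, metrics and the nested-CV classifier."""

import numpy as np
import pytest

import mbnf.evaluation as ev
from mbnf import (ConfusionCounts, TTestSelector, confusion_metrics,
                  edge_index, edge_vector, nested_cv_classify,
                  noise_robustness_experiment, paired_ttest_compare,
                  ttest_select)


class TestEdgeVector:
    def test_index_convention_for_four_nodes(self):
        assert edge_index(4) == [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3),
                                 (2, 3)]

    def test_length_for_standard_parcellation(self):
        assert len(edge_index(116)) == 6670

    def test_values_follow_index_map(self):
        rng = np.random.default_rng(0)
        W = rng.standard_normal((5, 5))
        W = 0.5 * (W + W.T)
        v = edge_vector(W)
        for pos, (i, j) in enumerate(edge_index(5)):
            assert v[pos] == W[i, j]

    def test_zero_network_gives_zero_vector(self):
        np.testing.assert_array_equal(edge_vector(np.eye(6)), np.zeros(15))

    def test_asymmetric_matrix_rejected(self):
        M = np.arange(16.0).reshape(4, 4)
        with pytest.raises(ValueError):
            edge_vector(M)


class TestSelection:
    def test_null_selection_rate_matches_alpha(self):
        rng = np.random.default_rng(12)
        n_edges = 2000
        X = rng.standard_normal((60, n_edges))
        y = np.array([0] * 30 + [1] * 30)
        frac = ttest_select(X, y, alpha=0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_edges)
        assert 0.05 - half <= frac <= 0.05 + half

    def test_planted_shift_fully_detected(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 200))
        y = np.array([0] * 30 + [1] * 30)
        X[y == 1, :10] += 2.0  # two pooled-sd shift: power ~ 1 at n=30
        mask = ttest_select(X, y, alpha=0.05)
        assert mask[:10].all()

    def test_zero_variance_edge_never_selected(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 5))
        X[:, 2] = 7.0
        y = np.array([0] * 20 + [1] * 20)
        assert not ttest_select(X, y)[2]

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 4))
        with pytest.raises(ValueError):
            ttest_select(X, np.zeros(10, dtype=int))

    def test_selector_composes_with_sklearn_pipelines(self):
        from sklearn.pipeline import make_pipeline
        from sklearn.svm import SVC
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 50))
        y = np.array([0] * 20 + [1] * 20)
        X[y == 1, :5] += 3.0
        pipe = make_pipeline(TTestSelector(alpha=0.05),
                             SVC(kernel="linear", C=1.0))
        pipe.fit(X, y)
        assert pipe.score(X, y) == 1.0
        assert pipe[0].get_support().sum() >= 5


class TestMetrics:
    @pytest.mark.parametrize("counts,expected", [
        ((1, 1, 0, 0), (100.0, 100.0, 100.0)),
        ((3, 4, 2, 1), (70.0, 75.0, 200.0 / 3.0)),
        ((0, 5, 0, 5), (50.0, 0.0, 100.0)),
    ])
    def test_closed_form_values(self, counts, expected):
        tp, tn, fp, fn = counts
        acc, sen, spe = confusion_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert (acc, sen, spe) == pytest.approx(expected)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(tp=0, tn=3, fp=2, fn=0))

    def test_accuracy_is_class_weighted_mean_of_sen_spe(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(1, 30, size=4)
            acc, sen, spe = confusion_metrics(
                ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            n_pos, n_neg = tp + fn, tn + fp
            direct = 100.0 * (tp + tn) / (tp + tn + fp + fn)
            weighted = (sen * n_pos + spe * n_neg) / (n_pos + n_neg)
            assert acc == pytest.approx(direct) == pytest.approx(weighted)
            assert min(sen, spe) - 1e-9 <= acc <= max(sen, spe) + 1e-9


def separable_features(seed=0, n=40, e=30):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, e))
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X[y == 1, 0] += 10.0
    return X, y


class TestNestedCv:
    def test_separable_features_classified_perfectly(self):
        X, y = separable_features()
        rep = nested_cv_classify({0.5: X}, y, n_repeats=3, seed=0)
        assert rep.acc_mean == 100.0 and rep.acc_sd == 0.0
        assert rep.auc_mean == 100.0

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(9)
        X, y = separable_features(seed=9, n=60, e=40)
        y_perm = rng.permutation(y)
        rep = nested_cv_classify({0.5: X}, y_perm, n_repeats=5, seed=9)
        half = 100 * 2.576 * np.sqrt(0.25 / 60)
        assert 50 - half <= rep.acc_mean <= 50 + half

    def test_deterministic_given_seed(self):
        X, y = separable_features(seed=2)
        a = nested_cv_classify({0.1: X, 0.2: X + 0.01}, y, n_repeats=2,
                               seed=5)
        b = nested_cv_classify({0.1: X, 0.2: X + 0.01}, y, n_repeats=2,
                               seed=5)
        assert a.to_dict() == b.to_dict()

    def test_tie_breaks_toward_smaller_grid_value(self):
        X, y = separable_features(seed=3)
        rep = nested_cv_classify({0.9: X, 0.2: X}, y, n_repeats=2, seed=1)
        assert all(v == 0.2 for fold in rep.chosen_hyperparams
                   for v in fold)

    def test_selection_never_sees_test_subjects(self, monkeypatch):
        """Every selector/SVM fit must use fewer rows than the cohort."""
        X, y = separable_features(seed=4, n=40)
        n_total = len(y)
        seen = []
        original = TTestSelector.fit

        def spy(self, Xf, yf):
            seen.append(len(yf))
            return original(self, Xf, yf)

        monkeypatch.setattr(TTestSelector, "fit", spy)
        nested_cv_classify({0.5: X}, y, n_repeats=1, seed=0)
        assert seen and max(seen) < n_total

    def test_networks_and_feature_matrices_equivalent(self):
        rng = np.random.default_rng(11)
        nets = rng.standard_normal((20, 6, 6))
        nets = 0.5 * (nets + nets.transpose(0, 2, 1))
        y = np.array([0, 1] * 10)
        feats = np.stack([edge_vector(W) for W in nets])
        a = nested_cv_classify({1.0: nets}, y, n_repeats=2, seed=3,
                               n_folds=3)
        b = nested_cv_classify({1.0: feats}, y, n_repeats=2, seed=3,
                               n_folds=3)
        assert a.to_dict() == b.to_dict()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            nested_cv_classify({}, np.array([0, 1] * 10), n_repeats=1)


class TestPairedComparison:
    def test_identical_series_not_significant(self):
        p, sig = paired_ttest_compare([80.0, 82.0, 81.0],
                                      [80.0, 82.0, 81.0])
        assert np.isnan(p) and not sig

    def test_constant_shift_with_jitter_is_significant(self):
        rng = np.random.default_rng(0)
        b = 80 + 0.1 * rng.standard_normal(10)
        a = b + 5.0 + 0.01 * rng.standard_normal(10)
        p, sig = paired_ttest_compare(a, b)
        assert sig and p < 1e-6

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest_compare([1.0], [2.0])


@pytest.fixture(scope="module")
def discriminable_networks():
    rng = np.random.default_rng(21)
    nets = []
    y = np.array([0] * 20 + [1] * 20)
    for label in y:
        W = rng.standard_normal((10, 10)) * 0.1
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        if label:
            W[0, 1] = W[1, 0] = W[0, 1] + 0.8
            W[2, 3] = W[3, 2] = W[2, 3] + 0.8
        nets.append(W)
    return np.stack(nets), y


class TestNoiseRobustness:
    def test_zero_sd_reproduces_clean_pipeline(self, discriminable_networks):
        nets, y = discriminable_networks
        clean = nested_cv_classify({0.0: nets}, y, n_repeats=2, seed=4)
        table = noise_robustness_experiment(nets, y, [0.0], n_repeats=2,
                                            seed=4)
        assert table[0]["acc_mean"] == clean.acc_mean

    def test_accuracy_degrades_with_noise(self, discriminable_networks):
        nets, y = discriminable_networks
        table = noise_robustness_experiment(nets, y, [0.0, 0.5, 2.0],
                                            n_repeats=2, seed=4)
        assert table[0]["acc_mean"] > table[-1]["acc_mean"]

    def test_invalid_grids_rejected(self, discriminable_networks):
        nets, y = discriminable_networks
        with pytest.raises(ValueError):
            noise_robustness_experiment(nets, y, [-0.1], n_repeats=1)
        with pytest.raises(ValueError):
            noise_robustness_experiment(nets, y, [0.5, 0.1], n_repeats=1)
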