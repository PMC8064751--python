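"""Diagonal LDA, LOOXV, subsampling and count-matched decoding."""

import dataclasses

import numpy as np
import pytest

import optovis as ov
from optovis import decoding as dc


def brute_force_predict(model, x):
    """Oracle: exhaustive diagonal-Gaussian posterior evaluation."""
    best, best_score = None, -np.inf
    for k in range(len(model.classes)):
        score = model.class_log_priors[k] - 0.5 * np.sum(
            (x - model.class_means[k]) ** 2 / model.pooled_variances
        )
        if score > best_score:  # strict: first maximum wins
            best, best_score = model.classes[k], score
    return best


class TestGroupOrientations:
    def test_opposite_directions_share_class(self):
        labels = dc.group_orientations(np.array([0.0, 180.0, 90.0, 270.0]))
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_eight_directions_four_classes(self):
        dirs = np.arange(8) * 45.0
        assert np.unique(dc.group_orientations(dirs)).size == 4

    def test_labels_are_consecutive_from_zero(self):
        labels = dc.group_orientations(np.array([315.0, 135.0, 0.0]))
        assert set(labels) == {0, 1}


class TestFit:
    def test_hand_computed_instance(self):
        X = np.array(
            [[1, 2], [3, 2], [2, 4], [2, 0], [8, 5], [10, 5], [9, 7], [9, 3]],
            dtype=float,
        )
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        m = dc.fit_diag_lda(X, y)
        assert np.allclose(m.class_means, [[2, 2], [9, 5]])
        # pooled SSW: class 0 -> (2, 8); class 1 -> (2, 8); / (8 - 2)
        assert np.allclose(m.pooled_variances, [4 / 6, 16 / 6])
        assert np.allclose(np.exp(m.class_log_priors), [0.5, 0.5])

    def test_small_class_named_in_error(self):
        X = np.zeros((3, 1))
        with pytest.raises(ValueError, match="'b'"):
            dc.fit_diag_lda(X, np.array(["a", "a", "b"]))

    def test_zero_variance_floored(self):
        X = np.array([[1.0, 5.0]] * 4 + [[2.0, 5.0]] * 4)
        y = np.repeat([0, 1], 4)
        m = dc.fit_diag_lda(X, y)
        assert np.all(m.pooled_variances > 0)
        assert np.isfinite(dc.predict(m, np.array([1.5, 5.0])))


class TestPredict:
    def test_nearest_mean_in_1d(self):
        m = dc.fit_diag_lda(
            np.array([[0.0], [0.1], [10.0], [9.9]]), np.array([0, 0, 1, 1])
        )
        assert dc.predict(m, np.array([2.0])) == 0

    def test_tie_breaks_to_lowest_class(self):
        X = np.array([[-1.0], [1.0], [3.0], [5.0]])
        m = dc.fit_diag_lda(X, np.array([0, 0, 1, 1]))
        # x exactly between the class means (0 and 4): scores tie exactly
        assert dc.predict(m, np.array([2.0])) == 0

    def test_dimension_mismatch_errors(self):
        m = dc.fit_diag_lda(np.zeros((4, 2)) + np.arange(4)[:, None],
                            np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError, match="units"):
            dc.predict(m, np.array([1.0, 2.0, 3.0]))

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(5.0, size=(40, 3)).astype(float)
        y = rng.integers(0, 4, 40)
        while np.bincount(y).min() < 2:
            y = rng.integers(0, 4, 40)
        m = dc.fit_diag_lda(X, y)
        for _ in range(300):
            x = rng.poisson(5.0, 3).astype(float)
            assert dc.predict(m, x) == brute_force_predict(m, x)

    def test_uninformative_unit_does_not_change_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(4.0, size=(60, 5)).astype(float)
        y = np.repeat(np.arange(3), 20)
        m1 = dc.fit_diag_lda(X, y)
        X2 = np.hstack([X, np.full((60, 1), 7.0)])
        m2 = dc.fit_diag_lda(X2, y)
        for _ in range(50):
            x = rng.poisson(4.0, 5).astype(float)
            assert dc.predict(m1, x) == dc.predict(m2, np.append(x, 7.0))


class TestLooxv:
    def test_separated_classes_perfect(self):
        X = np.concatenate([np.zeros((10, 2)), np.full((10, 2), 50.0)])
        X += np.random.default_rng(0).random((20, 2))
        y = np.repeat([0, 1], 10)
        assert dc.looxv_accuracy(X, y).accuracy == 1.0

    def test_two_singleton_trials_error(self):
        with pytest.raises(ValueError, match="leave-one-out"):
            dc.looxv_accuracy(np.array([[0.0], [5.0]]), np.array([0, 1]))

    @pytest.mark.parametrize("k", [2, 4, 6])
    def test_shuffled_labels_hit_chance(self, k):
        rng = np.random.default_rng(k)
        X = rng.poisson(5.0, size=(600, 20)).astype(float)
        y = rng.permutation(np.repeat(np.arange(k), 600 // k))
        acc = dc.looxv_accuracy(X, y).accuracy
        ci = 3 * np.sqrt((1 / k) * (1 - 1 / k) / 600)
        assert abs(acc - 1 / k) < ci + 0.01

    def test_matches_naive_refitting(self):
        rng = np.random.default_rng(3)
        X = rng.poisson(rng.uniform(1, 8, size=(3, 4))[
            np.repeat(np.arange(3), 7)
        ]).astype(float)
        y = np.repeat(np.arange(3), 7)
        res = dc.looxv_accuracy(X, y)
        naive = []
        for i in range(len(y)):
            m = np.ones(len(y), bool)
            m[i] = False
            model = dc.fit_diag_lda(X[m], y[m], min_per_class=1)
            naive.append(dc.predict(model, X[i]))
        assert np.array_equal(res.predictions, np.array(naive))

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(5.0, size=(40, 6)).astype(float)
        y = np.repeat(np.arange(4), 10)
        a = dc.looxv_accuracy(X, y)
        b = dc.looxv_accuracy(X, y)
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.predictions, b.predictions)


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(5)
    means = rng.uniform(2, 10, size=(4, 8))
    y = np.repeat(np.arange(4), 30)
    X = rng.poisson(means[y]).astype(float)
    return X, y


class TestSubsampling:
    def test_full_fraction_reproduces_full_accuracy(self, data):
        X, y = data
        full = dc.looxv_accuracy(X, y).accuracy
        accs = dc.subsampled_error_distribution(X, y, fraction=1.0, n_reps=5, seed=0)
        assert np.all(accs == full)

    def test_seeded_reproducible(self, data):
        X, y = data
        a = dc.subsampled_error_distribution(X, y, fraction=0.5, n_reps=10, seed=7)
        b = dc.subsampled_error_distribution(X, y, fraction=0.5, n_reps=10, seed=7)
        assert np.array_equal(a, b)

    def test_mean_near_full_accuracy(self, data):
        X, y = data
        full = dc.looxv_accuracy(X, y).accuracy
        accs = dc.subsampled_error_distribution(X, y, fraction=0.7, n_reps=30, seed=1)
        assert abs(accs.mean() - full) < 2 * accs.std() + 0.02

    def test_infeasible_fraction_errors(self, data):
        X, y = data
        with pytest.raises(ValueError, match="at least 2"):
            dc.subsampled_error_distribution(X, y, fraction=0.03, n_reps=2, seed=0)


class TestCountMatched:
    def test_full_population_counts_are_row_sums(self, small_table):
        table = small_table
        edges = np.array([0.0, 1e9])
        curve = dc.count_matched_decoding(
            table,
            n_neuron_grid=[table.n_units],
            n_combos=1,
            count_bins=edges,
            seed=0,
        )
        for ci, laser in enumerate((False, True)):
            assert curve.n_samples[ci, 0] == int(table.select(laser=laser).sum())

    def test_deterministic_given_seed(self, small_table):
        a = dc.count_matched_decoding(small_table, n_combos=5, seed=3)
        b = dc.count_matched_decoding(small_table, n_combos=5, seed=3)
        assert np.array_equal(a.bin_edges, b.bin_edges)
        assert np.array_equal(a.accuracy, b.accuracy, equal_nan=True)
        assert np.array_equal(a.bootstrap_se, b.bootstrap_se, equal_nan=True)

    def test_subset_size_above_population_needs_replacement(self, small_table):
        with pytest.raises(ValueError, match="replace"):
            dc.count_matched_decoding(
                small_table, n_neuron_grid=[small_table.n_units + 5], n_combos=2,
                seed=0,
            )

    def test_accuracy_monotone_in_tuning_strength(self):
        """Stronger orientation tuning must yield higher decoding accuracy."""
        mean_acc = []
        for kappa in (0.0, 1.0, 4.0):
            accs = []
            for seed in range(5):
                cfg = ov.GeneratorConfig(
                    n_units_bs=8, n_units_ns=2, n_repeats=5, n_channels=2,
                    tuning_concentration=kappa, seed=100 + seed,
                )
                sess, _ = ov.generate_session(cfg)
                table = ov.build_trials(sess)
                mask = table.select(laser=False)
                y = dc.group_orientations(table.stimulus_direction[mask])
                accs.append(dc.looxv_accuracy(table.counts[mask], y).accuracy)
            mean_acc.append(np.mean(accs))
        assert mean_acc[0] < mean_acc[1] < mean_acc[2]
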