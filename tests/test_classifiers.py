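"""Split/standardize plumbing and the three discriminant models."""

import numpy as np
import pytest

from herbspec import (
    CnnSpec,
    TrainedClassifier,
    build_cnn,
    fit_cnn,
    loo_cv,
    softmax,
    standardize_apply,
    standardize_fit,
    stratified_split,
    train_cnn,
    train_plsda,
    train_svm_rbf,
)
from herbspec.classifiers import TrainingDivergenceError, pooled_lengths


class TestStratifiedSplit:
    def test_default_census_split(self):
        labels = np.repeat(np.arange(12), 30)
        split = stratified_split(labels, (4, 1), seed=0)
        assert len(split.train_rows) == 288 and len(split.test_rows) == 72
        for k in range(12):
            assert (labels[split.train_rows] == k).sum() == 24
            assert (labels[split.test_rows] == k).sum() == 6

    def test_disjoint_and_covering(self):
        labels = np.repeat(np.arange(5), 10)
        split = stratified_split(labels, seed=1)
        merged = np.sort(np.concatenate([split.train_rows, split.test_rows]))
        assert np.array_equal(merged, np.arange(50))

    def test_seed_determinism(self):
        labels = np.repeat(np.arange(3), 15)
        a = stratified_split(labels, seed=4)
        b = stratified_split(labels, seed=4)
        c = stratified_split(labels, seed=5)
        assert np.array_equal(a.train_rows, b.train_rows)
        assert not np.array_equal(a.train_rows, c.train_rows)

    def test_minimal_class_of_five(self):
        split = stratified_split(np.zeros(5, dtype=int), (4, 1), seed=0)
        assert len(split.train_rows) == 4 and len(split.test_rows) == 1

    def test_too_small_class_named(self):
        labels = np.array([0] * 10 + [1] * 3)
        with pytest.raises(ValueError, match="class 1"):
            stratified_split(labels, (4, 1), seed=0)


class TestStandardizer:
    def test_two_row_symmetry(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        std = standardize_fit(X)
        out = standardize_apply(std, X)
        assert np.allclose(std.mean, 1.0)
        assert np.allclose(out, [[-1, -1], [1, 1]])

    def test_train_statistics_after_apply(self, rng):
        X = rng.random((40, 7)) * 5 + 2
        std = standardize_fit(X)
        out = standardize_apply(std, X)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(out.std(axis=0), 1.0, atol=1e-6)

    def test_test_rows_transformed_with_train_stats(self, rng):
        Xtr, Xte = rng.random((20, 4)), rng.random((5, 4))
        std = standardize_fit(Xtr)
        out = standardize_apply(std, Xte)
        m, s = Xtr.mean(axis=0), Xtr.std(axis=0)
        brute = np.array([[(Xte[i, j] - m[j]) / s[j] for j in range(4)]
                          for i in range(5)])
        assert np.allclose(out, brute)

    def test_constant_band_flagged_sd_one(self):
        X = np.column_stack([np.arange(6.0), np.full(6, 3.0)])
        std = standardize_fit(X)
        assert std.constant_bands == [1]
        assert std.sd[1] == 1.0


class TestLooCv:
    class _Constant:
        def predict(self, X):
            return np.zeros(len(X), dtype=int)

    class _NearestRow:
        def __init__(self, X, y):
            self.X, self.y = X, y

        def predict(self, Xq):
            d = ((Xq[:, None, :] - self.X[None]) ** 2).sum(-1)
            return self.y[np.argmin(d, axis=1)]

    def test_constant_learner_on_balanced_classes(self):
        X = np.arange(20.0)[:, None]
        y = np.array([0, 1] * 10)
        assert loo_cv(lambda X, y: self._Constant(), X, y) == 0.5

    def test_perfect_learner(self):
        X = np.concatenate([np.zeros(5), np.ones(5) * 10])[:, None]
        y = np.array([0] * 5 + [1] * 5)
        assert loo_cv(lambda Xi, yi: self._NearestRow(Xi, yi), X, y) == 1.0

    def test_matches_bruteforce_loop(self, rng):
        X = rng.random((10, 3))
        y = rng.integers(0, 2, 10)
        fn = lambda Xi, yi: self._NearestRow(Xi, yi)
        correct = 0
        for i in range(10):  # independent brute-force loop
            keep = [j for j in range(10) if j != i]
            model = fn(X[keep], y[keep])
            correct += int(model.predict(X[i:i + 1])[0] == y[i])
        assert loo_cv(fn, X, y) == correct / 10


class TestPlsda:
    def test_separable_two_class(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        clf = train_plsda(X, y, n_components=1)
        assert (clf.predict(X) == y).all()

    def test_auto_selects_two_components_when_needed(self, rng):
        # three class centroids spanning a plane: one latent direction cannot
        # separate them, two can
        centers = np.array([[0, 0], [4, 0], [2, 4.0]])
        X2 = np.vstack([c + rng.normal(0, 0.15, (15, 2)) for c in centers])
        X = np.hstack([X2, rng.normal(0, 0.05, (45, 3))])
        y = np.repeat(np.arange(3), 15)
        clf = train_plsda(X, y, n_components="auto", max_components=4)
        accs = clf.history["loo_accuracy"]
        assert accs[1] < 1.0
        assert clf.hyperparams["n_components"] == 2  # smallest of the tied best
        assert accs[2] == max(accs.values())

    def test_memorizes_one_row_per_class(self, rng):
        X = rng.normal(0, 1, (6, 8))
        y = np.arange(6)
        clf = train_plsda(X, y, n_components=5)
        assert (clf.predict(X) == y).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            train_plsda(rng.random((10, 3)), np.zeros(10, dtype=int))


class TestSvmRbf:
    def test_xor_pattern_needs_rbf(self, rng):
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0.0]])
        labels = np.array([0, 0, 1, 1])
        X = np.vstack([c + rng.normal(0, 0.05, (10, 2)) for c in centers])
        y = np.repeat(labels, 10)
        clf = train_svm_rbf(X, y, c_grid=(1.0, 10.0), g_grid=(1.0,), seed=0)
        assert (clf.predict(X) == y).all()

    def test_single_point_grid_selected(self, rng):
        X = rng.random((20, 3))
        y = rng.integers(0, 2, 20)
        clf = train_svm_rbf(X, y, c_grid=(7.0,), g_grid=(0.3,), seed=0)
        assert clf.hyperparams == {"c": 7.0, "g": 0.3}

    def test_tie_resolves_to_smallest_c_then_g(self, rng):
        # trivially separable: every grid point scores 1.0
        X = np.vstack([rng.normal(0, 0.05, (15, 2)), rng.normal(8, 0.05, (15, 2))])
        y = np.array([0] * 15 + [1] * 15)
        clf = train_svm_rbf(X, y, c_grid=(1.0, 10.0), g_grid=(0.1, 1.0), seed=0)
        scores = clf.history["grid_scores"]
        assert len(set(scores.values())) == 1  # genuine tie across the grid
        assert clf.hyperparams == {"c": 1.0, "g": 0.1}

    def test_selection_stays_inside_grid(self, rng):
        X = rng.random((30, 4))
        y = rng.integers(0, 3, 30)
        c_grid, g_grid = (0.5, 2.0), (0.01, 0.1)
        clf = train_svm_rbf(X, y, c_grid=c_grid, g_grid=g_grid, seed=1)
        assert clf.hyperparams["c"] in c_grid and clf.hyperparams["g"] in g_grid

    def test_fewer_rows_than_folds_rejected(self, rng):
        with pytest.raises(ValueError, match="folds"):
            train_svm_rbf(rng.random((3, 2)), np.array([0, 1, 0]), inner_cv_folds=5)


class TestCnn:
    def test_pooled_length_chain(self):
        assert pooled_lengths(176) == [88, 44, 22, 11, 5]

    def test_zero_weight_network_is_uniform(self):
        spec = CnnSpec(seed=0)
        model = build_cnn(spec, 64)
        for p in model.params():
            p[...] = 0.0
        logits = model.forward(np.random.default_rng(0).normal(size=(3, 1, 64)),
                               train=False)
        assert np.allclose(logits, logits[:, :1])
        assert np.allclose(softmax(logits, axis=1), 1 / 12)

    def test_output_shape(self):
        model = build_cnn(CnnSpec(seed=0), 64)
        out = model.forward(np.zeros((5, 1, 64)), train=False)
        assert out.shape == (5, 12)

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            build_cnn(CnnSpec(seed=0), 20)

    def test_first_epoch_loss_near_uniform_bound(self, separated_table, separated_split):
        X = separated_table.X[separated_split.train_rows]
        y = separated_table.labels[separated_split.train_rows]
        clf = fit_cnn(X, y, epochs=1, seed=0)
        assert clf.history["epoch_loss"][0] == pytest.approx(np.log(12), abs=0.3)

    def test_training_is_deterministic(self, separated_table, separated_split):
        X = separated_table.X[separated_split.train_rows][:96, :64]
        y = separated_table.labels[separated_split.train_rows][:96]
        spec = CnnSpec(seed=5, batch_size=48)
        a = fit_cnn(X, y, spec=spec, epochs=2)
        b = fit_cnn(X, y, spec=spec, epochs=2)
        assert a.history["epoch_loss"] == b.history["epoch_loss"]
        assert all(np.array_equal(p, q)
                   for p, q in zip(a.model.params(), b.model.params()))

    def test_divergence_reports_epoch(self, separated_table, separated_split):
        X = separated_table.X[separated_split.train_rows][:48, :64]
        y = separated_table.labels[separated_split.train_rows][:48]
        spec = CnnSpec(seed=0, n_classes=12)
        from herbspec.classifiers import standardize_apply, standardize_fit
        std = standardize_fit(X)
        model = build_cnn(spec, 64)
        model.params()[0][0, 0, 0] = np.nan
        with pytest.raises(TrainingDivergenceError, match="epoch 0"):
            train_cnn(model, standardize_apply(std, X), y, spec, epochs=1)

    def test_probabilities_sum_to_one(self, separated_table, separated_split):
        X = separated_table.X[separated_split.train_rows][:96, :64]
        y = separated_table.labels[separated_split.train_rows][:96]
        clf = fit_cnn(X, y, epochs=2, seed=1)
        p = clf.predict_proba(separated_table.X[separated_split.test_rows][:10, :64])
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()
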