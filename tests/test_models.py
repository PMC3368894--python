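"""ANN, SVM, bagging and ensemble prediction."""

import numpy as np
import pytest

from pdmsite.ann import AnnConfig, AnnModel, sigmoid, train_ann
from pdmsite.ensemble import (AtomTypeEnsemble, default_svm_grid, make_bags,
                              predict_activity, train_ann_bag, train_svm_bag,
                              TrainingBag)


def separable_blobs(n_pos=40, n_neg=60, delta=0.3, seed=0):
    """Two feature blobs in [0,1]^32 shifted by delta on ten components."""
    rng = np.random.default_rng(seed)
    x_neg = rng.uniform(0.1, 0.4, size=(n_neg, 32))
    x_pos = rng.uniform(0.1, 0.4, size=(n_pos, 32))
    x_pos[:, 5:15] += delta
    x = np.vstack([x_pos, x_neg])
    y = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    return x, y


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(np.array(0.0)) == pytest.approx(0.5)

    @pytest.mark.parametrize("x", [-10.0, -1.0, 3.0])
    def test_symmetry(self, x):
        assert sigmoid(np.array(x)) + sigmoid(np.array(-x)) == pytest.approx(1.0)

    def test_stable_for_huge_arguments(self):
        assert sigmoid(np.array(1000.0)) == 1.0
        assert sigmoid(np.array(-1000.0)) == 0.0


class TestBags:
    def test_stated_ratio(self):
        bags = make_bags(np.arange(100), np.arange(100, 1100), n_bags=10, seed=1)
        assert len(bags) == 10
        for b in bags:
            assert len(b.positive_idx) == 100
            assert len(b.negative_idx) == 150
            assert len(set(b.negative_idx)) == 150   # without replacement

    def test_negative_shortage_uses_all_with_warning(self):
        with pytest.warns(UserWarning, match="negatives"):
            bags = make_bags(np.arange(100), np.arange(100, 220), n_bags=3, seed=1)
        for b in bags:
            assert len(b.negative_idx) == 120

    def test_deterministic_under_seed(self):
        a = make_bags(np.arange(10), np.arange(10, 200), seed=42)
        b = make_bags(np.arange(10), np.arange(10, 200), seed=42)
        assert [x.negative_idx for x in a] == [y.negative_idx for y in b]

    def test_zero_positives_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            make_bags(np.array([], dtype=int), np.arange(10))


class TestAnn:
    def test_separable_blobs_reach_perfect_validation_mcc(self):
        x, y = separable_blobs()
        model = train_ann(x, y, x, y, seed=0, config=AnnConfig(n_iterations=300))
        assert model.best_validation_mcc == pytest.approx(1.0)
        pred = model.predict(x) >= 0.5
        assert np.array_equal(pred, y)

    def test_fixed_seed_is_bitwise_deterministic(self):
        x, y = separable_blobs(seed=3)
        cfg = AnnConfig(n_iterations=100)
        m1 = train_ann(x, y, x, y, seed=9, config=cfg)
        m2 = train_ann(x, y, x, y, seed=9, config=cfg)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(m1.w2, m2.w2)
        assert m1.best_iteration == m2.best_iteration

    def test_constant_features_converge_to_prior_without_crash(self):
        x = np.full((50, 32), 0.5)
        y = np.concatenate([np.ones(20, bool), np.zeros(30, bool)])
        model = train_ann(x, y, x, y, seed=0, config=AnnConfig(n_iterations=200))
        out = model.predict(x)
        assert np.all((out >= 0) & (out <= 1))
        assert np.allclose(out, out[0])
        assert abs(out.mean() - 0.4) < 0.2

    def test_single_class_validation_falls_back_with_warning(self):
        x, y = separable_blobs()
        with pytest.warns(UserWarning, match="single-class"):
            model = train_ann(x, y, x[:5], np.ones(5, bool), seed=0,
                              config=AnnConfig(n_iterations=50))
        assert np.isnan(model.best_validation_mcc)

    def test_output_in_open_unit_interval(self):
        rng = np.random.default_rng(0)
        model = AnnModel(w1=rng.normal(size=(32, 15)), b1=rng.normal(size=15),
                         w2=rng.normal(size=(15, 1)), b2=rng.normal(size=1))
        out = model.predict(rng.uniform(0, 1, size=(100, 32)))
        assert np.all((out > 0) & (out < 1))

    def test_json_round_trip(self):
        x, y = separable_blobs()
        m = train_ann(x, y, x, y, seed=1, config=AnnConfig(n_iterations=50))
        back = AnnModel.from_params(m.params())
        np.testing.assert_array_equal(back.predict(x), m.predict(x))


class TestSvm:
    def test_separable_blobs_classified_perfectly(self):
        x, y = separable_blobs(delta=0.5)
        bag = TrainingBag(tuple(np.flatnonzero(y)), tuple(np.flatnonzero(~y)))
        model = train_svm_bag(x, y, bag, grid=[(1.0, 0.5), (8.0, 0.5)], seed=0)
        assert np.array_equal(model.predict(x).astype(bool), y)
        proba = model.predict_proba(x)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_tie_breaks_to_smallest_parameters(self):
        x, y = separable_blobs(delta=0.6)
        bag = TrainingBag(tuple(np.flatnonzero(y)), tuple(np.flatnonzero(~y)))
        grid = [(4.0, 1.0), (1.0, 1.0), (1.0, 0.25)]
        model = train_svm_bag(x, y, bag, grid=grid, seed=0)
        assert model.estimator.C == 1.0
        assert model.estimator.gamma == 0.25

    def test_default_grid_shape(self):
        grid = default_svm_grid()
        assert len(grid) == 11 * 10
        cs = {c for c, _ in grid}
        assert min(cs) == 2 ** -5 and max(cs) == 2 ** 15


class TestEnsemble:
    class _Const:
        def __init__(self, v):
            self.v = v

        def predict(self, x):
            return np.full(len(np.atleast_2d(x)), self.v)

    def test_activity_is_member_mean(self):
        ens = AtomTypeEnsemble(type_id=8, algorithm="ann",
                               members=[self._Const(v) for v in (0.2, 0.4, 0.6)])
        out = predict_activity(ens, np.zeros((3, 32)))
        np.testing.assert_allclose(out, 0.4)

    def test_single_member_is_identity(self):
        ens = AtomTypeEnsemble(type_id=8, algorithm="ann", members=[self._Const(0.77)])
        np.testing.assert_allclose(predict_activity(ens, np.zeros((1, 32))), 0.77)

    def test_member_permutation_invariance_and_convexity(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 10)
        e1 = AtomTypeEnsemble(8, "ann", [self._Const(v) for v in vals])
        e2 = AtomTypeEnsemble(8, "ann", [self._Const(v) for v in vals[::-1]])
        x = np.zeros((5, 32))
        np.testing.assert_allclose(predict_activity(e1, x), predict_activity(e2, x))
        assert np.all((predict_activity(e1, x) >= 0) & (predict_activity(e1, x) <= 1))

    def test_wrong_feature_width_is_error(self):
        ens = AtomTypeEnsemble(8, "ann", [self._Const(0.5)])
        with pytest.raises(ValueError, match="32"):
            predict_activity(ens, np.zeros((2, 31)))
        with pytest.raises(ValueError, match="non-finite"):
            bad = np.zeros((2, 32))
            bad[1, 3] = np.nan
            predict_activity(ens, bad)


def test_planted_shift_recovered_by_bagged_cv():
    """Bagged ANN ensembles recover a delta=0.3 planted feature shift with
    5-fold CV atom-level MCC above 0.5."""
    from pdmsite.metrics import make_cv_folds, mcc_from_labels

    x, y = separable_blobs(n_pos=60, n_neg=140, delta=0.3, seed=11)
    noise = np.random.default_rng(12).normal(0, 0.05, size=x.shape)
    x = np.clip(x + noise, 0, 1)
    plan = make_cv_folds(y, k=5, seed=13)
    preds = np.zeros(len(y), dtype=bool)
    for r in range(5):
        test_idx, val_idx, train_idx = plan.rotation(r)
        bags = make_bags(np.flatnonzero(y[train_idx]),
                         np.flatnonzero(~y[train_idx]), n_bags=5, seed=r)
        members = [train_ann_bag(x[train_idx], y[train_idx], b,
                                 x[val_idx], y[val_idx], seed=r * 10 + i,
                                 config=AnnConfig(n_iterations=200))
                   for i, b in enumerate(bags)]
        ens = AtomTypeEnsemble(8, "ann", members)
        preds[test_idx] = ens.predict(x[test_idx]) >= 0.5
    assert mcc_from_labels(y, preds) > 0.5
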