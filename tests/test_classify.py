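"""Split design and one-vs-one RBF-SVM training, prediction, grid search."""

import numpy as np
import pytest
from sklearn.svm import SVC

import pixelspec as ps

WL5 = 874.0 + 5.0 * np.arange(5)


def _ds(X, y, wl=None):
    X = np.asarray(X, dtype=np.float64)
    wl = (874.0 + 5.0 * np.arange(X.shape[1])) if wl is None else wl
    n = X.shape[0]
    return ps.SpectraDataset(X=X, y=y, scene_id=np.zeros(n),
                             bean_id=np.arange(n), wavelengths=wl)


@pytest.fixture(scope="module")
def blobs_ds():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(3 * i, 0.5, (25, 6)) for i in range(4)])
    return _ds(X, np.repeat([1, 2, 3, 4], 25))


class TestSplits:
    def test_four_two_split(self, small_study, small_cfg):
        plan = ps.make_splits(small_study, cal_per_class=2)
        for k in range(1, 5):
            assert len(plan.cal_scenes[k]) == 2
            assert len(plan.pred_scenes[k]) == small_cfg.scenes_per_class - 2
            assert not set(plan.cal_scenes[k]) & set(plan.pred_scenes[k])

    def test_empty_prediction_set_rejected(self, small_study, small_cfg):
        with pytest.raises(ValueError):
            ps.make_splits(small_study, cal_per_class=small_cfg.scenes_per_class)

    def test_deterministic(self, small_study):
        a = ps.make_splits(small_study, cal_per_class=2)
        b = ps.make_splits(small_study, cal_per_class=2)
        assert a.cal_scenes == b.cal_scenes and a.pred_scenes == b.pred_scenes


class TestSamplePixels:
    def _pixels(self, n_per_class=300):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(4 * n_per_class, 5))
        y = np.repeat([1, 2, 3, 4], n_per_class)
        sid = np.tile([0, 1], 2 * n_per_class)
        return ps.SpectraDataset(X=X, y=y, scene_id=sid,
                                 bean_id=np.arange(len(y)), wavelengths=WL5,
                                 pixel_rc=np.zeros((len(y), 2)))

    def _plan(self, n):
        return ps.SplitPlan(cal_scenes={k: [0, 1] for k in range(1, 5)},
                            pred_scenes={k: [2] for k in range(1, 5)},
                            pixels_per_class_cal=n)

    def test_exact_counts_per_class(self):
        out = ps.sample_pixels(self._pixels(), self._plan(100), seed=0)
        assert len(out) == 400
        for k in range(1, 5):
            assert (out.y == k).sum() == 100

    def test_request_exceeding_supply_rejected(self):
        with pytest.raises(ValueError, match="available"):
            ps.sample_pixels(self._pixels(50), self._plan(100), seed=0)

    def test_two_seeds_differ_but_stay_balanced(self):
        pix = self._pixels()
        a = ps.sample_pixels(pix, self._plan(100), seed=1)
        b = ps.sample_pixels(pix, self._plan(100), seed=2)
        assert not np.array_equal(a.bean_id, b.bean_id)
        assert np.array_equal(np.sort(np.unique(b.y)), [1, 2, 3, 4])

    def test_non_calibration_pixels_rejected(self):
        pix = self._pixels()
        pix.scene_id[:] = 7
        with pytest.raises(ValueError, match="non-calibration"):
            ps.sample_pixels(pix, self._plan(10), seed=0)


class TestSVMTrain:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ps.svm_train(_ds(np.eye(3), [1, 1, 1]), C=1.0, g=1.0)

    def test_dual_feasibility_on_trained_model(self, blobs_ds):
        """Every binary problem satisfies sum(alpha*y)=0 and the box."""
        m = ps.svm_train(blobs_ds, C=10.0, g=0.5)
        assert len(list(m.binary_problems())) == 6
        for rec in m.binary_problems():
            assert abs(rec["alpha_y"].sum()) < 1e-6
            assert np.all(np.abs(rec["alpha_y"]) <= 10.0 + 1e-9)

    def test_bundle_prediction_matches_libsvm(self, blobs_ds):
        """The explicit kernel-evaluation vote agrees with libsvm's own."""
        m = ps.svm_train(blobs_ds, C=10.0, g=0.5)
        clf = SVC(C=10.0, gamma=0.5).fit(blobs_ds.X, blobs_ds.y)
        rng = np.random.default_rng(3)
        Xq = rng.normal(4.5, 3.0, (200, 6))
        np.testing.assert_array_equal(m.predict(Xq), clf.predict(Xq))

    def test_stored_training_predictions_reproduce(self, blobs_ds):
        m = ps.svm_train(blobs_ds, C=10.0, g=0.5)
        np.testing.assert_array_equal(m.train_pred, m.predict(blobs_ds.X))

    def test_separable_toy_matches_hard_margin_analytic(self):
        """Classes at x1=0 and x1=2: the max-margin hyperplane is x1=1 with
        margin width 2/||w|| = 2, i.e. ||w|| = 1 and |f| = 1 at the points."""
        X = np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]])
        y = np.array([1, 1, 2, 2])
        m = ps.svm_train(_ds(X, y), C=1e6, g=0.0, kernel="linear")
        assert m.cal_acc == 100.0
        rec = next(m.binary_problems())
        w = rec["alpha_y"] @ rec["support_X"]
        assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-6)
        assert 2.0 / np.linalg.norm(w) == pytest.approx(2.0, abs=1e-5)
        f = X @ w + rec["bias"]
        np.testing.assert_allclose(np.abs(f), 1.0, atol=1e-5)
        np.testing.assert_allclose(np.sign(f), [1, 1, -1, -1])

    def test_xor_pattern_separated_by_rbf(self):
        """The 4x4 RBF Gram matrix is full rank, so the dual problem admits
        an interpolating solution: training accuracy must be 100%."""
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        y = np.array([1, 1, 2, 2])
        sq = ((X[:, None] - X[None]) ** 2).sum(-1)
        assert np.linalg.matrix_rank(np.exp(-1.0 * sq)) == 4
        m = ps.svm_train(_ds(X, y), C=1e4, g=1.0)
        assert m.cal_acc == 100.0

    def test_laplacian_kernel_trains_and_predicts(self, blobs_ds):
        m = ps.svm_train(blobs_ds, C=10.0, g=0.1, kernel="laplacian")
        assert m.cal_acc > 95.0
        labels, _ = ps.svm_predict(m, blobs_ds)
        assert labels.shape == blobs_ds.y.shape

    def test_serialization_round_trip(self, tmp_path, blobs_ds):
        m = ps.svm_train(blobs_ds, C=10.0, g=0.5)
        m.to_json(tmp_path / "model.json")
        back = ps.SVMModelBundle.from_json(tmp_path / "model.json")
        np.testing.assert_array_equal(back.predict(blobs_ds.X),
                                      m.predict(blobs_ds.X))
        assert (tmp_path / "model.json").read_bytes()  # text artifact exists


class TestSVMPredict:
    def test_training_set_of_separable_toy_is_perfect(self, blobs_ds):
        m = ps.svm_train(blobs_ds, C=10.0, g=0.5)
        _, rep = ps.svm_predict(m, blobs_ds)
        assert rep.pred_acc == 100.0
        assert rep.confusion.sum() == len(blobs_ds)
        np.testing.assert_array_equal(rep.confusion,
                                      np.diag([25, 25, 25, 25]))

    def test_three_of_four_is_exactly_75(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        m = ps.svm_train(_ds(X, [1, 1, 2, 2]), C=100.0, g=1.0)
        truth = _ds(X, [1, 2, 2, 2])     # one training label flipped in truth
        _, rep = ps.svm_predict(m, truth)
        assert rep.pred_acc == pytest.approx(75.000)

    def test_row_permutation_invariance(self, blobs_ds):
        m = ps.svm_train(blobs_ds, C=10.0, g=0.5)
        perm = np.random.default_rng(5).permutation(len(blobs_ds))
        a = m.predict(blobs_ds.X)[perm]
        b = m.predict(blobs_ds.X[perm])
        np.testing.assert_array_equal(a, b)

    def test_band_count_mismatch_rejected(self, blobs_ds):
        m = ps.svm_train(blobs_ds, C=10.0, g=0.5)
        bad = _ds(blobs_ds.X[:, :3], blobs_ds.y)
        with pytest.raises(ValueError, match="bands"):
            ps.svm_predict(m, bad)


class TestGridSearch:
    def test_single_point_grid_returns_it(self, blobs_ds):
        C, g, trace = ps.grid_search(blobs_ds, C_grid=[2.0], g_grid=[0.25],
                                     folds=3, seed=0)
        assert (C, g) == (2.0, 0.25)
        assert len(trace) == 1

    def test_separating_point_reaches_full_cv_accuracy(self, blobs_ds):
        """Oracle loop over the trace: the returned point attains the best
        CV accuracy seen anywhere on the grid, and it is 100% here."""
        C_grid, g_grid = [0.1, 10.0], [0.01, 0.5]
        C, g, trace = ps.grid_search(blobs_ds, C_grid, g_grid, folds=3, seed=0)
        best = max(acc for _, _, acc in trace)
        returned = [acc for c_, g_, acc in trace if (c_, g_) == (C, g)][0]
        assert returned == best == 100.0

    def test_trace_covers_whole_grid(self, blobs_ds):
        _, _, trace = ps.grid_search(blobs_ds, C_grid=[1.0, 2.0],
                                     g_grid=[0.1, 0.2, 0.4], folds=3, seed=0)
        assert len(trace) == 6

    def test_ties_break_to_smaller_c_then_g(self, blobs_ds):
        C, g, trace = ps.grid_search(blobs_ds, C_grid=[4.0, 8.0],
                                     g_grid=[0.1, 0.2], folds=3, seed=0)
        best = max(acc for _, _, acc in trace)
        candidates = sorted((c_, g_) for c_, g_, acc in trace if acc == best)
        assert (C, g) == candidates[0]

    def test_fold_count_larger_than_class_rejected(self):
        tiny = _ds(np.arange(8).reshape(4, 2), [1, 1, 2, 2])
        with pytest.raises(ValueError):
            ps.grid_search(tiny, C_grid=[1.0], g_grid=[1.0], folds=3)
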