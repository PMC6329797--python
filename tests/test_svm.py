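import numpy as np
import pytest

import platinsig as ps

from _oracles import qp_decision_values


class TestHyperparams:
    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            ps.SvmHyperparams(0.0, 1.0)
        with pytest.raises(ValueError):
            ps.SvmHyperparams(1.0, -2.0)

    def test_gamma_round_trip(self):
        h = ps.SvmHyperparams(10.0, 100.0)
        h2 = ps.SvmHyperparams.from_gamma(10.0, h.gamma)
        assert h2.sigma == pytest.approx(100.0)

    def test_default_grid_covers_reported_hyperparameter_pairs(self):
        # (C; sigma) pairs the derived signatures are reported with
        reported = {(1e5, 100.0), (1e4, 100.0), (1e5, 1000.0), (10.0, 10.0), (1000.0, 100.0)}
        from platinsig.search import DEFAULT_C_GRID, DEFAULT_SIGMA_GRID

        grid = {(c, s) for c in DEFAULT_C_GRID for s in DEFAULT_SIGMA_GRID}
        assert reported <= grid


class TestTrainAndScore:
    def test_separable_clusters_classified(self, xy_factory):
        x, y = xy_factory([[0.0], [0.0], [10.0], [10.0]], [0, 0, 1, 1])
        m = ps.train_svm(x, y, ps.SvmHyperparams(10.0, 2.0))
        np.testing.assert_array_equal(m.training_predictions(), [0, 0, 1, 1])

    def test_label_swap_negates_scores(self, xy_factory):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y01 = np.array([0, 1] * 5)
        x, y = xy_factory(X, y01)
        x2, y2 = xy_factory(X, 1 - y01)
        h = ps.SvmHyperparams(5.0, 1.5)
        s1 = ps.train_svm(x, y, h).decision_scores(X)
        s2 = ps.train_svm(x2, y2, h).decision_scores(X)
        np.testing.assert_allclose(s1, -s2, atol=1e-9)

    def test_single_class_raises(self, xy_factory):
        x, y = xy_factory([[0.0], [1.0], [2.0]], [1, 1, 1])
        with pytest.raises(ValueError, match="degenerate"):
            ps.train_svm(x, y, ps.SvmHyperparams(1.0, 1.0))

    def test_margin_support_vectors_score_one(self, xy_factory):
        # widely separated pair, huge C -> hard margin; SVs sit on |f| = 1
        x, y = xy_factory([[-1.0], [1.0]], [0, 1])
        m = ps.train_svm(x, y, ps.SvmHyperparams(1e6, 1.0))
        s = m.decision_scores(np.array([[-1.0], [1.0]]))
        np.testing.assert_allclose(np.abs(s), [1.0, 1.0], atol=1e-6)

    def test_midpoint_of_symmetric_classes_scores_zero(self, xy_factory):
        x, y = xy_factory([[-2.0], [2.0]], [0, 1])
        m = ps.train_svm(x, y, ps.SvmHyperparams(10.0, 1.0))
        assert ps.decision_score(m, np.array([0.0])) == pytest.approx(0.0, abs=1e-9)

    def test_missing_gene_named_in_error(self, xy_factory):
        x, y = xy_factory([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0], [3.0, 1.0]], [0, 0, 1, 1])
        m = ps.train_svm(x, y, ps.SvmHyperparams(1.0, 1.0))
        with pytest.raises(KeyError, match="g1"):
            ps.decision_score(m, {"g0": 0.5})

    def test_serialization_round_trip(self, tmp_path, xy_factory):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 2))
        x, y = xy_factory(X, [0, 1] * 4)
        m = ps.train_svm(x, y, ps.SvmHyperparams(5.0, 1.0))
        p = tmp_path / "model.json"
        m.save(p)
        m2 = ps.SvmModel.load(p)
        np.testing.assert_array_equal(m.decision_scores(X), m2.decision_scores(X))


class TestQpAgreement:
    """The implementation must agree with an independent dual-QP solve."""

    def test_fixed_six_point_instance(self, xy_factory):
        X = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0], [3.0, 3.0], [4.0, 3.5], [3.5, 4.2]])
        y01 = np.array([0, 0, 0, 1, 1, 1])
        x, y = xy_factory(X, y01)
        h = ps.SvmHyperparams(5.0, 1.5)
        m = ps.train_svm(x, y, h)
        test = np.array([[0.5, 0.5], [3.5, 3.5], [2.0, 2.0], [-1.0, 5.0]])
        ref = qp_decision_values(X, y01, h.C, h.sigma, test)
        np.testing.assert_allclose(m.decision_scores(test), ref, atol=1e-6)

    @pytest.mark.parametrize("seed,C,sigma", [
        (0, 1.0, 0.5), (1, 5.0, 1.0), (2, 10.0, 2.0), (3, 1.0, 2.0), (4, 10.0, 0.5),
    ])
    def test_random_small_instances(self, xy_factory, seed, C, sigma):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        X = rng.normal(size=(n, 2))
        y01 = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
        x, y = xy_factory(X, y01)
        m = ps.train_svm(x, y, ps.SvmHyperparams(C, sigma))
        test = rng.normal(size=(6, 2))
        ref = qp_decision_values(X, y01, C, sigma, test)
        np.testing.assert_allclose(m.decision_scores(test), ref, atol=1e-6)


class TestLoocv:
    def test_separable_data_zero_misclassification(self, xy_factory):
        X = np.r_[np.full((5, 1), -3.0) + 0.1 * np.arange(5)[:, None],
                  np.full((5, 1), 3.0) + 0.1 * np.arange(5)[:, None]]
        x, y = xy_factory(X, [0] * 5 + [1] * 5)
        est = ps.loocv(x, y, ps.SvmHyperparams(10.0, 1.0))
        assert est.value == 0.0

    def test_matches_manual_fold_enumeration(self, xy_factory):
        from sklearn.svm import SVC

        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 2))
        y01 = np.array([0, 1, 0, 1, 0, 1])
        x, y = xy_factory(X, y01)
        h = ps.SvmHyperparams(2.0, 1.0)
        est = ps.loocv(x, y, h)
        errors = 0
        for i in range(6):
            tr = [j for j in range(6) if j != i]
            svc = SVC(C=h.C, gamma=h.gamma, tol=1e-8).fit(X[tr], y01[tr])
            errors += int(svc.predict(X[i][None])[0] != y01[i])
        assert est.value == pytest.approx(errors / 6)

    def test_every_sample_held_out_once(self, zpanel, median_labels):
        est = ps.loocv(zpanel, median_labels, ps.SvmHyperparams(10.0, 10.0),
                       genes=zpanel.gene_ids[:4])
        assert sorted(est.per_fold_predictions["sample_id"]) == sorted(zpanel.sample_ids)

    def test_permuted_labels_near_chance(self, xy_factory):
        # n must not be too small: LOOCV is pessimistically biased under
        # permutation (the held-out sample's class is under-represented in
        # its training fold), an O(1/n) effect
        rng = np.random.default_rng(7)
        X = np.r_[rng.normal(-2, 1, size=(15, 1)), rng.normal(2, 1, size=(15, 1))]
        h = ps.SvmHyperparams(10.0, 2.0)
        vals = []
        for _ in range(100):
            yperm = rng.permutation([0] * 15 + [1] * 15)
            x, y = xy_factory(X, yperm)
            vals.append(ps.loocv(x, y, h).value)
        assert np.mean(vals) == pytest.approx(0.5, abs=0.1)

    def test_too_few_per_class_raises(self, xy_factory):
        x, y = xy_factory([[0.0], [1.0], [2.0], [3.0]], [0, 1, 1, 1])
        with pytest.raises(ValueError, match="class"):
            ps.loocv(x, y, ps.SvmHyperparams(1.0, 1.0))

    def test_deterministic(self, zpanel, median_labels):
        h = ps.SvmHyperparams(100.0, 10.0)
        g = zpanel.gene_ids[:5]
        a = ps.loocv(zpanel, median_labels, h, genes=g)
        b = ps.loocv(zpanel, median_labels, h, genes=g)
        assert a.value == b.value
        np.testing.assert_array_equal(a.held_out_scores, b.held_out_scores)


class TestCalibration:
    def test_monotone_non_decreasing(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=40)
        y = (scores + rng.normal(0, 0.5, 40) > 0).astype(int)
        cal = ps.calibrate_posteriors(scores, y)
        grid = np.linspace(-5, 5, 101)
        p = cal(grid)
        assert np.all(np.diff(p) >= -1e-12)

    def test_separated_scores_confident(self):
        # Platt smoothing caps posteriors at (N+1)/(N+2), so confidence
        # beyond 0.95 needs N >= 19 per class
        scores = np.r_[np.full(25, -3.0), np.full(25, 3.0)]
        y = np.r_[np.zeros(25, int), np.ones(25, int)]
        cal = ps.calibrate_posteriors(scores, y)
        assert np.all(cal(scores[y == 1]) >= 0.95)
        assert np.all(cal(scores[y == 0]) <= 0.05)

    def test_symmetric_scores_give_half_at_zero(self):
        scores = np.r_[-np.linspace(0.5, 2, 10), np.linspace(0.5, 2, 10)]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        cal = ps.calibrate_posteriors(scores, y)
        assert cal(0.0) == pytest.approx(0.5, abs=0.05)

    def test_non_finite_scores_rejected(self):
        with pytest.raises(ValueError):
            ps.calibrate_posteriors(np.array([0.0, np.inf]), np.array([0, 1]))


class TestObjectives:
    def test_bounded_logloss_in_unit_interval(self, zpanel, median_labels):
        est = ps.loocv(zpanel, median_labels, ps.SvmHyperparams(10.0, 10.0),
                       objective="logloss", genes=zpanel.gene_ids[:3])
        assert 0.0 <= est.value <= 1.0

    def test_logloss_small_for_separable_data(self, xy_factory):
        # Platt smoothing floors 1 - p_hat near 1/(n/2 + 2), so separable
        # data gives a small but non-zero bounded log-loss
        X = np.r_[np.linspace(-4, -3, 8)[:, None], np.linspace(3, 4, 8)[:, None]]
        x, y = xy_factory(X, [0] * 8 + [1] * 8)
        est = ps.loocv(x, y, ps.SvmHyperparams(100.0, 1.0), objective="logloss")
        assert est.value < 0.2

    def test_cross_entropy_can_exceed_one(self, xy_factory):
        # anti-correlated labels: posteriors confidently wrong
        X = np.r_[np.linspace(-4, -3, 5)[:, None], np.linspace(3, 4, 5)[:, None]]
        x, y = xy_factory(X, [1] * 5 + [0] * 5)
        est = ps.loocv(x, y, ps.SvmHyperparams(100.0, 1.0), objective="cross_entropy")
        assert est.value > 0.0  # unbounded objective, just well-defined


class TestGridSearch:
    def test_single_cell_returns_it(self, zpanel, median_labels):
        h, est = ps.grid_search(zpanel, median_labels, [42.0], [7.0],
                                genes=zpanel.gene_ids[:3])
        assert (h.C, h.sigma) == (42.0, 7.0)

    def test_equals_min_over_cells(self, zpanel, median_labels):
        genes = zpanel.gene_ids[:3]
        C_grid, s_grid = [1.0, 100.0], [1.0, 10.0]
        h, est = ps.grid_search(zpanel, median_labels, C_grid, s_grid, genes=genes)
        cells = {(c, s): ps.loocv(zpanel, median_labels, ps.SvmHyperparams(c, s), genes=genes).value
                 for c in C_grid for s in s_grid}
        assert est.value == min(cells.values())
        assert cells[(h.C, h.sigma)] == est.value

    def test_tie_break_prefers_smaller_C_then_sigma(self, xy_factory):
        # perfectly separable -> every cell ties at 0; smallest pair wins
        X = np.r_[np.full((3, 1), -5.0), np.full((3, 1), 5.0)]
        x, y = xy_factory(X, [0] * 3 + [1] * 3)
        h, est = ps.grid_search(x, y, [10.0, 1.0], [2.0, 1.0])
        assert (h.C, h.sigma) == (1.0, 1.0)


class TestModelChecksum:
    def test_corrupted_serialization_detected(self, tmp_path, xy_factory):
        import json

        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 2))
        x, y = xy_factory(X, [0, 1] * 4)
        m = ps.train_svm(x, y, ps.SvmHyperparams(5.0, 1.0))
        p = tmp_path / "model.json"
        m.save(p)
        d = json.loads(p.read_text())
        d["training_y"][0] = 1 - d["training_y"][0]
        with pytest.raises(ValueError, match="checksum"):
            ps.SvmModel.from_dict(d)


class TestPerFoldScaling:
    def test_flag_produces_valid_estimate(self, zpanel, median_labels):
        genes = zpanel.gene_ids[:3]
        h = ps.SvmHyperparams(10.0, 10.0)
        est = ps.loocv(zpanel, median_labels, h, genes=genes, rescale_per_fold=True)
        assert 0.0 <= est.value <= 1.0
        assert len(est.per_fold_predictions) == zpanel.n_samples

    def test_scale_invariance_under_per_fold_scaling(self, xy_factory):
        # multiplying a feature by a constant changes nothing when folds
        # re-standardize, while global-scale LOOCV sees a different kernel
        rng = np.random.default_rng(9)
        X = rng.normal(size=(14, 2))
        y01 = np.array([0, 1] * 7)
        x1, y = xy_factory(X, y01)
        x2, _ = xy_factory(X * np.array([5.0, 1.0]), y01)
        h = ps.SvmHyperparams(10.0, 1.0)
        a = ps.loocv(x1, y, h, rescale_per_fold=True)
        b = ps.loocv(x2, y, h, rescale_per_fold=True)
        np.testing.assert_allclose(a.held_out_scores, b.held_out_scores, atol=1e-8)
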