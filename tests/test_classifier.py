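import itertools

import numpy as np
import pytest

from impactkit import classify as cl


class TestConfusionMetrics:
    @pytest.mark.parametrize("counts,expected", [
        # (TP, TN, FP, FN) -> (sens, spec, acc, prec) as printed percentages
        ((136, 221, 10, 20), (87.2, 95.7, 92.2, 93.2)),
        ((141, 223, 8, 15), (90.4, 96.5, 94.1, 94.6)),
        ((15, 15, 1, 1), (93.8, 93.8, 93.8, 93.8)),
        ((15, 11, 5, 1), (93.8, 68.8, 81.3, 75.0)),
    ])
    def test_reported_percentages(self, counts, expected):
        rep = cl.confusion_metrics(*counts)
        got = tuple(cl.round_percent(v) for v in
                    (rep.sensitivity, rep.specificity, rep.accuracy,
                     rep.precision))
        assert got == expected

    def test_f_measure_formula(self):
        assert cl._ratio_f(0.904, 0.946) == pytest.approx(0.92452, abs=1e-4)

    def test_degenerate_quotients_flagged(self):
        rep = cl.confusion_metrics(0, 5, 0, 0)
        assert rep.sensitivity == 0.0 and rep.degenerate
        with pytest.raises(ValueError):
            cl.confusion_metrics(0, 0, 0, 0)
        with pytest.raises(ValueError):
            cl.confusion_metrics(-1, 1, 1, 1)

    def test_rounding_half_away_from_zero(self):
        assert cl.round_percent(0.93750) == 93.8
        assert cl.round_percent(0.68450) == 68.5
        assert cl.round_percent(0.0005) == 0.1


class TestTrainAndSerialise:
    def test_separable_training_accuracy(self):
        X = np.array([[-1.0], [-1.1], [-0.9], [1.0], [1.1], [0.9]])
        y = np.array(["nonimpact"] * 3 + ["impact"] * 3)
        model = cl.train_rbf_svm(X, y)
        assert (model.predict(X) == y).all()

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = np.where(X[:, 0] > 0, "impact", "nonimpact")
        m1 = cl.train_rbf_svm(X, y)
        m2 = cl.train_rbf_svm(X, y)
        np.testing.assert_array_equal(m1.dual_coef, m2.dual_coef)
        assert m1.intercept == m2.intercept

    def test_decision_matches_kernel_expansion_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        y = np.where(X[:, 0] + X[:, 1] > 0, "impact", "nonimpact")
        model = cl.train_rbf_svm(X, y)
        Z = (X - model.means) / model.scales
        manual = np.array([
            sum(a * np.exp(-model.gamma * np.sum((z - sv) ** 2))
                for a, sv in zip(model.dual_coef, model.support_vectors))
            + model.intercept for z in Z])
        np.testing.assert_allclose(model.decision_values(X), manual, atol=1e-8)

    def test_json_round_trip_reproduces_decisions(self, tmp_path):
        from impactkit.io import read_json, write_json
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2))
        y = np.where(X[:, 0] > 0, "impact", "nonimpact")
        model = cl.train_rbf_svm(X, y, feature_names=["a", "b"])
        write_json(model.to_dict(), tmp_path / "m.json")
        back = cl.TrainedClassifier.from_dict(read_json(tmp_path / "m.json"))
        np.testing.assert_array_equal(back.decision_values(X),
                                      model.decision_values(X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cl.train_rbf_svm(np.zeros((4, 1)), ["impact"] * 4)


class TestLoocv:
    def test_separable_points_get_correct_signs(self):
        X = np.array([[-2.0], [-2.1], [2.0], [2.1]])
        y = np.array(["nonimpact", "nonimpact", "impact", "impact"])
        values, flagged = cl.loocv_decision_values(X, y)
        assert len(values) == 4 and not flagged.any()
        assert (np.sign(values) == np.where(y == "impact", 1, -1)).all()

    def test_single_class_training_fold_flagged_not_dropped(self):
        # holding out the only nonimpact leaves a one-class fold: flagged,
        # scored 0, and n conserved
        X = np.array([[-2.0], [2.0], [2.1]])
        y = np.array(["nonimpact", "impact", "impact"])
        values, flagged = cl.loocv_decision_values(X, y)
        assert len(values) == 3
        assert flagged.tolist() == [True, False, False]
        assert values[0] == 0.0 and values[1] > 0 and values[2] > 0

    def test_constant_feature_is_symmetric(self):
        X = np.ones((8, 1))
        y = np.array(["impact", "nonimpact"] * 4)
        values, _ = cl.loocv_decision_values(X, y)
        # held-out value cannot depend on which sample is left out beyond
        # its own label's effect on the training fold
        assert len(set(np.round(values[y == "impact"], 12))) == 1
        assert len(set(np.round(values[y == "nonimpact"], 12))) == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 2))
        y = np.where(X[:, 0] > 0, "impact", "nonimpact")
        values, _ = cl.loocv_decision_values(X, y)
        perm = rng.permutation(12)
        values_p, _ = cl.loocv_decision_values(X[perm], y[perm])
        np.testing.assert_allclose(values_p, values[perm], atol=1e-10)

    def test_no_standardisation_leakage(self):
        # an extreme held-out outlier must not shift the training fold's
        # standardisation: fold statistics computed with vs without the
        # held-out sample give different values
        X = np.array([[0.0], [0.1], [0.2], [0.3], [1000.0]])
        y = np.array(["nonimpact", "nonimpact", "impact", "impact", "impact"])
        values, _ = cl.loocv_decision_values(X, y)
        # manual fold for the outlier: train stats exclude it
        Xtr, ytr = X[:4], np.array([-1, -1, 1, 1])
        means, scales = Xtr.mean(0), Xtr.std(0)
        from sklearn.svm import SVC
        svc = SVC(C=1.0, gamma=1.0).fit((Xtr - means) / scales, ytr)
        expected = svc.decision_function((X[4:] - means) / scales)[0]
        assert values[4] == pytest.approx(expected, abs=1e-10)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            cl.loocv_decision_values(np.zeros((2, 1)), ["impact", "nonimpact"])

    @pytest.mark.parametrize("first_label", ["impact", "nonimpact"])
    def test_fast_fold_solver_matches_svc(self, first_label):
        # the libsvm fast path used inside LOOCV must reproduce the public
        # SVC decision function exactly, whichever class comes first
        from sklearn.svm import SVC
        rng = np.random.default_rng(9)
        for d in (1, 3):
            X = rng.normal(size=(40, d))
            y = np.where(X[:, 0] + rng.normal(0, 0.5, 40) > 0, 1, -1)
            if (y[0] > 0) != (first_label == "impact"):
                y = -y
            m, s = X.mean(0), X.std(0)
            Z = (X - m) / s
            gamma = 1.0 / d
            svc = SVC(C=1.0, gamma=gamma).fit(Z[:-1], y[:-1])
            expected = svc.decision_function(Z[-1:])[0]
            got = cl._fit_decision(Z[:-1], y[:-1], Z[-1:], gamma, 1.0)
            assert got == pytest.approx(expected, abs=1e-10)


def _brute_force_areas(scores, y):
    """Exhaustive threshold sweep over all unique scores."""
    scores = np.asarray(scores, float)
    ypos = np.asarray(y) == "impact"
    pts = []
    for thr in np.concatenate([[np.inf], np.unique(scores)[::-1], [-np.inf]]):
        pred = scores >= thr
        tp = (pred & ypos).sum(); fp = (pred & ~ypos).sum()
        pts.append((fp / (~ypos).sum(), tp / ypos.sum(),
                    tp / max(tp + fp, 1)))
    pts = np.array(pts)
    roc = np.trapezoid(pts[:, 1], pts[:, 0])
    # PR: recall-sorted, recall=0 endpoint at first precision
    rec, prec = pts[1:, 1], pts[1:, 2]
    rec = np.concatenate([[0.0], rec]); prec = np.concatenate([[prec[0]], prec])
    order = np.argsort(rec, kind="stable")
    return roc, np.trapezoid(prec[order], rec[order])


class TestCurves:
    def test_perfect_and_inverted_ranking(self):
        y = np.array(["impact"] * 3 + ["nonimpact"] * 3)
        rep = cl.roc_pr_curves([3, 2.5, 2, 1, 0.5, 0.1], y)
        assert rep.auc_roc == 1.0 and rep.auc_pr == 1.0
        rep = cl.roc_pr_curves([0.1, 0.5, 1, 2, 2.5, 3], y)
        assert rep.auc_roc == 0.0

    def test_random_scores_match_exhaustive_enumeration(self, rng):
        for trial in range(5):
            n = 20
            scores = np.round(rng.normal(size=n), 1)     # force ties
            y = np.where(rng.random(n) > 0.5, "impact", "nonimpact")
            if len(set(y)) < 2:
                continue
            rep = cl.roc_pr_curves(scores, y)
            roc, pr = _brute_force_areas(scores, y)
            assert rep.auc_roc == pytest.approx(roc, abs=1e-12)
            assert rep.auc_pr == pytest.approx(pr, abs=1e-12)

    def test_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(size=30)
        y = np.where(rng.random(30) > 0.5, "impact", "nonimpact")
        rep = cl.roc_pr_curves(scores, y)
        assert rep.auc_roc == pytest.approx(
            roc_auc_score(y == "impact", scores), abs=1e-12)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            cl.roc_pr_curves([1.0, 2.0], ["impact", "impact"])

    def test_baseline_is_definitional_equivalent(self, rng):
        peaks = rng.uniform(10, 60, 30)
        y = np.where(rng.random(30) > 0.5, "impact", "nonimpact")
        a = cl.baseline_threshold_curves(peaks, y)
        b = cl.roc_pr_curves(peaks, y)
        assert a.auc_roc == b.auc_roc and a.auc_pr == b.auc_pr

    def test_identical_distributions_near_chance(self, rng):
        peaks = np.concatenate([rng.uniform(10, 60, 200)] * 2)
        y = np.array(["impact"] * 200 + ["nonimpact"] * 200)
        rep = cl.baseline_threshold_curves(peaks, y)
        assert rep.auc_roc == pytest.approx(0.5, abs=0.1)


class TestForwardSelection:
    def test_single_perfect_feature_selected_then_stops(self):
        rng = np.random.default_rng(5)
        n = 24
        X = rng.normal(size=(n, 6))
        y = np.array(["impact"] * (n // 2) + ["nonimpact"] * (n // 2))
        X[:, 3] = np.where(y == "impact", 5.0, -5.0) + rng.normal(0, .1, n)
        selected, trace = cl.sequential_forward_selection(X, y)
        assert selected[0] == 3
        assert trace[0] == 0.0
        assert len(selected) == 1

    def test_tie_broken_toward_lower_index(self):
        rng = np.random.default_rng(6)
        n = 20
        y = np.array(["impact", "nonimpact"] * (n // 2))
        sep = np.where(y == "impact", 3.0, -3.0)
        X = np.column_stack([rng.normal(size=n), sep, sep.copy()])
        selected, _ = cl.sequential_forward_selection(X, y)
        assert selected[0] == 1

    def test_cost_trace_non_increasing(self):
        rng = np.random.default_rng(7)
        n = 30
        X = rng.normal(size=(n, 8))
        y = np.where(X[:, 0] + 0.5 * X[:, 4] + rng.normal(0, .8, n) > 0,
                     "impact", "nonimpact")
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        _, trace = cl.sequential_forward_selection(
            X, y, cl.ClassifierConfig(max_features=4))
        assert all(b <= a for a, b in zip(trace, trace[1:]))
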