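"""Pairwise SVM, decision rule, AUC, confidence intervals, McNemar comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize
from sklearn.metrics import roc_auc_score

from prknet.inference_eval import (
    TrainedModel,
    auc_confidence_interval,
    classify,
    cross_validate,
    decide,
    disagreement_counts,
    mcnemar_z,
    roc_auc,
    train_svm,
)
from prknet.rational_kernels import GramMatrix


def _psd_gram(rng, n, ids=None):
    f = rng.standard_normal((n, max(2, n // 2)))
    return GramMatrix(ids or [f"p{i}" for i in range(n)], f @ f.T)


class TestTrainSvm:
    def test_two_point_identity_kernel_separates(self):
        k = GramMatrix(["p", "q"], np.eye(2))
        model = train_svm(k, [1, -1], c=100.0)
        assert decide(model, k.values[0]) > 0 > decide(model, k.values[1])

    def test_separable_toy_classified_correctly(self, rng):
        # two well-separated clusters in feature space
        f = np.vstack([rng.standard_normal((5, 3)) + 4, rng.standard_normal((5, 3)) - 4])
        k = GramMatrix([f"p{i}" for i in range(10)], f @ f.T)
        labels = [1] * 5 + [-1] * 5
        model = train_svm(k, labels, c=10.0)
        preds = [classify(decide(model, row)) for row in k.values]
        assert preds == labels

    def test_dual_feasibility_and_box_constraints(self, rng):
        k = _psd_gram(rng, 12)
        labels = [1, -1] * 6
        c = 1.0
        model = train_svm(k, labels, c=c)
        assert np.all(model.alpha >= -1e-9)
        assert np.all(model.alpha <= c + 1e-9)
        assert abs(np.dot(model.alpha, model.labels)) < 1e-6

    def test_margin_support_vectors_satisfy_kkt(self, rng):
        k = _psd_gram(rng, 14)
        labels = [1, -1] * 7
        c = 1.0
        model = train_svm(k, labels, c=c)
        for i in range(14):
            f_i = decide(model, k.values[i])
            if 1e-6 < model.alpha[i] < c - 1e-6:  # on-margin support vector
                assert labels[i] * f_i == pytest.approx(1.0, abs=1e-3)

    def test_objective_matches_independent_qp(self, rng):
        k = _psd_gram(rng, 10)
        labels = np.array([1, -1] * 5, dtype=float)
        c = 1.0
        model = train_svm(k, labels.astype(int), c=c)
        q = k.values * np.outer(labels, labels)

        def neg_dual(a):
            return 0.5 * a @ q @ a - a.sum()

        res = optimize.minimize(
            neg_dual,
            x0=np.full(10, 0.5),
            jac=lambda a: q @ a - 1,
            bounds=[(0, c)] * 10,
            constraints=[{"type": "eq", "fun": lambda a: a @ labels}],
            method="SLSQP",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        assert res.success
        assert neg_dual(model.alpha) == pytest.approx(res.fun, abs=1e-4)

    def test_invalid_inputs_rejected(self, rng):
        k = _psd_gram(rng, 4)
        with pytest.raises(ValueError, match="C"):
            train_svm(k, [1, -1, 1, -1], c=0.0)
        with pytest.raises(ValueError, match="align"):
            train_svm(k, [1, -1, 1])
        with pytest.raises(ValueError, match="both classes"):
            train_svm(k, [1, 1, 1, 1])


class TestDecisionRule:
    def test_zero_score_maps_to_interacting(self):
        assert classify(0.0) == 1
        assert classify(3.0) == 1
        assert classify(-0.001) == -1

    def test_decision_matches_solver_decision_function(self, rng):
        from sklearn.svm import SVC

        k = _psd_gram(rng, 10)
        labels = [1, -1] * 5
        model = train_svm(k, labels, c=1.0)
        svc = SVC(kernel="precomputed", C=1.0).fit(k.values, labels)
        ours = [decide(model, row) for row in k.values]
        assert np.allclose(ours, svc.decision_function(k.values), atol=1e-9)

    def test_row_length_mismatch_rejected(self, rng):
        k = _psd_gram(rng, 4)
        model = train_svm(k, [1, -1, 1, -1], c=1.0)
        with pytest.raises(ValueError, match="length"):
            decide(model, [0.0, 1.0])

    def test_model_json_round_trip(self, rng, tmp_path):
        k = _psd_gram(rng, 6)
        model = train_svm(k, [1, -1] * 3, c=2.0)
        model.kernel_spec = {"prk_type": "tensor"}
        path = tmp_path / "model.json"
        model.to_json(path)
        again = TrainedModel.from_json(path)
        assert again.pair_ids == model.pair_ids
        assert np.allclose(again.alpha, model.alpha)
        assert again.b == pytest.approx(model.b)
        assert again.kernel_spec == {"prk_type": "tensor"}


class TestRocAuc:
    def test_perfect_and_inverted_rankings(self):
        assert roc_auc([3, 2, 1, 0], [1, 1, -1, -1]) == 1.0
        assert roc_auc([0, 1, 2, 3], [1, 1, -1, -1]) == 0.0

    def test_three_of_four_concordant(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, -1, 1, -1]) == pytest.approx(0.75)

    def test_ties_count_half(self):
        assert roc_auc([1.0, 1.0], [1, -1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            roc_auc([1.0, 2.0], [1, 1])

    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_trapezoidal_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        labels = np.where(rng.random(n) < 0.5, 1, -1)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 1, -1
        scores = rng.standard_normal(n)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class TestConfidenceInterval:
    def test_contains_point_estimate(self):
        lo, hi = auc_confidence_interval(0.7, 100, 100, 40)
        assert lo <= 0.7 <= hi

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (50, 500, 5000, 50_000):
            lo, hi = auc_confidence_interval(0.75, n, n, int(0.2 * 2 * n))
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)
        assert widths[-1] < 0.01

    def test_degenerate_point_estimate_keeps_positive_width(self):
        lo, hi = auc_confidence_interval(1.0, 50, 50, 5)
        assert hi == 1.0 and lo < 1.0

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            auc_confidence_interval(0.5, 10, 10, 2, level=1.5)

    def test_coverage_on_simulated_scores(self):
        # normal score model with true AUC = Phi(1/sqrt(2)); nominal 95%
        rng = np.random.default_rng(42)
        n = 200
        true_auc = 0.7602499389065233
        hits = 0
        for _ in range(500):
            pos = rng.standard_normal(n) + 1.0
            neg = rng.standard_normal(n)
            scores = np.concatenate([pos, neg])
            labels = np.array([1] * n + [-1] * n)
            auc = roc_auc(scores, labels)
            errors = int((np.where(scores >= 0.5, 1, -1) != labels).sum())
            lo, hi = auc_confidence_interval(auc, n, n, errors)
            hits += lo <= true_auc <= hi
        assert hits / 500 >= 0.90


class TestCrossValidation:
    def test_duplicated_dataset_gives_identical_fold_aucs(self, rng):
        # every positive is a copy of u, every negative a copy of v: any
        # stratified split sees the same geometry, so fold AUCs coincide
        u, v = rng.standard_normal(3) + 2, rng.standard_normal(3) - 2
        f2 = np.vstack([np.tile(u, (8, 1)), np.tile(v, (8, 1))])
        k = GramMatrix([f"p{i}" for i in range(16)], f2 @ f2.T)
        labels = [1] * 8 + [-1] * 8
        report = cross_validate(k, labels, folds=2, seed=0)
        assert report.fold_aucs[0] == pytest.approx(report.fold_aucs[1])

    def test_mean_bounded_by_fold_extremes(self, rng):
        k = _psd_gram(rng, 40)
        labels = [1, -1] * 20
        report = cross_validate(k, labels, folds=5, seed=3)
        assert min(report.fold_aucs) <= report.mean_auc <= max(report.fold_aucs)

    def test_bit_reproducible_under_seed(self, rng):
        k = _psd_gram(rng, 30)
        labels = [1, -1] * 15
        r1 = cross_validate(k, labels, folds=5, seed=7)
        r2 = cross_validate(k, labels, folds=5, seed=7)
        assert r1.fold_aucs == r2.fold_aucs
        assert r1.n_errors == r2.n_errors

    def test_infeasible_stratification_rejected(self, rng):
        k = _psd_gram(rng, 8)
        labels = [1] * 6 + [-1] * 2
        with pytest.raises(ValueError, match="stratify"):
            cross_validate(k, labels, folds=5, seed=0)


class TestMcNemar:
    def test_equal_disagreements_give_zero(self):
        assert mcnemar_z(5, 5) == 0.0

    def test_signed_value(self):
        assert mcnemar_z(8, 2) == pytest.approx(6 / np.sqrt(10))

    def test_antisymmetry(self):
        for a, b in [(3, 9), (1, 0), (20, 5)]:
            assert mcnemar_z(a, b) == pytest.approx(-mcnemar_z(b, a))

    def test_positive_z_means_b_better(self):
        # B corrects 8 of A's failures, A corrects only 2 of B's -> B better
        assert mcnemar_z(8, 2) > 0

    def test_sign_agrees_with_exact_binomial_direction(self):
        from scipy.stats import binomtest

        n_fs, n_sf = 8, 2
        z = mcnemar_z(n_fs, n_sf)
        p_greater = binomtest(n_fs, n_fs + n_sf, 0.5, alternative="greater").pvalue
        assert (z > 0) == (p_greater < 0.5)

    def test_continuity_correction(self):
        assert mcnemar_z(8, 2, continuity=True) == pytest.approx(5 / np.sqrt(10))
        assert mcnemar_z(2, 8, continuity=True) == pytest.approx(-5 / np.sqrt(10))

    def test_undefined_when_no_disagreement(self):
        with pytest.raises(ValueError, match="undefined"):
            mcnemar_z(0, 0)


class TestDisagreementCounts:
    def test_identical_predictions(self):
        preds = [1, -1, 1]
        assert disagreement_counts(preds, preds, [1, 1, -1]) == (0, 0)

    def test_total_disagreement(self):
        truth = [1] * 7
        assert disagreement_counts([-1] * 7, [1] * 7, truth) == (7, 0)

    def test_matches_brute_force(self, rng):
        a = rng.choice([1, -1], size=50)
        b = rng.choice([1, -1], size=50)
        t = rng.choice([1, -1], size=50)
        n_fs = sum(1 for i in range(50) if a[i] != t[i] and b[i] == t[i])
        n_sf = sum(1 for i in range(50) if a[i] == t[i] and b[i] != t[i])
        assert disagreement_counts(a, b, t) == (n_fs, n_sf)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            disagreement_counts([1], [1, -1], [1, -1])
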