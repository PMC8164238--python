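import itertools

import numpy as np
import pytest

import acpsmo as a
from acpsmo.smo import SmoTrainer
from conftest import oracle_bias, qp_dual_oracle, random_tiny_problem

TWO_POINT = a.TrainingProblem(
    np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]), C=10.0
)


class TestKernels:
    def test_linear_is_dot_product(self):
        assert a.kernel_eval([1.0, 0.0], [1.0, 0.0], a.KernelSpec("linear")) == 1.0
        assert a.kernel_eval([1.0, 2.0], [3.0, 4.0], a.KernelSpec("linear")) == 11.0

    def test_rbf_self_similarity_and_closed_form(self):
        rbf = a.KernelSpec("rbf", gamma=1.0)
        assert a.kernel_eval([0.3, -2.0], [0.3, -2.0], rbf) == 1.0
        assert a.kernel_eval([0.0], [1.0], rbf) == pytest.approx(np.exp(-1.0))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(a.FeatureMismatchError):
            a.kernel_eval([1.0], [1.0, 2.0], a.KernelSpec("linear"))

    def test_matrix_agrees_with_scalar_eval(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        for spec in (a.KernelSpec("linear"), a.KernelSpec("rbf", gamma=0.7)):
            K = a.kernel_matrix(X, X, spec)
            for i, j in itertools.product(range(5), repeat=2):
                assert K[i, j] == pytest.approx(a.kernel_eval(X[i], X[j], spec))
            assert np.allclose(K, K.T)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            a.KernelSpec("poly")
        with pytest.raises(ValueError):
            a.KernelSpec("rbf", gamma=-1.0)


class TestDualObjective:
    def test_zero_multipliers_give_zero(self):
        assert a.dual_objective(TWO_POINT, np.zeros(2)) == 0.0

    def test_hand_evaluated_two_point_value(self):
        # sum(l) - 0.5*(0.5*1 + 0.5*(-1))... with K=[[1,-1],[-1,1]]:
        # 1 - 0.5 * (0.5+0.5)^2 = 0.5
        assert a.dual_objective(TWO_POINT, np.array([0.5, 0.5])) == pytest.approx(0.5)

    def test_feasible_points_bounded_by_grid_optimum(self):
        # exhaustive grid over the constraint line of the two-point dual
        best = max(
            a.dual_objective(TWO_POINT, np.array([t, t])) for t in np.arange(0, 10.01, 0.01)
        )
        assert best == pytest.approx(0.5)
        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.uniform(0, 10)
            assert a.dual_objective(TWO_POINT, np.array([t, t])) <= best + 1e-12


class TestTakeStep:
    def test_two_point_single_step_reaches_optimum(self):
        t = SmoTrainer(TWO_POINT, debug=True)
        assert t.take_step(0, 1)
        assert t.alphas == pytest.approx([0.5, 0.5])
        assert t.b == pytest.approx(0.0, abs=1e-12)

    def test_same_index_rejected(self):
        t = SmoTrainer(TWO_POINT)
        assert not t.take_step(0, 0)

    def test_optimal_pair_is_a_fixed_point(self):
        t = SmoTrainer(TWO_POINT, debug=True)
        t.take_step(0, 1)
        obj = t.current_objective()
        assert not t.take_step(0, 1)
        assert t.current_objective() == obj


class TestTrainSmo:
    def test_two_point_analytic_solution(self):
        model = a.train_smo(TWO_POINT, debug=True)
        assert model.lambdas == pytest.approx([0.5, 0.5])
        assert model.bias == pytest.approx(0.0, abs=1e-9)
        assert model.w == pytest.approx([1.0])
        assert a.decision_value(model, np.array([0.0])) == pytest.approx(0.0, abs=1e-9)
        # margin points sit at +-1
        assert a.decision_value(model, np.array([1.0])) == pytest.approx(1.0)
        assert a.decision_value(model, np.array([-1.0])) == pytest.approx(-1.0)

    def test_xor_like_rbf_problem_uses_all_support_vectors(self):
        X = np.array([[-3.0], [-1.0], [1.0], [3.0]])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        prob = a.TrainingProblem(X, y, C=10.0, kernel=a.KernelSpec("rbf", gamma=1.0))
        model = a.train_smo(prob, debug=True)
        assert len(model.support_index) == 4
        pred = np.sign(a.decision_values(model, X))
        assert np.array_equal(pred, y)
        ref_obj, _ = qp_dual_oracle(X, y, 10.0, prob.kernel)
        assert model.dual_objective == pytest.approx(ref_obj, abs=1e-3)

    def test_separable_blobs_match_sklearn_dual(self):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(2.0, 1.0, (100, 2)), rng.normal(-2.0, 1.0, (100, 2))])
        y = np.r_[np.ones(100), -np.ones(100)]
        prob = a.TrainingProblem(X, y, C=1.0)
        model = a.train_smo(prob)
        clf = sklearn_svm.SVC(kernel="linear", C=1.0, tol=1e-6).fit(X, y)
        lam_ref = np.zeros(len(y))
        lam_ref[clf.support_] = np.abs(clf.dual_coef_[0])
        ref_obj = a.dual_objective(prob, lam_ref)
        assert model.dual_objective == pytest.approx(ref_obj, abs=1e-3)
        assert np.array_equal(
            np.sign(a.decision_values(model, X)), np.sign(clf.decision_function(X))
        )

    def test_single_class_or_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            a.TrainingProblem(np.ones((3, 1)), np.ones(3))
        with pytest.raises(ValueError):
            a.TrainingProblem(np.array([[np.nan], [1.0]]), np.array([1.0, -1.0]))

    def test_feasibility_and_monotone_objective_on_random_problems(self):
        rng = np.random.default_rng(100)
        for trial in range(10):
            X, y, C, kernel = random_tiny_problem(rng, trial)
            t = SmoTrainer(a.TrainingProblem(X, y, C=C, kernel=kernel, seed=trial), debug=True)
            t.solve()  # debug mode asserts monotone objective + feasibility per step
            assert abs(float(t.alphas @ y)) <= 1e-9
            assert (t.alphas >= 0).all() and (t.alphas <= C + 1e-12).all()
            assert t.objective_trace == sorted(t.objective_trace)

    def test_permutation_invariance_on_margin_separated_toy(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(3.0, 0.5, (20, 2)), rng.normal(-3.0, 0.5, (20, 2))])
        y = np.r_[np.ones(20), -np.ones(20)]
        model = a.train_smo(a.TrainingProblem(X, y, C=1.0))
        perm = rng.permutation(40)
        model_p = a.train_smo(a.TrainingProblem(X[perm], y[perm], C=1.0))
        assert model_p.dual_objective == pytest.approx(model.dual_objective, abs=1e-6)
        Q = rng.normal(size=(30, 2))
        assert np.array_equal(
            np.sign(a.decision_values(model, Q)), np.sign(a.decision_values(model_p, Q))
        )

    def test_incremental_w_matches_recomputed_expansion(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 4))
        y = np.r_[np.ones(15), -np.ones(15)]
        model = a.train_smo(a.TrainingProblem(X, y, C=2.0, seed=1))
        w_direct = (model.lambdas * model.y) @ model.x
        assert model.w == pytest.approx(w_direct, abs=1e-9)
        for q in rng.normal(size=(5, 4)):
            assert a.decision_value(model, q) == pytest.approx(
                float(model.w @ q) + model.bias, abs=1e-9
            )


class TestPlatt:
    def test_symmetric_decisions_give_half_probability_at_zero(self):
        f = np.r_[np.ones(50), -np.ones(50)]
        y = np.r_[np.ones(50), -np.ones(50)]
        A, B = a.fit_platt(f, y)
        p0 = 1.0 / (1.0 + np.exp(B))
        assert p0 == pytest.approx(0.5, abs=1e-6)

    def test_confident_correct_decisions_give_high_probabilities(self):
        rng = np.random.default_rng(3)
        f = np.r_[rng.uniform(3, 5, 100), rng.uniform(-5, -3, 100)]
        y = np.r_[np.ones(100), -np.ones(100)]
        A, B = a.fit_platt(f, y)
        p_pos = 1.0 / (1.0 + np.exp(A * 4.0 + B))
        assert p_pos > 0.9

    def test_recovers_generating_sigmoid_parameters(self):
        rng = np.random.default_rng(19)
        A_true, B_true = -2.0, 0.3
        f = rng.uniform(-4, 4, 50_000)
        p = 1.0 / (1.0 + np.exp(A_true * f + B_true))
        y = np.where(rng.uniform(size=f.size) < p, 1.0, -1.0)
        A, B = a.fit_platt(f, y)
        assert A == pytest.approx(A_true, rel=0.05)
        assert B == pytest.approx(B_true, abs=abs(A_true) * 0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            a.fit_platt(np.r_[1.0, 2.0], np.r_[1.0, 1.0])


class TestPredictProba:
    def make_calibrated(self):
        rng = np.random.default_rng(23)
        X = np.vstack([rng.normal(1.5, 1.0, (40, 2)), rng.normal(-1.5, 1.0, (40, 2))])
        y = np.r_[np.ones(40), -np.ones(40)]
        return a.calibrate(a.train_smo(a.TrainingProblem(X, y, C=1.0))), X

    def test_probabilities_sum_to_one_and_track_decisions(self):
        model, X = self.make_calibrated()
        proba = a.predict_proba(model, X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        f = a.decision_values(model, X)
        order = np.argsort(f)
        assert np.all(np.diff(proba[order, 0]) >= -1e-12)

    def test_uncalibrated_model_rejected(self):
        model = a.train_smo(TWO_POINT)
        with pytest.raises(a.NotCalibratedError):
            a.predict_proba(model, np.array([[0.0]]))
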