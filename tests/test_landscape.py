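import numpy as np
import pytest

import synmaint as sm
from synmaint.landscape import TeacherStudentLoss, dense_hessian


def _naive_task_error(task, w):
    """Independent per-input loop oracle for the mean-squared maintenance error."""
    student = task.teacher.with_flat_weights(w)
    total = 0.0
    for u, y0 in zip(task.suite.inputs, task.teacher_outputs):
        diff = sm.forward(student, u) - y0
        total += float(diff @ diff)
    return total / task.suite.n_inputs


class TestTaskError:
    def test_zero_at_teacher(self, small_task):
        assert sm.task_error(small_task, small_task.teacher.flat_weights()) == 0.0

    def test_linear_hand_example(self):
        teacher = sm.LayeredNetwork((1, 1), [np.array([[1.0]])], "linear")
        suite = sm.InputSuite(np.array([[1.0], [-1.0]]))
        task = sm.TeacherStudentTask(teacher, suite)
        # student weight 2: errors (2-1)^2 and (-2+1)^2, mean 1.0
        assert sm.task_error(task, np.array([2.0])) == pytest.approx(1.0)

    def test_matches_naive_loop(self, small_task, rng):
        w = small_task.teacher.flat_weights() + 0.3 * rng.standard_normal(small_task.n_params)
        fast = sm.task_error(small_task, w)
        assert fast == pytest.approx(_naive_task_error(small_task, w), abs=1e-12)

    def test_shape_error(self, small_task):
        with pytest.raises(ValueError):
            sm.task_error(small_task, np.zeros(3))


class TestGradient:
    def test_quadratic_gradient_at_minimum_is_zero(self, diag123):
        loss = sm.QuadraticLoss(diag123)
        assert np.allclose(loss.gradient(np.zeros(3)), 0.0)

    def test_quadratic_diag_example(self):
        quad = sm.QuadraticLandscape(np.array([1.0, 4.0]), np.eye(2), np.zeros(2))
        g = sm.QuadraticLoss(quad).gradient(np.array([1.0, 1.0]))
        assert np.allclose(g, [1.0, 4.0])

    def test_network_gradient_vs_finite_difference(self, rng):
        task = sm.make_task(layer_sizes=(12, 20, 10), n_inputs=50, seed=11)
        loss = TeacherStudentLoss(task)
        w = task.teacher.flat_weights() + 0.2 * rng.standard_normal(task.n_params)
        g = loss.gradient(w)
        h = 1e-5
        idx = rng.choice(task.n_params, size=60, replace=False)
        for i in idx:
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            fd = (loss.evaluate(wp) - loss.evaluate(wm)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-10)

    def test_descent_direction_property(self, small_task, rng):
        loss = TeacherStudentLoss(small_task)
        for _ in range(5):
            w = small_task.teacher.flat_weights() + 0.5 * rng.standard_normal(small_task.n_params)
            g = loss.gradient(w)
            ghat = g / np.linalg.norm(g)
            assert loss.evaluate(w - 1e-4 * ghat) < loss.evaluate(w)


class TestHessianVector:
    def test_quadratic_exact(self, diag123):
        loss = sm.QuadraticLoss(diag123)
        hv = loss.hessian_vector(np.ones(3), np.array([0.0, 1.0, 0.0]))
        assert np.allclose(hv, [0.0, 2.0, 0.0])

    def test_zero_direction_returns_zero(self, toy_task):
        loss = TeacherStudentLoss(toy_task)
        w = toy_task.teacher.flat_weights()
        assert np.allclose(loss.hessian_vector(w, np.zeros(w.size)), 0.0)

    def test_linearity_in_direction(self, small_task, rng):
        loss = TeacherStudentLoss(small_task)
        w = small_task.teacher.flat_weights() + 0.1 * rng.standard_normal(small_task.n_params)
        a = rng.standard_normal(w.size)
        b = rng.standard_normal(w.size)
        lhs = loss.hessian_vector(w, 2.0 * a + b)
        rhs = 2.0 * loss.hessian_vector(w, a) + loss.hessian_vector(w, b)
        assert np.allclose(lhs, rhs, atol=1e-6 * (1 + np.abs(rhs).max()))

    def test_matches_dense_fd_hessian_on_toy_net(self, toy_task, rng):
        loss = TeacherStudentLoss(toy_task)
        w = toy_task.teacher.flat_weights() + 0.3 * rng.standard_normal(toy_task.n_params)
        n = toy_task.n_params
        h = 1e-5
        H = np.empty((n, n))
        for i in range(n):  # dense Hessian column-by-column from gradient differences
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            H[:, i] = (loss.gradient(wp) - loss.gradient(wm)) / (2 * h)
        assert np.abs(H - H.T).max() < 1e-3 * (1 + np.abs(H).max())  # symmetry
        v = rng.standard_normal(n)
        assert np.allclose(loss.hessian_vector(w, v), H @ v,
                           rtol=1e-3, atol=1e-6 * np.abs(H @ v).max() + 1e-9)


class TestQValue:
    def test_identity_hessian(self):
        quad = sm.make_quadratic(np.ones(4), np.zeros(4), seed=0)
        loss = sm.QuadraticLoss(quad)
        assert sm.q_value(loss, np.zeros(4), np.array([1.0, 2.0, -1.0, 0.5])) == pytest.approx(1.0)

    def test_diag_example(self, diag123):
        loss = sm.QuadraticLoss(diag123)
        assert sm.q_value(loss, np.zeros(3), np.array([1.0, 1.0, 0.0])) == pytest.approx(1.5)

    def test_scale_invariance_on_network(self, small_task, rng):
        loss = TeacherStudentLoss(small_task)
        w = small_task.teacher.flat_weights() + 0.2 * rng.standard_normal(small_task.n_params)
        v = rng.standard_normal(w.size)
        assert sm.q_value(loss, w, 2.0 * v) == pytest.approx(sm.q_value(loss, w, v), abs=1e-10)

    def test_zero_direction_rejected(self, diag123):
        with pytest.raises(ValueError):
            sm.q_value(sm.QuadraticLoss(diag123), np.zeros(3), np.zeros(3))


class TestHutchinson:
    def test_identity_exact_for_any_probe(self):
        quad = sm.make_quadratic(np.ones(7), np.zeros(7), seed=0)
        loss = sm.QuadraticLoss(quad)
        # Rademacher v has v^T I v = N exactly, so any probe count is exact
        assert sm.hutchinson_trace(loss, np.zeros(7), n_probes=3, seed=0) == pytest.approx(7.0)

    def test_diag123_exact_when_axis_aligned(self, diag123):
        # for diagonal H each Rademacher probe gives v^T H v = Tr(H) exactly
        loss = sm.QuadraticLoss(diag123)
        est = sm.hutchinson_trace(loss, np.zeros(3), n_probes=100, seed=4)
        assert est == pytest.approx(6.0, abs=1e-12)

    def test_linearity_under_shared_probes(self, rng):
        basis = sm.make_quadratic(np.ones(6), np.zeros(6), seed=9).basis
        l1 = np.linspace(1, 2, 6)
        l2 = np.linspace(0.5, 3, 6)
        q1 = sm.QuadraticLandscape(l1, basis, np.zeros(6))
        q2 = sm.QuadraticLandscape(l2, basis, np.zeros(6))
        q12 = sm.QuadraticLandscape(l1 + l2, basis, np.zeros(6))
        args = dict(w=np.zeros(6), n_probes=50, seed=77)
        est1 = sm.hutchinson_trace(sm.QuadraticLoss(q1), **args)
        est2 = sm.hutchinson_trace(sm.QuadraticLoss(q2), **args)
        est12 = sm.hutchinson_trace(sm.QuadraticLoss(q12), **args)
        assert est12 == pytest.approx(est1 + est2, abs=1e-10)

    def test_unbiased_on_rotated_hessian(self, aniso_quad):
        loss = sm.QuadraticLoss(aniso_quad)
        est = sm.hutchinson_trace(loss, np.zeros(30), n_probes=4000, seed=8)
        # 3 standard errors of the probe sample
        probes = [sm.hutchinson_trace(loss, np.zeros(30), 1, seed=s) for s in range(200)]
        se = np.std(probes, ddof=1) / np.sqrt(4000)
        assert abs(est - aniso_quad.trace) < max(3 * se, 0.05 * aniso_quad.trace)


class TestClassifyTrainedState:
    @pytest.mark.parametrize(
        "eigs,label",
        [
            ([1.0, 2.0, 3.0], "highly_trained"),
            ([2.0, -1.0], "partially_trained"),
            ([-1.0, -2.0], "neither"),
        ],
    )
    def test_quadratic_labels(self, eigs, label):
        quad = sm.QuadraticLandscape(np.array(eigs), np.eye(len(eigs)), np.zeros(len(eigs)))
        out = sm.classify_trained_state(sm.QuadraticLoss(quad), np.zeros(len(eigs)))
        assert out.label == label
        assert out.trace == pytest.approx(sum(eigs))

    def test_supplied_estimates_bypass_dense_hessian(self):
        quad = sm.make_quadratic(np.ones(3), np.zeros(3), seed=0)
        out = sm.classify_trained_state(
            sm.QuadraticLoss(quad), np.zeros(3), trace=5.0, min_eigenvalue=-2.0
        )
        assert out.label == "partially_trained"

    def test_oversize_without_estimates_raises(self):
        class Big:
            n_params = 5000

            def evaluate(self, w):
                return 0.0

            def gradient(self, w):
                return np.zeros(5000)

            def hessian_vector(self, w, v):
                return np.zeros(5000)

        with pytest.raises(ValueError):
            sm.classify_trained_state(Big(), np.zeros(5000))


class TestExpectedErrorGrowth:
    def test_unbiased_fluctuations_grow_error_by_trace_over_2N(self, aniso_quad, rng):
        """Monte-Carlo E[F(w+de) - F(w)] = ||de||^2 Tr(H) / (2N) on a quadratic."""
        loss = sm.QuadraticLoss(aniso_quad)
        w = rng.standard_normal(30) * 0.5
        f0 = loss.evaluate(w)
        mag = 0.2
        deltas = []
        for k in range(4000):
            de = sm.fluctuation_step(30, mag, seed=rng)
            deltas.append(loss.evaluate(w + de) - f0)
        deltas = np.asarray(deltas)
        expect = mag**2 * aniso_quad.trace / (2 * 30)
        se = deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs(deltas.mean() - expect) < 3 * se
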