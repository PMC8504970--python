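"""Loss landscapes: task error, gradients, Hessian-vector products, curvature.

Two loss handles share one interface: :class:`TeacherStudentLoss` evaluates the
mean-squared output mismatch of a student network against a frozen teacher and
computes its gradient by hand-derived reverse-mode differentiation (plain
backpropagation, full batch over the input suite); :class:`QuadraticLoss` wraps
an analytic quadratic surface where all derivatives are exact.

The central geometric quantity is the normalised Hessian quadratic form

    Q_w[v] = v_hat^T  grad^2 F[w]  v_hat,

the upward curvature of the landscape in direction v at state w.  It depends
only on the direction of v, not its magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .task_models import (
    LayeredNetwork,
    QuadraticLandscape,
    TeacherStudentTask,
    _as_rng,
    sigmoid,
)

__all__ = [
    "LossHandle",
    "TeacherStudentLoss",
    "QuadraticLoss",
    "TrainedStateLabel",
    "as_loss",
    "task_error",
    "gradient",
    "hessian_vector",
    "q_value",
    "hutchinson_trace",
    "dense_hessian",
    "classify_trained_state",
]


@runtime_checkable
class LossHandle(Protocol):
    """Minimal surface a loss must expose: value, gradient, Hessian-vector."""

    n_params: int

    def evaluate(self, w: np.ndarray) -> float: ...

    def gradient(self, w: np.ndarray) -> np.ndarray: ...

    def hessian_vector(self, w: np.ndarray, v: np.ndarray) -> np.ndarray: ...


def _check_shape(w: np.ndarray, n: int, name: str = "w") -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"{name} has shape {w.shape}, expected ({n},)")
    return w


class TeacherStudentLoss:
    """Mean-squared maintenance error of a student against a frozen teacher.

    F(w) = (1/|U|) * sum_u || y(w, u) - y(w0, u) ||^2

    where y(w, u) is the student output and y(w0, u) the cached teacher output.
    The gradient is exact (analytic backpropagation); Hessian-vector products
    use a central difference of two analytic gradients with step
    h = 1e-5 * (1 + ||w||_inf), which keeps relative truncation error stable
    across weight scales.
    """

    def __init__(self, task: TeacherStudentTask):
        self.task = task
        self.net = task.teacher
        self._shapes = [w.shape for w in self.net.weights]
        self.n_params = self.net.n_params
        self._X = task.suite.inputs
        self._Y0 = task.teacher_outputs
        self._n = task.suite.n_inputs

    def _unflatten(self, w: np.ndarray) -> list[np.ndarray]:
        mats, i = [], 0
        for shape in self._shapes:
            size = shape[0] * shape[1]
            mats.append(w[i : i + size].reshape(shape))
            i += size
        return mats

    def _forward_cached(self, mats):
        a = self._X
        acts = [a]
        for wk in mats:
            a = a @ wk.T
            if self.net.activation == "sigmoid":
                a = sigmoid(a)
            acts.append(a)
        return acts

    def evaluate(self, w: np.ndarray) -> float:
        w = _check_shape(w, self.n_params)
        acts = self._forward_cached(self._unflatten(w))
        diff = acts[-1] - self._Y0
        return float(np.einsum("ij,ij->", diff, diff) / self._n)

    def gradient(self, w: np.ndarray) -> np.ndarray:
        w = _check_shape(w, self.n_params)
        mats = self._unflatten(w)
        acts = self._forward_cached(mats)
        # dF/dy for the squared-error loss averaged over the suite
        delta = 2.0 * (acts[-1] - self._Y0) / self._n
        sig = self.net.activation == "sigmoid"
        grads = [None] * len(mats)
        for k in range(len(mats) - 1, -1, -1):
            if sig:
                a = acts[k + 1]
                delta = delta * a * (1.0 - a)
            grads[k] = delta.T @ acts[k]
            if k > 0:
                delta = delta @ mats[k]
        return np.concatenate([g.ravel() for g in grads])

    def hessian_vector(self, w: np.ndarray, v: np.ndarray) -> np.ndarray:
        w = _check_shape(w, self.n_params)
        v = _check_shape(v, self.n_params, "v")
        norm = np.linalg.norm(v)
        if norm == 0.0:
            return np.zeros_like(v)
        vhat = v / norm
        h = 1e-5 * (1.0 + np.abs(w).max())
        gp = self.gradient(w + h * vhat)
        gm = self.gradient(w - h * vhat)
        return (gp - gm) * (norm / (2.0 * h))


class QuadraticLoss:
    """F(w) = 1/2 (w - w*)^T H (w - w*); every derivative is exact."""

    def __init__(self, landscape: QuadraticLandscape):
        self.landscape = landscape
        self.n_params = landscape.n_params

    def evaluate(self, w: np.ndarray) -> float:
        w = _check_shape(w, self.n_params)
        c = self.landscape.basis.T @ (w - self.landscape.minimiser)
        return float(0.5 * np.sum(self.landscape.eigenvalues * c * c))

    def gradient(self, w: np.ndarray) -> np.ndarray:
        w = _check_shape(w, self.n_params)
        c = self.landscape.basis.T @ (w - self.landscape.minimiser)
        return self.landscape.basis @ (self.landscape.eigenvalues * c)

    def hessian_vector(self, w: np.ndarray, v: np.ndarray) -> np.ndarray:
        v = _check_shape(v, self.n_params, "v")
        c = self.landscape.basis.T @ v
        return self.landscape.basis @ (self.landscape.eigenvalues * c)


def as_loss(obj) -> LossHandle:
    """Coerce a task, landscape, or existing loss handle to a LossHandle."""
    if isinstance(obj, TeacherStudentTask):
        return TeacherStudentLoss(obj)
    if isinstance(obj, QuadraticLandscape):
        return QuadraticLoss(obj)
    if isinstance(obj, LossHandle):
        return obj
    raise TypeError(f"cannot interpret {type(obj).__name__} as a loss")


def task_error(task: TeacherStudentTask, student_weights: np.ndarray) -> float:
    """Mean squared error of the student in recreating the teacher's outputs."""
    return TeacherStudentLoss(task).evaluate(student_weights)


def gradient(loss: LossHandle, w: np.ndarray) -> np.ndarray:
    return loss.gradient(np.asarray(w, dtype=float))


def hessian_vector(loss: LossHandle, w: np.ndarray, v: np.ndarray) -> np.ndarray:
    return loss.hessian_vector(np.asarray(w, dtype=float), np.asarray(v, dtype=float))


def q_value(loss: LossHandle, w: np.ndarray, v: np.ndarray) -> float:
    """Directional curvature Q_w[v] = v_hat^T H(w) v_hat (scale invariant)."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise ValueError("curvature of the zero direction is undefined")
    vhat = v / norm
    return float(vhat @ loss.hessian_vector(np.asarray(w, dtype=float), vhat))


def hutchinson_trace(loss: LossHandle, w: np.ndarray, n_probes: int, seed=0) -> float:
    """Unbiased Monte-Carlo estimate of Tr(H(w)) from Rademacher probes."""
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = _as_rng(seed)
    w = np.asarray(w, dtype=float)
    total = 0.0
    for _ in range(n_probes):
        v = rng.integers(0, 2, size=loss.n_params) * 2.0 - 1.0
        total += float(v @ loss.hessian_vector(w, v))
    return total / n_probes


def dense_hessian(loss: LossHandle, w: np.ndarray) -> np.ndarray:
    """Full Hessian built column-by-column from Hessian-vector products."""
    n = loss.n_params
    if n > 2000:
        raise ValueError(f"refusing dense Hessian for N={n} > 2000")
    w = np.asarray(w, dtype=float)
    if isinstance(loss, QuadraticLoss):
        return loss.landscape.hessian
    cols = np.empty((n, n))
    eye = np.eye(n)
    for i in range(n):
        cols[:, i] = loss.hessian_vector(w, eye[i])
    return cols


@dataclass
class TrainedStateLabel:
    """Curvature-based classification of a network state.

    ``partially_trained``: the Hessian trace is positive, so unbiased
    fluctuations increase task error in expectation.  ``highly_trained``: the
    Hessian is additionally positive semidefinite, so every direction curves
    upward (always true near a local minimum).
    """

    label: str  # highly_trained | partially_trained | neither
    trace: float
    min_eigenvalue: float


def classify_trained_state(
    loss: LossHandle,
    w: np.ndarray,
    trace: float | None = None,
    min_eigenvalue: float | None = None,
) -> TrainedStateLabel:
    """Label a state by its curvature structure.

    For small problems (N <= 2000) the dense Hessian is formed; otherwise the
    caller must supply trace and minimum-eigenvalue estimates.  The positive
    semidefinite check tolerates eigenvalues down to -1e-8 times the spectral
    norm, absorbing finite-difference noise.
    """
    if trace is None or min_eigenvalue is None:
        if loss.n_params > 2000:
            raise ValueError(
                "N too large for a dense Hessian; supply trace and min_eigenvalue"
            )
        H = dense_hessian(loss, w)
        H = 0.5 * (H + H.T)
        eig = np.linalg.eigvalsh(H)
        trace = float(eig.sum())
        min_eigenvalue = float(eig[0])
        spectral = float(np.abs(eig).max()) if eig.size else 0.0
    else:
        spectral = abs(min_eigenvalue) + abs(trace)
    psd_tol = -1e-8 * max(spectral, 1e-300)
    if trace > 0 and min_eigenvalue >= psd_tol:
        label = "highly_trained"
    elif trace > 0:
        label = "partially_trained"
    else:
        label = "neither"
    return TrainedStateLabel(label=label, trace=trace, min_eigenvalue=min_eigenvalue)
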