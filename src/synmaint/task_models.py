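"""Synthetic task generators: feedforward networks, input suites, quadratic landscapes.

The simulated system is a small rate-based feedforward network maintaining a
previously learned input-output mapping.  The "teacher" is a frozen copy of the
network at time zero; the "student" is the same architecture whose weights drift
under plasticity.  Quadratic landscapes with a chosen eigen-spectrum provide an
analytically tractable test bed where gradients and curvature are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import ortho_group

__all__ = [
    "LayeredNetwork",
    "InputSuite",
    "TeacherStudentTask",
    "QuadraticLandscape",
    "make_layered_network",
    "make_input_suite",
    "make_task",
    "make_quadratic",
    "forward",
    "network_to_json",
    "network_from_json",
    "suite_to_json",
    "suite_from_json",
]

_ACTIVATIONS = ("linear", "sigmoid")


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically safe logistic function 1 / (1 + exp(-x))."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LayeredNetwork:
    """Fully connected feedforward rate network without biases.

    ``layer_sizes`` lists the input dimension followed by the width of every
    layer; ``weights[k]`` has shape (fan_out, fan_in) so that a layer computes
    ``act(W @ r_prev)``.  The activation (identity or logistic) is applied at
    every layer, including the output layer.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    activation: str = "sigmoid"

    def __post_init__(self):
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        for k, w in enumerate(self.weights):
            expect = (self.layer_sizes[k + 1], self.layer_sizes[k])
            if w.shape != expect:
                raise ValueError(
                    f"layer {k} weight shape {w.shape} != expected {expect}"
                )

    @property
    def input_dim(self) -> int:
        return self.layer_sizes[0]

    @property
    def output_dim(self) -> int:
        return self.layer_sizes[-1]

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights)

    def flat_weights(self) -> np.ndarray:
        """Flatten layer-major, row-major within each layer (fixed convention)."""
        return np.concatenate([w.ravel() for w in self.weights])

    def unflatten(self, flat: np.ndarray) -> list[np.ndarray]:
        """Inverse of :meth:`flat_weights`; exact round trip."""
        flat = np.asarray(flat, dtype=float)
        if flat.shape != (self.n_params,):
            raise ValueError(
                f"flat weight vector has shape {flat.shape}, expected ({self.n_params},)"
            )
        mats, i = [], 0
        for w in self.weights:
            mats.append(flat[i : i + w.size].reshape(w.shape))
            i += w.size
        return mats

    def with_flat_weights(self, flat: np.ndarray) -> "LayeredNetwork":
        return LayeredNetwork(self.layer_sizes, self.unflatten(flat), self.activation)


@dataclass
class InputSuite:
    """A fixed collection of input firing-rate vectors, one per row."""

    inputs: np.ndarray  # (n_inputs, dim)

    def __post_init__(self):
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        if self.inputs.shape[0] < 1:
            raise ValueError("input suite must contain at least one vector")

    @property
    def n_inputs(self) -> int:
        return self.inputs.shape[0]

    @property
    def dim(self) -> int:
        return self.inputs.shape[1]


@dataclass
class TeacherStudentTask:
    """Student-teacher maintenance task.

    The teacher is frozen; its outputs on the input suite are cached once and
    define the target mapping.  Task error of any student weight vector is the
    mean over inputs of the squared output mismatch (see ``landscape``).
    """

    teacher: LayeredNetwork
    suite: InputSuite
    student_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    teacher_outputs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.suite.dim != self.teacher.input_dim:
            raise ValueError(
                f"suite dim {self.suite.dim} != network input dim {self.teacher.input_dim}"
            )
        if self.teacher_outputs is None:
            self.teacher_outputs = forward(self.teacher, self.suite.inputs)
        if self.student_weights is None:
            self.student_weights = self.teacher.flat_weights().copy()
        self.student_weights = np.asarray(self.student_weights, dtype=float)

    @property
    def n_params(self) -> int:
        return self.teacher.n_params


@dataclass
class QuadraticLandscape:
    """Analytic loss F(w) = 1/2 (w - w*)^T H (w - w*) with known eigenstructure.

    ``basis`` columns are the eigenvectors of H; ``eigenvalues`` the matching
    eigenvalues.  Gradient and Hessian are exact, making this the reference
    surface for the curvature theory.
    """

    eigenvalues: np.ndarray
    basis: np.ndarray
    minimiser: np.ndarray

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.basis = np.asarray(self.basis, dtype=float)
        self.minimiser = np.asarray(self.minimiser, dtype=float)
        n = self.eigenvalues.size
        if self.basis.shape != (n, n) or self.minimiser.shape != (n,):
            raise ValueError("inconsistent landscape dimensions")
        err = np.abs(self.basis.T @ self.basis - np.eye(n)).max()
        if err > 1e-10:
            raise ValueError(f"basis is not orthonormal (max deviation {err:.2e})")

    @property
    def n_params(self) -> int:
        return self.eigenvalues.size

    @property
    def hessian(self) -> np.ndarray:
        return (self.basis * self.eigenvalues) @ self.basis.T

    @property
    def trace(self) -> float:
        return float(self.eigenvalues.sum())

    def is_positive_definite(self, tol: float = 0.0) -> bool:
        return bool(np.all(self.eigenvalues > tol))


def make_layered_network(
    layer_sizes: Sequence[int],
    activation: str = "sigmoid",
    seed=0,
    distribution: str = "uniform",
) -> LayeredNetwork:
    """Build a network with Xavier-initialised weights.

    ``distribution`` selects the uniform variant U(-a, a) with
    a = sqrt(6 / (fan_in + fan_out)) (default) or the normal variant with
    standard deviation sqrt(2 / (fan_in + fan_out)).
    """
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 2:
        raise ValueError("layer_sizes needs the input dimension plus >= 1 layer")
    if any(s <= 0 for s in sizes):
        raise ValueError(f"all layer sizes must be positive, got {sizes}")
    if distribution not in ("uniform", "normal"):
        raise ValueError("distribution must be 'uniform' or 'normal'")
    rng = _as_rng(seed)
    weights = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        if distribution == "uniform":
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, size=(fan_out, fan_in))
        else:
            std = np.sqrt(2.0 / (fan_in + fan_out))
            w = rng.normal(0.0, std, size=(fan_out, fan_in))
        weights.append(w)
    return LayeredNetwork(sizes, weights, activation)


def forward(net: LayeredNetwork, inputs: np.ndarray) -> np.ndarray:
    """Propagate one input vector (or a batch, one per row) through the network."""
    x = np.asarray(inputs, dtype=float)
    single = x.ndim == 1
    a = np.atleast_2d(x)
    if a.shape[1] != net.input_dim:
        raise ValueError(
            f"input dim {a.shape[1]} != network input dim {net.input_dim}"
        )
    for w in net.weights:
        a = a @ w.T
        if net.activation == "sigmoid":
            a = sigmoid(a)
    return a[0] if single else a


def make_input_suite(n_inputs: int, dim: int, seed=0) -> InputSuite:
    """Draw ``n_inputs`` vectors with i.i.d. standard-normal components."""
    if n_inputs < 1 or dim < 1:
        raise ValueError("n_inputs and dim must be >= 1")
    rng = _as_rng(seed)
    return InputSuite(rng.standard_normal((n_inputs, dim)))


def make_task(
    layer_sizes: Sequence[int] = (12, 20, 10),
    activation: str = "sigmoid",
    n_inputs: int = 1000,
    seed=0,
    distribution: str = "uniform",
) -> TeacherStudentTask:
    """Convenience constructor: teacher network + input suite + cached targets.

    The defaults reproduce the standard nonlinear maintenance task: a 12-20-10
    sigmoid network probed with 1000 unit-Gaussian input vectors.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    net_seed, suite_seed = ss.spawn(2)
    teacher = make_layered_network(layer_sizes, activation, net_seed, distribution)
    suite = make_input_suite(n_inputs, teacher.input_dim, suite_seed)
    return TeacherStudentTask(teacher, suite)


def make_quadratic(eigenvalues: Sequence[float], w_star: Sequence[float], seed=0) -> QuadraticLandscape:
    """Quadratic landscape with the given spectrum and a random orthonormal basis."""
    lam = np.asarray(eigenvalues, dtype=float)
    w_star = np.asarray(w_star, dtype=float)
    n = lam.size
    if w_star.shape != (n,) or n < 1:
        raise ValueError("eigenvalues and w_star must have equal length >= 1")
    rng = _as_rng(seed)
    if n == 1:
        basis = np.array([[1.0]])
    else:
        basis = ortho_group.rvs(n, random_state=rng)
    return QuadraticLandscape(lam, basis, w_star)


# -- JSON fixtures ------------------------------------------------------------

def network_to_json(net: LayeredNetwork) -> str:
    return json.dumps(
        {
            "layer_sizes": list(net.layer_sizes),
            "activation": net.activation,
            "flat_weights": net.flat_weights().tolist(),
        }
    )


def network_from_json(text: str) -> LayeredNetwork:
    d = json.loads(text)
    sizes = tuple(d["layer_sizes"])
    shapes = [(o, i) for i, o in zip(sizes[:-1], sizes[1:])]
    flat = np.asarray(d["flat_weights"], dtype=float)
    mats, i = [], 0
    for shape in shapes:
        size = shape[0] * shape[1]
        mats.append(flat[i : i + size].reshape(shape))
        i += size
    return LayeredNetwork(sizes, mats, d["activation"])


def suite_to_json(suite: InputSuite) -> str:
    return json.dumps({"inputs": suite.inputs.tolist()})


def suite_from_json(text: str) -> InputSuite:
    return InputSuite(np.asarray(json.loads(text)["inputs"], dtype=float))
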