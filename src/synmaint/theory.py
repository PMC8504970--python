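"""Closed-form predictions of the curvature-based optimality theory.

To second order, the expected change in task error over one small interval is

    E[dF] = dc^T grad F + 1/2 ||dc||^2 Q_w[dc] + 1/2 ||de||^2 Q_w[de],

because a task-independent fluctuation de has zero expected overlap with the
gradient and with H dc.  Minimising over the compensatory magnitude gives the
optimal step length for a given direction; imposing steady state (E[dF] = 0)
yields the headline ratio

    ||dc||*^2 / ||de||^2 = Q_w[de] / Q_w[dc],

so compensation should not outcompete fluctuations whenever its direction is
at least as upwardly curved as an average direction.  During active learning
(E[dF] < 0) the optimal magnitude only grows, so the steady-state value is a
lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OptimalityPrediction",
    "predicted_delta_F",
    "optimal_magnitude",
    "steady_state_ratio",
    "expected_q_random",
    "q_gradient_quadratic",
    "isotropic_steady_state",
]


@dataclass
class OptimalityPrediction:
    """Bundle of theory outputs for one operating point."""

    optimal_c_magnitude: float
    steady_state_ratio: float
    q_c: float
    q_eps: float
    regime: str = "steady_state"  # steady_state | learning


def predicted_delta_F(
    grad: np.ndarray,
    delta_c: np.ndarray,
    eps_magnitude: float,
    q_c: float,
    q_eps_expected: float,
) -> float:
    """Expected one-step error change under unbiased fluctuations.

    The fluctuation's linear term and its cross term with the compensatory
    update vanish in expectation, leaving the compensatory first- and
    second-order terms plus the fluctuation curvature penalty.
    """
    grad = np.asarray(grad, dtype=float)
    delta_c = np.asarray(delta_c, dtype=float)
    c2 = float(delta_c @ delta_c)
    return float(delta_c @ grad) + 0.5 * c2 * q_c + 0.5 * eps_magnitude**2 * q_eps_expected


def optimal_magnitude(grad: np.ndarray, direction: np.ndarray, q_dir: float) -> float:
    """Error-minimising step length along ``direction``.

    ||dc||* = (-d_hat^T grad_hat / Q_w[d]) * ||grad||, clamped at zero for
    uphill directions.  Valid only for upwardly curved directions (q_dir > 0);
    a non-positive curvature means the second-order expansion has no interior
    minimum along the ray and the caller must treat it separately.
    """
    if q_dir <= 0:
        raise ValueError("optimal magnitude undefined for non-positive curvature")
    grad = np.asarray(grad, dtype=float)
    direction = np.asarray(direction, dtype=float)
    dnorm = np.linalg.norm(direction)
    if dnorm == 0.0:
        raise ValueError("direction must be nonzero")
    gnorm = np.linalg.norm(grad)
    if gnorm == 0.0:
        return 0.0
    cos = float(direction @ grad) / (dnorm * gnorm)
    return max(0.0, -cos * gnorm / q_dir)


def steady_state_ratio(q_eps: float, q_c: float) -> float:
    """Optimal ||dc|| : ||de|| at steady-state error: sqrt(Q[de] / Q[dc]).

    Both curvatures must be strictly positive; the formula's derivation breaks
    down otherwise (indefinite directions have no steady-state optimum).
    """
    if q_eps <= 0 or q_c <= 0:
        raise ValueError("steady-state ratio requires strictly positive curvatures")
    return float(np.sqrt(q_eps / q_c))


def expected_q_random(trace: float, N: int) -> float:
    """Expected curvature of an isotropically random direction: Tr(H) / N."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return trace / N


def q_gradient_quadratic(eigenvalues, projections) -> float:
    """Curvature of the gradient direction on a quadratic landscape.

    With eigenvalues {l_i} and projections {c_i} of the displacement w - w*
    onto the eigenvectors, grad F = H (w - w*) gives

        Q_w[grad F] = sum c_i^2 l_i^3 / sum c_i^2 l_i^2.

    High-curvature components of the displacement are magnified by H, so the
    gradient is biased toward high-curvature directions — the mechanism behind
    the sub-unity optimal ratio for first-order rules.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    c = np.asarray(projections, dtype=float)
    if lam.shape != c.shape:
        raise ValueError("eigenvalues and projections must have equal length")
    denom = float(np.sum(c * c * lam * lam))
    if denom <= 0:
        raise ValueError("gradient vanishes: sum c_i^2 l_i^2 = 0")
    return float(np.sum(c * c * lam**3)) / denom


def isotropic_steady_state(c_magnitude: float, eps_magnitude: float) -> tuple[float, float]:
    """Closed-form steady state on the isotropic quadratic F = 1/2 ||w - w*||^2.

    With an exact-gradient compensatory step of fixed norm m (pointing straight
    at w*) and a fluctuation of norm e in a random direction, the squared
    distance obeys E[d'^2] = (d - m)^2 + e^2.  Its fixed point is

        d = (m^2 + e^2) / (2 m),    F = d^2 / 2.

    The formula is valid on the branch d >= m (no overshoot past the
    minimiser); with e = 0 realised trajectories instead collapse to d = 0.
    Returns (distance, error).
    """
    if c_magnitude <= 0:
        raise ValueError("c_magnitude must be positive")
    d = (c_magnitude**2 + eps_magnitude**2) / (2.0 * c_magnitude)
    return d, 0.5 * d * d
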