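"""Per-timestep plasticity generators.

Total weight change each step decomposes as dw = dc + de: a compensatory term
dc that moves downhill on the task-error landscape in expectation, and a
task-independent fluctuation term de whose direction is uncorrelated with the
error gradient.  Rules are grouped by the information they use:

* zero-order: probe the loss along a random direction, keep or oppose it;
* first-order: step down the (possibly noise-corrupted) gradient,
  dc = -gamma1 * grad_hat + gamma2 * nu_hat with fresh Gaussian noise nu;
* second-order: the Newton direction -H^{-1} grad (defined here only on
  positive-definite quadratic landscapes).

Fluctuations are norm-controlled white noise, optionally restricted to a
subspace (e.g. the span of low-curvature Hessian eigenvectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import LossHandle
from .task_models import QuadraticLandscape, _as_rng

__all__ = [
    "PlasticityStep",
    "CompensationConfig",
    "fluctuation_step",
    "corrupted_gradient_step",
    "zero_order_step",
    "newton_step",
    "RULES",
]

RULES = ("exact_gradient", "corrupted_gradient", "zero_order", "newton")


@dataclass
class PlasticityStep:
    """One time-step's compensatory and fluctuation updates.

    Fluctuations are norm-controlled, so ``delta_eps`` must carry exactly
    ``eps_magnitude``; the compensatory norm may deviate from ``c_magnitude``
    for unnormalised rules (the O(1/sqrt(N)) cross-term).
    """

    delta_c: np.ndarray
    delta_eps: np.ndarray
    c_magnitude: float
    eps_magnitude: float

    def __post_init__(self):
        self.delta_c = np.asarray(self.delta_c, dtype=float)
        self.delta_eps = np.asarray(self.delta_eps, dtype=float)
        if self.delta_c.shape != self.delta_eps.shape:
            raise ValueError("delta_c and delta_eps must have equal length")
        if abs(np.linalg.norm(self.delta_eps) - self.eps_magnitude) > 1e-9 * (
            1.0 + self.eps_magnitude
        ):
            raise ValueError("||delta_eps|| must equal eps_magnitude")

    @property
    def total(self) -> np.ndarray:
        return self.delta_c + self.delta_eps


@dataclass
class CompensationConfig:
    """Settings of the compensatory rule.

    gamma1 scales the normalised negative gradient, gamma2 the normalised
    white-noise corruption; sqrt(gamma1^2 + gamma2^2) sets the overall
    magnitude and gamma2:gamma1 the imprecision of the rule.  With
    ``renormalize`` the emitted step is rescaled to exactly that magnitude
    (the unnormalised sum differs from it by an O(1/sqrt(N)) cross-term).
    """

    rule: str = "exact_gradient"
    gamma1: float = 1.0
    gamma2: float = 0.0
    probe_scale: float | None = None  # zero-order only; default 1e-3*(1+||w||_inf)
    renormalize: bool = False

    def __post_init__(self):
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        if self.gamma1 < 0 or self.gamma2 < 0:
            raise ValueError("gamma1 and gamma2 must be non-negative")
        if self.rule == "exact_gradient" and self.gamma2 != 0:
            raise ValueError("exact_gradient requires gamma2 = 0")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.gamma1, self.gamma2))

    @property
    def noise_ratio(self) -> float:
        """gamma2 : gamma1 corruption ratio (inf for pure noise)."""
        if self.gamma1 == 0:
            return float("inf") if self.gamma2 > 0 else 0.0
        return self.gamma2 / self.gamma1

    def with_magnitude(self, magnitude: float) -> "CompensationConfig":
        """Rescale (gamma1, gamma2) to a new overall magnitude, keeping their ratio."""
        if magnitude < 0:
            raise ValueError("magnitude must be non-negative")
        old = self.magnitude
        if old == 0:
            if magnitude == 0:
                return CompensationConfig(self.rule, 0.0, 0.0, self.probe_scale, self.renormalize)
            raise ValueError("cannot rescale a zero-magnitude config")
        s = magnitude / old
        return CompensationConfig(
            self.rule, self.gamma1 * s, self.gamma2 * s, self.probe_scale, self.renormalize
        )

    @classmethod
    def from_ratio(
        cls,
        rule: str,
        magnitude: float,
        noise_ratio: float = 0.0,
        probe_scale: float | None = None,
        renormalize: bool = False,
    ) -> "CompensationConfig":
        """Build a config from overall magnitude and gamma2:gamma1 corruption ratio."""
        g1 = magnitude / np.sqrt(1.0 + noise_ratio**2)
        g2 = noise_ratio * g1
        return cls(rule, g1, g2, probe_scale, renormalize)


def fluctuation_step(
    N: int,
    magnitude: float,
    seed=0,
    subspace: np.ndarray | None = None,
) -> np.ndarray:
    """Isotropic white-noise fluctuation with exactly the requested 2-norm.

    If ``subspace`` (N x k, orthonormal columns) is given, the draw is confined
    to its span — the "fluctuations restricted to unimportant synapses" case.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return np.zeros(N)
    rng = _as_rng(seed)
    if subspace is not None:
        S = np.asarray(subspace, dtype=float)
        if S.ndim != 2 or S.shape[0] != N:
            raise ValueError(f"subspace must be N x k with N={N}")
        if np.abs(S.T @ S - np.eye(S.shape[1])).max() > 1e-8:
            raise ValueError("subspace columns are not orthonormal")
        v = S @ rng.standard_normal(S.shape[1])
    else:
        v = rng.standard_normal(N)
    norm = np.linalg.norm(v)
    if norm == 0.0:  # astronomically unlikely; redraw would bias the stream
        v = np.ones(N)
        norm = np.sqrt(N)
    return v * (magnitude / norm)


def corrupted_gradient_step(
    grad: np.ndarray,
    gamma1: float,
    gamma2: float,
    seed=0,
    renormalize: bool = False,
) -> np.ndarray:
    """First-order compensatory update dc = -gamma1 * grad_hat + gamma2 * nu_hat."""
    grad = np.asarray(grad, dtype=float)
    gnorm = np.linalg.norm(grad)
    if gamma1 > 0 and gnorm == 0.0:
        raise ValueError("gradient is zero; the descent direction is undefined")
    step = np.zeros_like(grad)
    if gamma1 > 0:
        step = -gamma1 * grad / gnorm
    if gamma2 > 0:
        rng = _as_rng(seed)
        nu = rng.standard_normal(grad.size)
        step = step + gamma2 * nu / np.linalg.norm(nu)
    if renormalize:
        target = float(np.hypot(gamma1, gamma2))
        norm = np.linalg.norm(step)
        if norm > 0:
            step = step * (target / norm)
    return step


def zero_order_step(
    loss: LossHandle,
    w: np.ndarray,
    magnitude: float,
    probe_scale: float | None = None,
    seed=0,
) -> np.ndarray:
    """Single-probe sign rule: try a random direction, keep it if the loss drops.

    Draws a uniform random unit direction d_hat, probes F(w + probe_scale*d_hat),
    and returns -sign(F_probe - F(w)) * magnitude * d_hat.  This is the minimal
    member of the exploratory (REINFORCE-family) class: in expectation it moves
    downhill, and its accepted directions carry only average curvature.
    """
    w = np.asarray(w, dtype=float)
    if probe_scale is None:
        probe_scale = 1e-3 * (1.0 + np.abs(w).max())
    if probe_scale <= 0:
        raise ValueError("probe_scale must be positive")
    rng = _as_rng(seed)
    d = rng.standard_normal(w.size)
    d /= np.linalg.norm(d)
    df = loss.evaluate(w + probe_scale * d) - loss.evaluate(w)
    sign = np.sign(df) if df != 0 else 1.0
    return -sign * magnitude * d


def newton_step(quad: QuadraticLandscape, w: np.ndarray, magnitude: float) -> np.ndarray:
    """Second-order update: ``magnitude`` along -H^{-1} grad F = w* - w.

    On a positive-definite quadratic the Newton direction is the straight line
    ("beeline") to the minimiser, so its curvature matches that of the
    fluctuation that displaced the state.
    """
    if not quad.is_positive_definite():
        raise ValueError("Newton rule requires a positive-definite landscape")
    w = np.asarray(w, dtype=float)
    d = quad.minimiser - w
    norm = np.linalg.norm(d)
    if norm == 0.0:
        return np.zeros_like(w)
    return d * (magnitude / norm)
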