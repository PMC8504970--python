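"""Maintenance simulations: noisy weight dynamics, ratio sweeps, staircases.

Each timestep applies w <- w + dc + de: a compensatory update dc from the
configured rule and a norm-controlled white-noise fluctuation de.  The student
starts at the teacher (zero error) and the two processes settle into a steady
state whose mean error depends on the magnitude ratio ||dc|| : ||de||.  The
two headline protocols are the staircase (hold the fluctuation rate fixed,
ratchet the compensation rate up in stages, locate the sweet spot) and the
ratio sweep (independent runs per ratio on a grid, steady-state error read
from the tail of each run).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .landscape import LossHandle, QuadraticLoss, TeacherStudentLoss, as_loss
from .plasticity_rules import (
    CompensationConfig,
    corrupted_gradient_step,
    fluctuation_step,
    newton_step,
    zero_order_step,
)
from .task_models import QuadraticLandscape, TeacherStudentTask

__all__ = [
    "Trajectory",
    "SweepResult",
    "StaircaseResult",
    "run_maintenance",
    "steady_state_error",
    "ratio_sweep",
    "staircase",
]

logger = logging.getLogger(__name__)


@dataclass
class Trajectory:
    """Task error per timestep plus sparse weight snapshots and a config echo."""

    errors: np.ndarray  # length n_steps + 1 (includes t = 0)
    snapshot_times: np.ndarray
    weight_snapshots: np.ndarray  # (n_snapshots, N)
    config_echo: dict
    aborted: bool = False

    @property
    def n_steps(self) -> int:
        return len(self.errors) - 1

    def final_weights(self) -> np.ndarray:
        return self.weight_snapshots[-1]


@dataclass
class SweepResult:
    """Steady-state error as a function of the compensation:fluctuation ratio."""

    ratios: np.ndarray
    steady_errors: np.ndarray  # mean over repeats, per ratio
    steady_sds: np.ndarray
    per_cell: np.ndarray  # (repeats, n_ratios); NaN where a cell aborted
    argmin_ratio: float
    repeats: int
    config_echo: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for j in range(self.per_cell.shape[0]):
            for i, r in enumerate(self.ratios):
                rows.append(
                    {"ratio": float(r), "repeat": j, "steady_error": self.per_cell[j, i]}
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "ratios": [float(r) for r in self.ratios],
            "steady_errors": [float(e) for e in self.steady_errors],
            "steady_sds": [float(s) for s in self.steady_sds],
            "argmin_ratio": float(self.argmin_ratio),
            "repeats": self.repeats,
            "config": self.config_echo,
        }


@dataclass
class StaircaseResult:
    """One continuous run with the compensation magnitude raised in stages."""

    stage_magnitudes: np.ndarray
    stage_steady_errors: np.ndarray
    sweet_spot_magnitude: float
    fluctuation_magnitude: float
    trajectory: Trajectory

    def summary(self) -> dict:
        return {
            "stage_magnitudes": [float(m) for m in self.stage_magnitudes],
            "stage_steady_errors": [float(e) for e in self.stage_steady_errors],
            "sweet_spot_magnitude": float(self.sweet_spot_magnitude),
            "fluctuation_magnitude": float(self.fluctuation_magnitude),
        }


def _resolve_system(system) -> tuple[LossHandle, np.ndarray, QuadraticLandscape | None]:
    """Return (loss, default start weights, quadratic landscape if any)."""
    loss = as_loss(system)
    if isinstance(system, TeacherStudentTask):
        return loss, system.teacher.flat_weights().copy(), None
    if isinstance(system, QuadraticLandscape):
        return loss, system.minimiser.copy(), system
    quad = loss.landscape if isinstance(loss, QuadraticLoss) else None
    w0 = None
    if quad is not None:
        w0 = quad.minimiser.copy()
    elif isinstance(loss, TeacherStudentLoss):
        w0 = loss.task.teacher.flat_weights().copy()
    return loss, w0, quad


def _compensation(
    loss: LossHandle,
    quad: QuadraticLandscape | None,
    w: np.ndarray,
    comp: CompensationConfig,
    magnitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One compensatory update of the requested overall magnitude."""
    if magnitude == 0.0:
        return np.zeros_like(w)
    cfg = comp.with_magnitude(magnitude)
    if cfg.rule in ("exact_gradient", "corrupted_gradient"):
        g = loss.gradient(w)
        if np.linalg.norm(g) == 0.0:
            # Flat point (e.g. student exactly at the teacher): the descent
            # direction is undefined, so only the noise component acts.
            if cfg.gamma2 > 0:
                return corrupted_gradient_step(g, 0.0, cfg.gamma2, rng, cfg.renormalize)
            return np.zeros_like(w)
        return corrupted_gradient_step(g, cfg.gamma1, cfg.gamma2, rng, cfg.renormalize)
    if cfg.rule == "zero_order":
        return zero_order_step(loss, w, magnitude, cfg.probe_scale, rng)
    if cfg.rule == "newton":
        if quad is None:
            raise ValueError("newton rule is only defined on quadratic landscapes")
        return newton_step(quad, w, magnitude)
    raise ValueError(f"unknown rule {cfg.rule!r}")


def run_maintenance(
    system,
    comp: CompensationConfig,
    eps_magnitude: float,
    c_magnitude: float,
    n_steps: int,
    seed=0,
    w0: np.ndarray | None = None,
    snapshot_every: int = 100,
    subspace: np.ndarray | None = None,
) -> Trajectory:
    """Iterate w <- w + dc + de for ``n_steps``, recording task error each step.

    ``system`` is a TeacherStudentTask, a QuadraticLandscape, or any LossHandle
    (then ``w0`` is required).  Fluctuation and compensation noise draw from
    independent streams spawned from ``seed``, so the two never alias.  A
    non-finite loss aborts the run, returning the valid prefix flagged
    ``aborted``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    loss, default_w0, quad = _resolve_system(system)
    w = np.array(default_w0 if w0 is None else w0, dtype=float)
    if w is None:
        raise ValueError("w0 is required for a bare LossHandle")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    eps_rng, comp_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    N = w.size
    errors = np.empty(n_steps + 1)
    errors[0] = loss.evaluate(w)
    snap_t, snaps = [0], [w.copy()]
    echo = {
        "rule": comp.rule,
        "noise_ratio": comp.noise_ratio,
        "renormalize": comp.renormalize,
        "eps_magnitude": float(eps_magnitude),
        "c_magnitude": float(c_magnitude),
        "n_steps": int(n_steps),
        "seed": repr(ss.entropy),
    }
    aborted = False
    for t in range(1, n_steps + 1):
        dc = _compensation(loss, quad, w, comp, c_magnitude, comp_rng)
        de = fluctuation_step(N, eps_magnitude, eps_rng, subspace)
        w = w + dc + de
        f = loss.evaluate(w)
        if not np.isfinite(f):
            logger.warning("loss became non-finite at step %d; aborting run", t)
            errors = errors[:t]
            aborted = True
            break
        errors[t] = f
        if t % snapshot_every == 0 or t == n_steps:
            snap_t.append(t)
            snaps.append(w.copy())
    return Trajectory(
        errors=errors,
        snapshot_times=np.asarray(snap_t),
        weight_snapshots=np.asarray(snaps),
        config_echo=echo,
        aborted=aborted,
    )


def steady_state_error(traj: Trajectory, window: int = 500) -> float:
    """Mean task error over the final ``window`` timepoints of a trajectory."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(traj.errors):
        raise ValueError(
            f"window {window} exceeds trajectory length {len(traj.errors)}"
        )
    return float(np.mean(traj.errors[-window:]))


def _argmin_ratio(ratios: np.ndarray, means: np.ndarray) -> float:
    """Smallest ratio attaining the minimal mean steady error (ties -> smallest)."""
    finite = np.isfinite(means)
    if not finite.any():
        raise RuntimeError("every sweep cell aborted; no argmin available")
    best = np.nanmin(means)
    return float(ratios[np.flatnonzero(means <= best)[0]])


def ratio_sweep(
    system,
    comp: CompensationConfig,
    eps_magnitude: float,
    ratios: Sequence[float],
    n_steps: int,
    repeats: int,
    seed=0,
    window: int = 500,
    system_factory: Callable[[np.random.SeedSequence], object] | None = None,
    snapshot_every: int = 1000,
) -> SweepResult:
    """Steady-state error across a grid of compensation:fluctuation ratios.

    For each ratio r the compensation magnitude is r * eps_magnitude; each of
    ``repeats`` repeats runs an independent trajectory.  If ``system_factory``
    is given it is called once per repeat with a spawned seed (fresh teacher
    and input suite per repeat); otherwise the fixed ``system`` is reused and
    only the noise streams differ.  Aborted cells are excluded with a warning.
    """
    ratios = np.asarray(list(ratios), dtype=float)
    if ratios.size == 0 or np.any(ratios <= 0):
        raise ValueError("ratios must be a non-empty grid of positive values")
    if eps_magnitude <= 0:
        raise ValueError("eps_magnitude must be positive for a ratio sweep")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    repeat_seeds = ss.spawn(repeats)
    per_cell = np.full((repeats, ratios.size), np.nan)
    for j in range(repeats):
        sys_j = system_factory(repeat_seeds[j]) if system_factory is not None else system
        traj_seeds = repeat_seeds[j].spawn(ratios.size)
        for i, r in enumerate(ratios):
            traj = run_maintenance(
                sys_j,
                comp,
                eps_magnitude,
                float(r) * eps_magnitude,
                n_steps,
                seed=traj_seeds[i],
                snapshot_every=snapshot_every,
            )
            if traj.aborted or len(traj.errors) < window:
                warnings.warn(
                    f"sweep cell (ratio={r:g}, repeat={j}) aborted; excluded",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            per_cell[j, i] = steady_state_error(traj, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(per_cell, axis=0)
        sds = np.nanstd(per_cell, axis=0, ddof=1) if repeats > 1 else np.zeros(ratios.size)
    sds = np.nan_to_num(sds, nan=0.0)
    echo = {
        "rule": comp.rule,
        "noise_ratio": comp.noise_ratio,
        "eps_magnitude": float(eps_magnitude),
        "n_steps": int(n_steps),
        "window": int(window),
        "fresh_system_per_repeat": system_factory is not None,
        "seed": repr(ss.entropy),
    }
    return SweepResult(
        ratios=ratios,
        steady_errors=means,
        steady_sds=sds,
        per_cell=per_cell,
        argmin_ratio=_argmin_ratio(ratios, means),
        repeats=repeats,
        config_echo=echo,
    )


def staircase(
    system,
    comp: CompensationConfig,
    eps_magnitude: float,
    stage_magnitudes: Sequence[float],
    stage_length: int = 2000,
    settle_discard: int = 1500,
    seed=0,
    snapshot_every: int = 100,
) -> StaircaseResult:
    """One continuous run with the compensation magnitude ratcheted up in stages.

    Each magnitude is held for ``stage_length`` steps; the first
    ``settle_discard`` steps of a stage are discarded as transient and the
    stage's steady error is the mean over the remainder.  The sweet spot is the
    stage magnitude with minimal steady error.
    """
    mags = np.asarray(list(stage_magnitudes), dtype=float)
    if mags.size == 0 or np.any(np.diff(mags) <= 0):
        raise ValueError("stage_magnitudes must be strictly increasing")
    if settle_discard >= stage_length:
        raise ValueError("stage_length must exceed settle_discard")
    loss, default_w0, quad = _resolve_system(system)
    w = np.array(default_w0, dtype=float)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    eps_rng, comp_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    N = w.size
    n_total = stage_length * mags.size
    errors = np.empty(n_total + 1)
    errors[0] = loss.evaluate(w)
    snap_t, snaps = [0], [w.copy()]
    stage_err = np.empty(mags.size)
    t = 0
    for s, m in enumerate(mags):
        for _ in range(stage_length):
            t += 1
            dc = _compensation(loss, quad, w, comp, float(m), comp_rng)
            de = fluctuation_step(N, eps_magnitude, eps_rng)
            w = w + dc + de
            errors[t] = loss.evaluate(w)
            if t % snapshot_every == 0:
                snap_t.append(t)
                snaps.append(w.copy())
        stage_err[s] = errors[t - (stage_length - settle_discard) + 1 : t + 1].mean()
    sweet = float(mags[int(np.argmin(stage_err))])
    traj = Trajectory(
        errors=errors,
        snapshot_times=np.asarray(snap_t),
        weight_snapshots=np.asarray(snaps),
        config_echo={
            "rule": comp.rule,
            "eps_magnitude": float(eps_magnitude),
            "stage_magnitudes": mags.tolist(),
            "stage_length": int(stage_length),
            "settle_discard": int(settle_discard),
            "seed": repr(ss.entropy),
        },
    )
    return StaircaseResult(
        stage_magnitudes=mags,
        stage_steady_errors=stage_err,
        sweet_spot_magnitude=sweet,
        fluctuation_magnitude=float(eps_magnitude),
        trajectory=traj,
    )
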