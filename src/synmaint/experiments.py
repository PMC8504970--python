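"""Config-driven experiment runners reproducing the headline protocols.

Four experiments are shipped:

* ``staircase`` — nonlinear 12-20-10 sigmoid maintenance run with fixed
  fluctuation magnitude and a compensation magnitude ratcheted up in stages,
  locating the sweet spot.
* ``nonlinear_sweep`` — grid of ratio sweeps on the nonlinear task, varying the
  fluctuation magnitude across columns and the gradient-corruption ratio
  (gamma2:gamma1) down rows.
* ``linear_sweep`` — the same sweep on the 12-to-10 linear network.
* ``theory_check`` — random anisotropic positive-definite quadratics:
  the predicted optimal ratio sqrt(Q[de]/Q[dc]) against the simulated
  sweep argmin, instance by instance.

Every output CSV row carries the master seed and a hash of the resolved
config, so any table is reconstructible from the config file alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import theory
from .landscape import QuadraticLoss, q_value
from .plasticity_rules import CompensationConfig
from .simulate import SweepResult, ratio_sweep, staircase
from .task_models import make_quadratic, make_task

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "plot_sweep",
    "theory_vs_simulation",
    "DEFAULT_RATIOS",
    "SCALES",
]

logger = logging.getLogger(__name__)

EXPERIMENTS = ("staircase", "nonlinear_sweep", "linear_sweep", "theory_check")

DEFAULT_RATIOS = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0)

# Problem sizes: "full" follows the reference protocol (8000 steps, 8 repeats,
# 1000-input suite, steady window 500); "desk" scales down for interactive use.
SCALES = {
    "full": {"n_steps": 8000, "repeats": 8, "n_inputs": 1000, "window": 500},
    "desk": {"n_steps": 4000, "repeats": 4, "n_inputs": 200, "window": 500},
}


@dataclass
class ExperimentConfig:
    """Fully resolved settings for one experiment run."""

    experiment: str = "nonlinear_sweep"
    layer_sizes: tuple[int, ...] = (12, 20, 10)
    activation: str = "sigmoid"
    eps_magnitudes: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    gamma_noise_ratios: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    n_steps: int = 8000
    repeats: int = 8
    window: int = 500
    n_inputs: int = 1000
    master_seed: int = 0
    output_dir: str = "synmaint_out"
    make_plots: bool = False
    # staircase-specific
    staircase_eps: float = 2.0
    staircase_rel_magnitudes: tuple[float, ...] = (0.25, 0.35, 0.5, 0.7, 1.0, 1.4, 2.0)
    stage_length: int = 2000
    settle_discard: int = 1500
    # theory-check-specific
    n_instances: int = 10
    quad_dim: int = 30
    quad_condition: float = 100.0
    theory_eps: float = 0.05

    def validate(self) -> None:
        problems = []
        if self.experiment not in EXPERIMENTS:
            problems.append(f"experiment must be one of {EXPERIMENTS}")
        if len(self.layer_sizes) < 2 or any(s <= 0 for s in self.layer_sizes):
            problems.append("layer_sizes needs >= 2 positive entries")
        for name in ("eps_magnitudes", "gamma_noise_ratios", "ratios"):
            grid = getattr(self, name)
            if len(grid) == 0:
                problems.append(f"{name} must be a non-empty grid")
            elif name != "gamma_noise_ratios" and any(v <= 0 for v in grid):
                problems.append(f"{name} entries must be positive")
            elif any(v < 0 for v in grid):
                problems.append(f"{name} entries must be non-negative")
        for name in ("n_steps", "repeats", "window", "n_inputs", "n_instances", "quad_dim"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        if self.window > self.n_steps:
            problems.append("window must not exceed n_steps")
        if self.settle_discard >= self.stage_length:
            problems.append("stage_length must exceed settle_discard")
        if problems:
            raise ValueError("invalid experiment config:\n  - " + "\n  - ".join(problems))

    def with_scale(self, scale: str) -> "ExperimentConfig":
        if scale not in SCALES:
            raise ValueError(f"scale must be one of {tuple(SCALES)}")
        return dataclasses.replace(self, **SCALES[scale])

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        d = dict(d)
        for name in ("layer_sizes", "eps_magnitudes", "gamma_noise_ratios",
                     "ratios", "staircase_rel_magnitudes"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("output_dir", None)  # hash the scientific settings, not the destination
        d.pop("make_plots", None)
        text = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha1(text.encode()).hexdigest()[:12]


def _annotate(df: pd.DataFrame, cfg: ExperimentConfig) -> pd.DataFrame:
    df = df.copy()
    df["master_seed"] = cfg.master_seed
    df["config_hash"] = cfg.config_hash()
    return df


def _task_factory(cfg: ExperimentConfig):
    def build(seed_seq):
        return make_task(cfg.layer_sizes, cfg.activation, cfg.n_inputs, seed_seq)

    return build


def _run_staircase(cfg: ExperimentConfig, out: Path) -> dict:
    task = make_task(cfg.layer_sizes, cfg.activation, cfg.n_inputs,
                     np.random.SeedSequence([cfg.master_seed, 0]))
    comp = CompensationConfig(rule="exact_gradient")
    mags = tuple(m * cfg.staircase_eps for m in cfg.staircase_rel_magnitudes)
    result = staircase(
        task, comp, cfg.staircase_eps, mags,
        stage_length=cfg.stage_length, settle_discard=cfg.settle_discard,
        seed=np.random.SeedSequence([cfg.master_seed, 1]),
    )
    rows = pd.DataFrame(
        {
            "stage": np.arange(len(result.stage_magnitudes)),
            "c_magnitude": result.stage_magnitudes,
            "steady_error": result.stage_steady_errors,
        }
    )
    _annotate(rows, cfg).to_csv(out / "staircase.csv", index=False)
    errs = pd.DataFrame({"t": np.arange(len(result.trajectory.errors)),
                         "task_error": result.trajectory.errors})
    _annotate(errs, cfg).to_csv(out / "staircase_trajectory.csv", index=False)
    summary = result.summary()
    summary["sweet_spot_ratio"] = summary["sweet_spot_magnitude"] / cfg.staircase_eps
    return summary


def _run_sweep_grid(cfg: ExperimentConfig, out: Path) -> dict:
    factory = _task_factory(cfg)
    rows, panels = [], {}
    cells = len(cfg.gamma_noise_ratios) * len(cfg.eps_magnitudes)
    done = 0
    for gi, g_ratio in enumerate(cfg.gamma_noise_ratios):
        rule = "exact_gradient" if g_ratio == 0 else "corrupted_gradient"
        comp = CompensationConfig.from_ratio(rule, 1.0, g_ratio)
        for ei, eps in enumerate(cfg.eps_magnitudes):
            seed = np.random.SeedSequence([cfg.master_seed, gi, ei])
            res = ratio_sweep(
                None, comp, eps, cfg.ratios, cfg.n_steps, cfg.repeats,
                seed=seed, window=cfg.window, system_factory=factory,
            )
            df = res.to_dataframe()
            df["gamma_noise_ratio"] = g_ratio
            df["eps_magnitude"] = eps
            rows.append(df)
            panels[f"noise{g_ratio:g}_eps{eps:g}"] = res.summary()
            done += 1
            logger.info("sweep panel %d/%d done (noise=%g, eps=%g, argmin=%g)",
                        done, cells, g_ratio, eps, res.argmin_ratio)
            if cfg.make_plots:
                plot_sweep(res, out / f"sweep_noise{g_ratio:g}_eps{eps:g}.png")
    table = _annotate(pd.concat(rows, ignore_index=True), cfg)
    table.to_csv(out / "sweep_cells.csv", index=False)
    return {"panels": panels}


def theory_vs_simulation(
    n_instances: int = 10,
    dim: int = 30,
    condition: float = 100.0,
    eps_magnitude: float = 0.05,
    ratios=tuple(np.geomspace(0.25, 2.0, 7)),
    n_steps: int = 3000,
    repeats: int = 4,
    window: int = 500,
    seed=0,
) -> pd.DataFrame:
    """Predicted vs simulated optimal ratio on random anisotropic PD quadratics.

    Eigenvalues are log-spaced over the given condition number.  The predicted
    ratio sqrt(Q[de]/Q[dc]) is evaluated at the steady-state operating point:
    Q[dc] is the time-average of the gradient-direction curvature over the tail
    snapshots of the argmin run, and Q[de] the average-direction curvature
    Tr(H)/N, which is exact for isotropic fluctuations.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ratios = np.asarray(list(ratios), dtype=float)
    comp = CompensationConfig(rule="exact_gradient")
    rows = []
    for k, inst_seed in enumerate(ss.spawn(n_instances)):
        rng = np.random.default_rng(inst_seed)
        lam = np.geomspace(1.0 / np.sqrt(condition), np.sqrt(condition), dim)
        quad = make_quadratic(lam, np.zeros(dim), rng)
        res = ratio_sweep(
            quad, comp, eps_magnitude, ratios, n_steps, repeats,
            seed=inst_seed.spawn(1)[0], window=window, snapshot_every=25,
        )
        # Q[dc] time-averaged over the tail of a run at the simulated argmin
        from .simulate import run_maintenance  # local import avoids a cycle

        traj = run_maintenance(
            quad, comp, eps_magnitude, res.argmin_ratio * eps_magnitude,
            n_steps, seed=inst_seed.spawn(2)[1], snapshot_every=25,
        )
        loss = QuadraticLoss(quad)
        tail = traj.weight_snapshots[traj.snapshot_times > n_steps - window]
        q_cs = []
        for w in tail:
            g = loss.gradient(w)
            if np.linalg.norm(g) > 0:
                q_cs.append(q_value(loss, w, g))
        q_c = float(np.mean(q_cs))
        q_eps = theory.expected_q_random(quad.trace, dim)
        predicted = theory.steady_state_ratio(q_eps, q_c)
        # distance in grid steps (geometric grid -> log spacing)
        log_step = np.log(ratios[1] / ratios[0])
        grid_dist = abs(np.log(predicted / res.argmin_ratio)) / log_step
        rows.append(
            {
                "instance": k,
                "predicted_ratio": predicted,
                "simulated_argmin": res.argmin_ratio,
                "grid_steps_apart": grid_dist,
                "q_c": q_c,
                "q_eps": q_eps,
            }
        )
    return pd.DataFrame(rows)


def _run_theory_check(cfg: ExperimentConfig, out: Path) -> dict:
    df = theory_vs_simulation(
        n_instances=cfg.n_instances,
        dim=cfg.quad_dim,
        condition=cfg.quad_condition,
        eps_magnitude=cfg.theory_eps,
        n_steps=min(cfg.n_steps, 3000),
        window=cfg.window,
        seed=np.random.SeedSequence([cfg.master_seed, 7]),
    )
    _annotate(df, cfg).to_csv(out / "theory_check.csv", index=False)
    return {
        "max_grid_steps_apart": float(df["grid_steps_apart"].max()),
        "mean_predicted_ratio": float(df["predicted_ratio"].mean()),
        "mean_simulated_argmin": float(df["simulated_argmin"].mean()),
    }


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one experiment; returns the summary dict also written to disk."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2, default=str))
    if config.experiment == "staircase":
        summary = _run_staircase(config, out)
    elif config.experiment == "nonlinear_sweep":
        summary = _run_sweep_grid(config, out)
    elif config.experiment == "linear_sweep":
        cfg = dataclasses.replace(config, layer_sizes=(12, 10), activation="linear")
        summary = _run_sweep_grid(cfg, out)
    else:
        summary = _run_theory_check(config, out)
    summary = {"experiment": config.experiment,
               "config_hash": config.config_hash(), **summary}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary


def plot_sweep(result: SweepResult, path) -> None:
    """Mean steady error vs ratio with a +/- 1 sd band and the argmin marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    r = result.ratios
    m = result.steady_errors
    s = result.steady_sds
    ax.plot(r, m, "o-", color="tab:blue", ms=4)
    ax.fill_between(r, m - s, m + s, alpha=0.25, color="tab:blue")
    ax.axvline(result.argmin_ratio, color="tab:red", ls="--", lw=1,
               label=f"argmin = {result.argmin_ratio:g}")
    ax.set_xlabel(r"$\|\Delta c\|_2 : \|\Delta\epsilon\|_2$")
    ax.set_ylabel("steady-state task error")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": "synmaint"})
    plt.close(fig)
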