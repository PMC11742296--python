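"""Desk-scale reproductions of the three headline experiments.

1. ``run_trajectory_experiment`` — one object at (0, 2), agent at (0, 0),
   20 steps, Euclidean versus projective geometry (idle versus approach).
2. ``run_direction_profile`` — a 20x20 grid of object positions around the
   agent; for each admissible position the first-step translations are
   scored and averaged per direction relative to the object (flat profile
   for Euclidean geometry, peaked at the object direction for projective).
3. ``run_behavior_sweep`` — the two-object scene swept over (gamma,
   epsilon), summarized by swap and reach counts over 40 steps.

All outputs are plain pandas DataFrames; deterministic under the quadrature
pushforward and a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agent import (
    SimulationConfig,
    build_action_set,
    compute_metrics,
    evaluate_move,
    initial_state,
    run_simulation,
)
from .geometry import GeometryConfig
from .inference import PushforwardScheme

__all__ = [
    "GridExperimentConfig",
    "SweepConfig",
    "one_object_config",
    "two_object_config",
    "run_trajectory_experiment",
    "run_direction_profile",
    "run_behavior_sweep",
    "plot_trajectory",
    "plot_direction_profile",
    "plot_sweep_heatmaps",
]


def one_object_config(
    geometry: GeometryConfig, epsilon: float = 0.1, **overrides
) -> SimulationConfig:
    """The single-object scene: agent at (0, 0), object at (0, 2), 20 steps."""
    defaults = dict(
        geometry=geometry,
        object_positions=((0.0, 2.0),),
        agent_start=(0.0, 0.0),
        epsilon=epsilon,
        n_steps=20,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def two_object_config(
    geometry: GeometryConfig, epsilon: float = 0.1, **overrides
) -> SimulationConfig:
    """The two-object scene: objects at (-0.5, 0.75) and (0.5, 0.75), 40 steps."""
    defaults = dict(
        geometry=geometry,
        object_positions=((-0.5, 0.75), (0.5, 0.75)),
        agent_start=(0.0, 0.0),
        epsilon=epsilon,
        n_steps=40,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def run_trajectory_experiment(base: SimulationConfig, gamma: float = 1.0):
    """One-object runs under both geometries with otherwise identical settings.

    Returns ``(euclidean_trajectory, projective_trajectory)``.
    """
    eucl = run_simulation(replace(base, geometry=GeometryConfig.euclidean()))
    proj = run_simulation(
        replace(base, geometry=GeometryConfig.projective(gamma))
    )
    return eucl, proj


@dataclass(frozen=True)
class GridExperimentConfig:
    """Grid of object positions for the direction-value profile.

    ``n_grid`` positions per side over [-extent, extent]^2 centred on the
    agent; positions closer than ``exclusion_radius`` are skipped so the
    projective effect is not swamped by near-horizon geometry.
    """

    n_grid: int = 20
    extent: float = 2.0
    exclusion_radius: float = 0.3
    gamma: float = 1.0
    epsilon: float = 0.1
    k: float = 0.01
    step_norm: float = 0.1
    scheme: PushforwardScheme = field(default_factory=PushforwardScheme)

    def __post_init__(self) -> None:
        if self.n_grid < 2 or self.extent <= 0 or self.exclusion_radius < 0:
            raise ValueError("invalid grid specification")

    def positions(self) -> np.ndarray:
        axis = np.linspace(-self.extent, self.extent, self.n_grid)
        xs, ys = np.meshgrid(axis, axis, indexing="ij")
        grid = np.column_stack([xs.ravel(), ys.ravel()])
        keep = np.linalg.norm(grid, axis=1) >= self.exclusion_radius
        return grid[keep]


def run_direction_profile(config: GridExperimentConfig) -> pd.DataFrame:
    """Mean first-step epistemic value per translation direction.

    For each admissible object position the agent (at the origin, facing the
    object) scores its eight first-step translations; each translation's
    direction is expressed relative to the object direction and the values
    are averaged per direction bin across positions, separately for the two
    geometries.  Columns: mode, angle, mean_value, stderr, n_positions.
    """
    rows = []
    positions = config.positions()
    for mode, geometry in (
        ("euclidean", GeometryConfig.euclidean()),
        ("projective", GeometryConfig.projective(config.gamma)),
    ):
        bins: dict[float, list[float]] = {}
        for obj in positions:
            sim = SimulationConfig(
                geometry=geometry,
                object_positions=(tuple(obj),),
                agent_start=(0.0, 0.0),
                epsilon=config.epsilon,
                k=config.k,
                step_norm=config.step_norm,
                scheme=config.scheme,
                n_steps=1,
            )
            state = initial_state(sim)
            for move in build_action_set(state, sim):
                if move.kind != "translate":
                    continue
                value = evaluate_move(state, move, 0, sim)
                bins.setdefault(round(move.angle, 12), []).append(value)
        for angle in sorted(bins):
            vals = np.asarray(bins[angle])
            rows.append(
                {
                    "mode": mode,
                    "angle": angle,
                    "mean_value": vals.mean(),
                    "stderr": vals.std(ddof=1) / math.sqrt(len(vals)),
                    "n_positions": len(vals),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepConfig:
    """(gamma, epsilon) grid for the two-object behaviour sweep.

    Every cell runs the identical two-object scenario except for the swept
    pair; gamma = 0 is the Euclidean limit.
    """

    gamma_values: tuple = (0.0, 0.1, 0.25, 0.5, 0.75, 1.0)
    epsilon_values: tuple = (0.1, 0.25, 0.5, 0.75, 1.0)
    n_steps: int = 40
    base: SimulationConfig | None = None

    def resolved_base(self) -> SimulationConfig:
        base = self.base or two_object_config(GeometryConfig.projective(0.0))
        return replace(base, n_steps=self.n_steps)


def run_behavior_sweep(config: SweepConfig) -> pd.DataFrame:
    """Swap/reach metrics over the (gamma, epsilon) grid.

    Columns: gamma, epsilon, swap_count, reach_count, final_x, final_y.
    """
    base = config.resolved_base()
    rows = []
    for gamma in config.gamma_values:
        for epsilon in config.epsilon_values:
            sim = replace(
                base,
                geometry=GeometryConfig.projective(gamma),
                epsilon=epsilon,
            )
            trajectory = run_simulation(sim)
            metrics = compute_metrics(trajectory)
            final = trajectory.positions()[-1]
            rows.append(
                {
                    "gamma": gamma,
                    "epsilon": epsilon,
                    "swap_count": metrics["swap_count"],
                    "reach_count": metrics["reach_count"],
                    "final_x": final[0],
                    "final_y": final[1],
                }
            )
    return pd.DataFrame(rows)


# -- optional plotting --------------------------------------------------------


def plot_trajectory(trajectory, ax=None):
    """Agent path and object positions in the world plane."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    start = np.asarray(trajectory.config.agent_start)
    path = np.vstack([start, trajectory.positions()])
    ax.plot(path[:, 0], path[:, 1], "o-", ms=3, label="agent")
    objs = trajectory.config.objects
    ax.plot(objs[:, 0], objs[:, 1], "r*", ms=12, label="objects")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_aspect("equal")
    ax.legend()
    return ax


def plot_direction_profile(profile: pd.DataFrame, ax=None):
    """Mean epistemic value versus translation direction, per geometry."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for mode, sub in profile.groupby("mode"):
        sub = sub.sort_values("angle")
        ax.errorbar(
            sub["angle"], sub["mean_value"], yerr=sub["stderr"], label=mode
        )
    ax.set_xlabel("translation direction relative to object (rad)")
    ax.set_ylabel("mean epistemic value (nats)")
    ax.legend()
    return ax


def plot_sweep_heatmaps(sweep: pd.DataFrame, axes=None):
    """Swap- and reach-count heatmaps over the (gamma, epsilon) grid."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, metric in zip(axes, ("swap_count", "reach_count")):
        pivot = sweep.pivot(index="gamma", columns="epsilon", values=metric)
        im = ax.imshow(pivot.values, origin="lower", aspect="auto")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns)
        ax.set_yticks(range(len(pivot.index)), pivot.index)
        ax.set_xlabel("epsilon")
        ax.set_ylabel("gamma")
        ax.set_title(metric)
        plt.colorbar(im, ax=ax)
    return axes
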