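"""The curiosity-driven exploration loop.

One step of the loop: the agent enumerates candidate moves (eight planar
translations of a fixed norm — one of them aimed straight at the faced
object — plus an idle state, optionally crossed with a choice of which
object to orient toward), scores each by the epistemic value of its
one-step-ahead pushforward beliefs, executes the best move, observes the
objects inside its field of view, and conditions the corresponding beliefs.
Objects outside the field of view are left untouched (Pearl's update) and
contribute zero value.

Beliefs are kept per object in the chart of the frame that faces that
object (the agent imagines facing each object when planning); orientation
choices therefore affect candidate values only through the field-of-view
mask.  If every candidate of the winning orientation scores within a small
tolerance of that orientation's idle state, the differences are treated as
numerical noise and the agent stays put.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (
    Frame,
    GeometryConfig,
    HorizonError,
    apply_to_plane,
    embed_plane,
    projective_chart,
    transition_map,
    world_to_frame,
)
from .inference import (
    GaussianBelief,
    PushforwardScheme,
    SensorModel,
    condition_on_observation,
    epistemic_value,
    pearl_update_unobserved,
    pushforward,
)

__all__ = [
    "Move",
    "AgentState",
    "SimulationConfig",
    "TrajectoryStep",
    "Trajectory",
    "build_action_set",
    "evaluate_move",
    "select_move",
    "observe",
    "fov_mask",
    "run_simulation",
    "run_one_object",
    "run_two_object",
    "compute_metrics",
]

_DEFAULT_FORWARD = np.array([0.0, 1.0])


@dataclass(frozen=True)
class Move:
    """A candidate action: a planar translation plus an orientation choice.

    ``angle`` is the translation direction relative to the faced object
    (0 = straight toward it), kept for logging; it is NaN for idle.
    """

    kind: str  # "idle" | "translate"
    translation: np.ndarray  # (2,) world-plane displacement
    angle: float
    target_object: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.translation, dtype=float).reshape(2)
        object.__setattr__(self, "translation", t)
        if self.kind not in ("idle", "translate"):
            raise ValueError(f"unknown move kind {self.kind!r}")
        if self.kind == "idle" and np.linalg.norm(t) > 0:
            raise ValueError("idle moves must have zero translation")


@dataclass
class AgentState:
    """Pose and beliefs of the agent: planar position, faced object, beliefs."""

    position: np.ndarray
    oriented_object: int
    beliefs: list[GaussianBelief]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)

    def frame(self, objects) -> Frame:
        """Frame at the current position facing the oriented object."""
        return _object_frame(
            self.position, np.asarray(objects)[self.oriented_object]
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Scene, sensor and algorithm parameters for one simulation run."""

    geometry: GeometryConfig
    object_positions: tuple
    agent_start: tuple = (0.0, 0.0)
    epsilon: float = 0.1
    k: float = 0.01
    step_norm: float = 0.1
    n_steps: int = 20
    fov_half_angle: float = math.radians(20.0)
    idle_tolerance: float = 1e-4
    seed: int = 0
    observation_noise: bool = False
    scheme: PushforwardScheme = field(default_factory=PushforwardScheme)

    def __post_init__(self) -> None:
        objs = tuple(tuple(float(c) for c in o) for o in self.object_positions)
        if not objs:
            raise ValueError("at least one object is required")
        object.__setattr__(self, "object_positions", objs)
        object.__setattr__(
            self, "agent_start", tuple(float(c) for c in self.agent_start)
        )
        for name in ("epsilon", "k", "step_norm", "idle_tolerance"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be nonnegative")
        if not 0 < self.fov_half_angle <= math.pi:
            raise ValueError("fov_half_angle must lie in (0, pi]")

    @property
    def objects(self) -> np.ndarray:
        return np.asarray(self.object_positions, dtype=float)

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "object_positions": [list(o) for o in self.object_positions],
            "agent_start": list(self.agent_start),
            "epsilon": self.epsilon,
            "k": self.k,
            "step_norm": self.step_norm,
            "n_steps": self.n_steps,
            "fov_half_angle": self.fov_half_angle,
            "idle_tolerance": self.idle_tolerance,
            "seed": self.seed,
            "observation_noise": self.observation_noise,
            "scheme": {
                "method": self.scheme.method,
                "n_samples": self.scheme.n_samples,
                "seed": self.scheme.seed,
                "quadrature_order": self.scheme.quadrature_order,
            },
        }


def _object_frame(position2, object2, fallback_forward3=None) -> Frame:
    """Frame at a planar position facing a planar object."""
    fallback = (
        (0.0, 0.0, 1.0) if fallback_forward3 is None else fallback_forward3
    )
    return Frame.facing(
        embed_plane(np.asarray(position2, dtype=float)),
        embed_plane(np.asarray(object2, dtype=float)),
        fallback_forward=fallback,
    )


def _chart(frame: Frame, geo: GeometryConfig):
    if geo.mode == "euclidean":
        return world_to_frame(frame)
    return projective_chart(frame, geo.gamma)


def _exec_scheme(config: SimulationConfig) -> PushforwardScheme:
    if config.geometry.mode == "euclidean":
        return PushforwardScheme(method="closed_form_rigid")
    return config.scheme


def initial_state(config: SimulationConfig) -> AgentState:
    """Agent at its start pose, facing object 0, with isotropic priors.

    Each prior is centred on the internal-coordinate image of the true
    object position (the agent knows where to look but not precisely where
    the object is) with covariance k * I.
    """
    pos = np.asarray(config.agent_start, dtype=float)
    beliefs = []
    for obj in config.objects:
        chart = _chart(_object_frame(pos, obj), config.geometry)
        mean = apply_to_plane(chart, obj)
        beliefs.append(GaussianBelief.isotropic(mean, config.k))
    return AgentState(pos, 0, beliefs)


def _rot(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


def _wrap(angle: float) -> float:
    """Wrap an angle into [-pi, pi)."""
    return float((angle + math.pi) % (2.0 * math.pi) - math.pi)


def build_action_set(state: AgentState, config: SimulationConfig) -> list[Move]:
    """Candidate moves: idle plus eight equal-norm translations.

    The translations are at 45-degree increments rotated so that one points
    straight at the currently faced object.  Translations aiming at an
    object already closer than ``step_norm`` (which the agent could not
    approach without overstepping) are excluded.  With several objects the
    set is crossed with the orientation choices.
    """
    objects = config.objects
    pos = state.position
    toward = objects[state.oriented_object] - pos
    norm = np.linalg.norm(toward)
    unit = toward / norm if norm > 1e-9 else _DEFAULT_FORWARD

    moves = [Move("idle", np.zeros(2), math.nan)]
    for j in range(8):
        angle = j * math.pi / 4.0
        direction = _rot(angle) @ unit
        blocked = False
        for obj in objects:
            gap = obj - pos
            dist = np.linalg.norm(gap)
            if dist < config.step_norm and dist > 1e-9:
                if direction @ (gap / dist) > 1.0 - 1e-9:
                    blocked = True
        if not blocked:
            moves.append(
                Move("translate", config.step_norm * direction, _wrap(angle))
            )
    if len(objects) == 1:
        return moves
    return [
        replace(m, target_object=j)
        for j in range(len(objects))
        for m in moves
    ]


def evaluate_move(
    state: AgentState,
    move: Move,
    object_index: int,
    config: SimulationConfig,
) -> float:
    """Epistemic value of one object's belief pushed through one move.

    The before/after frames both face the object (the planning convention);
    the pushforward uses the exact rigid form in Euclidean mode and the
    configured scheme otherwise.  Moves whose evaluation crosses the
    projective horizon score -inf and are thereby rejected.
    """
    obj = config.objects[object_index]
    f0 = _object_frame(state.position, obj)
    f1 = _object_frame(
        state.position + move.translation, obj, fallback_forward3=f0.forward
    )
    psi = transition_map(f0, f1, config.geometry)
    try:
        pushed = pushforward(
            state.beliefs[object_index], psi, _exec_scheme(config)
        )
    except HorizonError:
        warnings.warn(
            "candidate move crossed the projective horizon; rejected",
            RuntimeWarning,
            stacklevel=2,
        )
        return -math.inf
    return epistemic_value(pushed, SensorModel(config.epsilon))


def _visible_from(position2, orientation_dir2, objects, fov_half_angle):
    """Indices of objects within the field of view from a pose."""
    visible = set()
    n0 = np.linalg.norm(orientation_dir2)
    unit = orientation_dir2 / n0 if n0 > 1e-9 else _DEFAULT_FORWARD
    for i, obj in enumerate(np.asarray(objects, dtype=float)):
        gap = obj - position2
        dist = np.linalg.norm(gap)
        if dist < 1e-9:
            visible.add(i)
            continue
        cosang = float(np.clip(unit @ (gap / dist), -1.0, 1.0))
        if math.acos(cosang) <= fov_half_angle + 1e-12:
            visible.add(i)
    return visible


def fov_mask(state: AgentState, config: SimulationConfig) -> set:
    """Objects currently visible (angular distance <= fov_half_angle, closed)."""
    objects = config.objects
    direction = objects[state.oriented_object] - state.position
    return _visible_from(
        state.position, direction, objects, config.fov_half_angle
    )


def select_move(
    moves: list[Move], values: list[float], config: SimulationConfig
) -> int:
    """Index of the chosen move.

    The argmax wins (ties broken by lowest index).  But if every candidate
    sharing the winner's orientation lies within ``idle_tolerance`` of that
    orientation's idle value — differences at the level of numerical
    imprecision — the idle state is selected instead.
    """
    vals = np.asarray(values, dtype=float)
    best = int(np.argmax(vals))
    target = moves[best].target_object
    group = [i for i, m in enumerate(moves) if m.target_object == target]
    idle_idx = next(i for i in group if moves[i].kind == "idle")
    if np.all(np.abs(vals[group] - vals[idle_idx]) <= config.idle_tolerance):
        return idle_idx
    return best


def observe(
    state: AgentState, object_index: int, config: SimulationConfig, rng=None
):
    """Internal-coordinate observation of one object, or None if unseen.

    The observation is the chart image of the true object position in the
    frame facing that object (noiseless unless ``observation_noise`` is
    enabled, in which case seeded N(0, eps^2 I) noise is added).
    """
    if object_index not in fov_mask(state, config):
        return None
    obj = config.objects[object_index]
    frame = _object_frame(state.position, obj)
    y = apply_to_plane(_chart(frame, config.geometry), obj)
    if config.observation_noise:
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        y = y + config.epsilon * rng.standard_normal(2)
    return y


@dataclass(frozen=True)
class TrajectoryStep:
    """Everything recorded about one executed step."""

    step: int
    position: np.ndarray
    oriented_object: int
    move_kind: str
    move_angle: float
    candidate_values: np.ndarray
    per_object_values: tuple
    observed: tuple
    distances: tuple


@dataclass
class Trajectory:
    """Per-step log of a simulation run."""

    config: SimulationConfig
    steps: list = field(default_factory=list)

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.steps]).reshape(-1, 2)

    def orientations(self) -> np.ndarray:
        return np.array([s.oriented_object for s in self.steps], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        n_obj = len(self.config.object_positions)
        rows = []
        for s in self.steps:
            row = {
                "step": s.step,
                "x": s.position[0],
                "y": s.position[1],
                "oriented_object": s.oriented_object,
                "move_kind": s.move_kind,
                "move_angle": s.move_angle,
                "C_total": float(np.sum(s.per_object_values)),
            }
            for i in range(n_obj):
                row[f"C_obj{i + 1}"] = s.per_object_values[i]
                row[f"observed_{i + 1}"] = s.observed[i]
                row[f"dist_{i + 1}"] = s.distances[i]
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        out = {"config": self.config.to_dict(), "n_steps": len(self.steps)}
        if self.steps:
            out["final_position"] = self.steps[-1].position.tolist()
            out.update(compute_metrics(self))
        return out

    def write(self, csv_path, json_path=None) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(self.summary(), fh, indent=2, default=float)


def _candidate_totals(
    state: AgentState, moves: list[Move], config: SimulationConfig
):
    """Total (FOV-masked, summed over objects) value of each candidate.

    Per-object values depend only on the translation, so they are cached
    across orientation choices.
    """
    objects = config.objects
    n_obj = len(objects)
    cache: dict[tuple, float] = {}

    def value(i_obj: int, move: Move) -> float:
        key = (i_obj, move.translation.tobytes())
        if key not in cache:
            cache[key] = evaluate_move(state, move, i_obj, config)
        return cache[key]

    totals = []
    for move in moves:
        new_pos = state.position + move.translation
        direction = objects[move.target_object] - new_pos
        visible = _visible_from(
            new_pos, direction, objects, config.fov_half_angle
        )
        totals.append(sum(value(i, move) for i in visible) if visible else 0.0)
    return totals


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Run the exploration loop for ``n_steps`` steps.

    Per step: score all candidates one step ahead, select (idle wins inside
    the numerical-noise band), execute by pushing every belief through its
    frame-transition map, observe the objects in view and condition their
    beliefs; hidden objects keep their beliefs (Pearl update, zero value).
    """
    state = initial_state(config)
    sensor = SensorModel(config.epsilon)
    rng = np.random.default_rng(config.seed)
    trajectory = Trajectory(config=config)
    objects = config.objects

    for step in range(1, config.n_steps + 1):
        moves = build_action_set(state, config)
        totals = _candidate_totals(state, moves, config)
        chosen = moves[select_move(moves, totals, config)]

        old_pos = state.position
        new_pos = old_pos + chosen.translation
        pushed = []
        for i, obj in enumerate(objects):
            f0 = _object_frame(old_pos, obj)
            f1 = _object_frame(new_pos, obj, fallback_forward3=f0.forward)
            psi = transition_map(f0, f1, config.geometry)
            pushed.append(
                pushforward(state.beliefs[i], psi, _exec_scheme(config))
            )
        state.position = new_pos
        state.oriented_object = chosen.target_object

        visible = fov_mask(state, config)
        observed, per_object_values, new_beliefs = [], [], []
        for i in range(len(objects)):
            if i in visible:
                y = observe(state, i, config, rng=rng)
                new_beliefs.append(condition_on_observation(pushed[i], sensor, y))
                per_object_values.append(epistemic_value(pushed[i], sensor))
                observed.append(True)
            else:
                belief, contribution = pearl_update_unobserved(pushed[i])
                new_beliefs.append(belief)
                per_object_values.append(contribution)
                observed.append(False)
        state.beliefs = new_beliefs

        trajectory.steps.append(
            TrajectoryStep(
                step=step,
                position=state.position.copy(),
                oriented_object=state.oriented_object,
                move_kind=chosen.kind,
                move_angle=chosen.angle,
                candidate_values=np.asarray(totals, dtype=float),
                per_object_values=tuple(per_object_values),
                observed=tuple(observed),
                distances=tuple(
                    float(np.linalg.norm(obj - state.position))
                    for obj in objects
                ),
            )
        )
    return trajectory


def run_one_object(config: SimulationConfig) -> Trajectory:
    """Exploration with a single object (no orientation choices)."""
    if len(config.object_positions) != 1:
        raise ValueError("run_one_object requires exactly one object")
    return run_simulation(config)


def run_two_object(config: SimulationConfig) -> Trajectory:
    """Exploration with two objects, rotations and field-of-view masking."""
    if len(config.object_positions) != 2:
        raise ValueError("run_two_object requires exactly two objects")
    return run_simulation(config)


def compute_metrics(trajectory: Trajectory, config=None) -> dict:
    """Swap and reach counts of a trajectory.

    A swap is a step on which the faced object changes.  A reach event is
    the first step of an approach episode on which the distance to the faced
    object drops below ``step_norm``; leaving the reach zone re-arms the
    event, so a re-approached object counts again.
    """
    config = config or trajectory.config
    objects = config.objects
    start = np.asarray(config.agent_start, dtype=float)
    in_zone = [
        bool(np.linalg.norm(obj - start) < config.step_norm) for obj in objects
    ]
    previous_orientation = 0  # the agent starts facing object 0
    swap_count = 0
    reach_count = 0
    for record in trajectory.steps:
        if record.oriented_object != previous_orientation:
            swap_count += 1
        previous_orientation = record.oriented_object
        for i in range(len(objects)):
            close = record.distances[i] < config.step_norm
            if close and not in_zone[i] and i == record.oriented_object:
                reach_count += 1
            in_zone[i] = close
    return {"swap_count": swap_count, "reach_count": reach_count}
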