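"""The foraging world: a 1 m x 1 m torus with two robots and two food items.

Robots are hard discs (7 cm diameter) driven by differential-drive
kinematics from their two wheel velocities.  Food items (5.4 cm diameter)
are non-solid; driving over one eats it (one fitness unit) and it respawns
uniformly at random.  Each robot becomes stuck with a constant per-step
probability; a stuck robot turns blue and regains mobility at a low
constant hazard, or five times faster while its partner stays within 1 cm
(edge-to-edge) -- helping.  A robot senses the world through 8 proximity
sensors (detecting the other robot only) and a 9-neuron RGB camera covering
a 60 degree forward cone.

This module exposes the world at two granularities: a step-level API
(:class:`WorldState`, :func:`step`, :func:`sense_proximity`,
:func:`sense_camera`) for inspection and unit testing, and
:func:`run_evaluation`, which runs a complete evaluation of a genome pair
in one compiled call.  Both run through the same compiled kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernels as K
from .controller import Network, NetworkTopology, MemoryState, build_network
from .genome import Genome, decode_genome

__all__ = [
    "ArenaConfig",
    "WorldState",
    "StepEvents",
    "EvalResult",
    "step",
    "sense_proximity",
    "sense_camera",
    "run_evaluation",
    "simulate_stuck_episodes",
    "save_trajectory",
    "TRAJECTORY_COLUMNS",
]

TRAJECTORY_COLUMNS = (
    "x0",
    "y0",
    "heading0",
    "stuck0",
    "x1",
    "y1",
    "heading1",
    "stuck1",
    "food0",
    "food1",
    "memory0",
    "memory1",
)


class ConfigurationError(ValueError):
    """Invalid arena configuration or placement failure."""


@dataclass(frozen=True)
class ArenaConfig:
    """Physical and stochastic parameters of the world.

    Defaults are the standard experimental values: a 1 m toroidal arena,
    7 cm robots, 5.4 cm food, 100 ms control steps, wheel speeds up to
    8.2 cm/s, sticking and self-release probabilities of 5e-4 per step,
    a five-fold release speed-up while helped, a 1 cm helping gap, and
    20,000-step evaluations.
    """

    arena_side: float = 1.0
    robot_diameter: float = 0.07
    food_diameter: float = 0.054
    n_food: int = 2
    dt: float = 0.1
    wheel_vmax: float = 8.2
    p_stuck: float = 5e-4
    p_self_release: float = 5e-4
    help_multiplier: float = 5.0
    help_gap: float = 0.01
    proximity_range: float = 0.05
    eval_steps: int = 20_000

    def __post_init__(self) -> None:
        for name in ("arena_side", "robot_diameter", "food_diameter", "dt",
                     "wheel_vmax", "help_gap", "proximity_range"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("p_stuck", "p_self_release"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        if self.help_multiplier * self.p_self_release > 1.0:
            raise ConfigurationError(
                "helped release probability exceeds 1 per step"
            )
        if self.n_food < 1 or self.eval_steps < 0:
            raise ConfigurationError("n_food must be >= 1 and eval_steps >= 0")

    def params_array(self) -> np.ndarray:
        p = np.empty(K.N_PARAMS)
        p[K.P_SIDE] = self.arena_side
        p[K.P_ROBOT_R] = self.robot_diameter / 2.0
        p[K.P_FOOD_R] = self.food_diameter / 2.0
        p[K.P_DT] = self.dt
        p[K.P_VMAX] = self.wheel_vmax
        p[K.P_PSELF] = self.p_self_release
        p[K.P_HELPMULT] = self.help_multiplier
        p[K.P_HELPGAP] = self.help_gap
        p[K.P_PROXRANGE] = self.proximity_range
        return p


@dataclass
class StepEvents:
    """Per-robot events reported by one world step."""

    stuck_onset: tuple[bool, bool]
    released: tuple[bool, bool]
    helped: tuple[bool, bool]


@dataclass
class WorldState:
    """Mutable world state for the step-level API.

    Holds positions/headings of the two robots, food positions, stuck
    flags, per-robot food and memory counters, and its own random stream.
    A robot's display color is derived: blue iff stuck, green otherwise.
    """

    config: ArenaConfig
    pos: np.ndarray
    heading: np.ndarray
    stuck: np.ndarray
    food: np.ndarray
    food_counts: np.ndarray = field(default=None)  # type: ignore[assignment]
    step_index: int = 0
    _rs: np.ndarray = field(default=None)  # type: ignore[assignment]
    _mem_opp: np.ndarray = field(default=None)  # type: ignore[assignment]
    _mem_help: np.ndarray = field(default=None)  # type: ignore[assignment]
    helping_given: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pos = np.array(self.pos, dtype=np.float64).reshape(2, 2)
        self.heading = np.array(self.heading, dtype=np.float64).reshape(2)
        self.stuck = np.array(self.stuck, dtype=np.uint8).reshape(2)
        self.food = np.array(self.food, dtype=np.float64).reshape(-1, 2)
        if self.food_counts is None:
            self.food_counts = np.zeros(2, np.int64)
        if self._rs is None:
            self._rs = _seed_state(0)
        if self._mem_opp is None:
            self._mem_opp = np.zeros(2, np.int64)
        if self._mem_help is None:
            self._mem_help = np.zeros(2, np.int64)
        if self.helping_given is None:
            self.helping_given = np.zeros(2, np.int64)

    @classmethod
    def create(
        cls,
        config: ArenaConfig,
        seed: int,
        *,
        pos=None,
        heading=None,
        food=None,
        stuck=(False, False),
    ) -> "WorldState":
        """Build a world, drawing any unspecified geometry at random."""
        rs = _seed_state(seed)
        params = config.params_array()
        if pos is None or heading is None:
            p = np.empty((2, 2))
            h = np.empty(2)
            status = K.place_robots(rs, params, 0.0, p, h)
            if status != K.STATUS_OK:
                raise ConfigurationError("robot placement failed")
            pos = p if pos is None else pos
            heading = h if heading is None else heading
        if food is None:
            food = np.array(
                [
                    [K._uniform(rs) * config.arena_side, K._uniform(rs) * config.arena_side]
                    for _ in range(config.n_food)
                ]
            )
        world = cls(
            config=config,
            pos=pos,
            heading=heading,
            stuck=np.array(stuck, dtype=np.uint8),
            food=food,
        )
        world._rs = rs
        return world

    def memory_state(self, robot_index: int) -> MemoryState:
        return MemoryState(
            opportunities=int(self._mem_opp[robot_index]),
            helps=int(self._mem_help[robot_index]),
        )


def _seed_state(seed: int) -> np.ndarray:
    raw = np.random.SeedSequence(seed).generate_state(1, np.uint64)
    return np.array(raw, dtype=np.uint64)


def step(
    world: WorldState,
    velocities,
    *,
    p_stuck: tuple[float, float] | None = None,
    can_self_release: tuple[bool, bool] = (True, True),
) -> tuple[WorldState, StepEvents]:
    """Advance the world one step under the given wheel velocities (cm/s).

    Mutates and returns ``world``.  ``p_stuck`` overrides the per-robot
    sticking probability (e.g. 0 to pin a robot mobile).
    """
    cfg = world.config
    vel = np.asarray(velocities, dtype=np.float64).reshape(2, 2)
    if np.abs(vel).max() > cfg.wheel_vmax + 1e-9:
        raise ValueError("wheel velocity beyond the physical maximum")
    ps = np.full(2, cfg.p_stuck) if p_stuck is None else np.asarray(p_stuck, float)
    cs = np.array(can_self_release, dtype=np.uint8)
    ev = np.zeros((2, 3), np.int64)
    K.step_core(
        world.pos,
        world.heading,
        world.stuck,
        world.food,
        world.food_counts,
        world._mem_opp,
        world._mem_help,
        world.helping_given,
        vel,
        cfg.params_array(),
        ps,
        cs,
        world._rs,
        ev,
    )
    world.step_index += 1
    events = StepEvents(
        stuck_onset=(bool(ev[0, 0]), bool(ev[1, 0])),
        released=(bool(ev[0, 1]), bool(ev[1, 1])),
        helped=(bool(ev[0, 2]), bool(ev[1, 2])),
    )
    return world, events


def sense_proximity(
    world: WorldState, robot_index: int, *, include_partner: bool = True
) -> np.ndarray:
    """Eight proximity activations in [0, 1] for one robot."""
    out = np.empty(8)
    o = 1 - robot_index
    K.sense_proximity(
        world.pos[robot_index, 0],
        world.pos[robot_index, 1],
        world.heading[robot_index],
        world.pos[o, 0],
        world.pos[o, 1],
        1 if include_partner else 0,
        world.config.params_array(),
        out,
    )
    return out


def sense_camera(
    world: WorldState, robot_index: int, *, include_partner: bool = True
) -> np.ndarray:
    """Nine camera activations (red, green, blue x 3 sectors) in [0, 1]."""
    out = np.empty(9)
    o = 1 - robot_index
    K.sense_camera(
        world.pos[robot_index, 0],
        world.pos[robot_index, 1],
        world.heading[robot_index],
        world.pos[o, 0],
        world.pos[o, 1],
        world.stuck[o],
        1 if include_partner else 0,
        world.food,
        world.config.params_array(),
        out,
    )
    return out


@dataclass
class EvalResult:
    """Outcome of one full evaluation of a robot pair.

    ``stuck_episodes[r]`` lists completed episodes of robot ``r`` as
    ``(start_step, end_step, helped)``; episodes begun before step 0 have
    start -1, so duration is always ``end - start``.  ``censored[r]`` is
    the start step of an episode still ongoing at the end, or None.
    """

    food_counts: tuple[int, int]
    helping_given: tuple[int, int]
    stuck_episodes: tuple[list, list]
    censored: tuple[int | None, int | None]
    memory: tuple[MemoryState, MemoryState]
    steps_done: int
    trajectory: np.ndarray | None = None


def _networks_for(
    genome_pair: tuple[Genome, Genome], topology: NetworkTopology
) -> list[Network]:
    nets = []
    for g in genome_pair:
        if g.spec.n_weights != topology.n_weights:
            raise ConfigurationError(
                f"genome encodes {g.spec.n_weights} weights but the topology "
                f"needs {topology.n_weights}"
            )
        nets.append(build_network(decode_genome(g), topology))
    return nets


def run_evaluation(
    genome_pair: tuple[Genome, Genome],
    topology: NetworkTopology,
    config: ArenaConfig,
    seed: int,
    *,
    n_steps: int | None = None,
    memory_clamp: tuple[int, int] = (-1, -1),
    partner_visible: tuple[bool, bool] = (True, True),
    p_stuck: tuple[float, float] | None = None,
    can_self_release: tuple[bool, bool] = (True, True),
    init_stuck: tuple[bool, bool] = (False, False),
    min_initial_gap: float = 0.0,
    end_on_release_of: int = -1,
    record_trajectory: bool = False,
) -> EvalResult:
    """Run one evaluation; fully reproducible from ``seed``.

    The keyword flags expose the behavioral-assay variants: a permanently
    stuck partner (``init_stuck`` + ``can_self_release``), an invisible
    partner (``partner_visible``), and a clamped memory input
    (``memory_clamp``, -1 meaning unclamped).
    """
    cfg = config
    steps = cfg.eval_steps if n_steps is None else n_steps
    nets = _networks_for(genome_pair, topology)
    ps = np.full(2, cfg.p_stuck) if p_stuck is None else np.asarray(p_stuck, float)
    traj = (
        np.zeros((steps, len(TRAJECTORY_COLUMNS)))
        if record_trajectory
        else np.zeros((1, len(TRAJECTORY_COLUMNS)))
    )
    out = K.run_eval(
        nets[0].w_in,
        nets[0].w_out,
        nets[1].w_in,
        nets[1].w_out,
        1 if topology.has_memory else 0,
        np.asarray(memory_clamp, dtype=np.int8),
        np.asarray([1 if v else 0 for v in partner_visible], dtype=np.uint8),
        cfg.params_array(),
        ps,
        np.asarray([1 if v else 0 for v in can_self_release], dtype=np.uint8),
        steps,
        cfg.n_food,
        np.asarray([1 if v else 0 for v in init_stuck], dtype=np.uint8),
        min_initial_gap,
        end_on_release_of,
        _seed_state(seed)[0],
        record_trajectory,
        traj,
    )
    (
        status,
        steps_done,
        food_counts,
        helping_given,
        mem_opp,
        mem_help,
        n_ep,
        ep_start,
        ep_end,
        ep_helped,
    ) = out
    if status != K.STATUS_OK:
        raise ConfigurationError("robot placement failed after bounded retries")
    episodes: list[list] = [[], []]
    censored: list[int | None] = [None, None]
    for r in range(2):
        for k in range(n_ep[r]):
            if ep_helped[r, k] < 0:
                censored[r] = int(ep_start[r, k])
            else:
                episodes[r].append(
                    (int(ep_start[r, k]), int(ep_end[r, k]), bool(ep_helped[r, k]))
                )
    return EvalResult(
        food_counts=(int(food_counts[0]), int(food_counts[1])),
        helping_given=(int(helping_given[0]), int(helping_given[1])),
        stuck_episodes=(episodes[0], episodes[1]),
        censored=(censored[0], censored[1]),
        memory=(
            MemoryState(int(mem_opp[0]), int(mem_help[0])),
            MemoryState(int(mem_opp[1]), int(mem_help[1])),
        ),
        steps_done=int(steps_done),
        trajectory=traj[: int(steps_done)] if record_trajectory else None,
    )


def simulate_stuck_episodes(
    n_episodes: int,
    config: ArenaConfig,
    seed: int,
    *,
    partner_adjacent: bool,
    self_release: bool = True,
) -> np.ndarray:
    """Sample durations of stuck episodes with a motionless partner.

    With ``partner_adjacent`` the partner sits inside the helping gap for
    the whole episode (continuously helped); otherwise it is far away.
    Durations are geometric with mean 1/(help_multiplier * p_self_release)
    when helped and 1/p_self_release when not.
    """
    if not self_release and not partner_adjacent:
        raise ConfigurationError("a never-helped robot with no self-release never frees itself")
    gap = config.help_gap / 2.0 if partner_adjacent else 10.0 * config.help_gap
    return K.stuck_episode_durations(
        n_episodes,
        gap,
        config.params_array(),
        1 if self_release else 0,
        _seed_state(seed)[0],
    )


def save_trajectory(path: str | Path, result: EvalResult) -> None:
    """Write the per-step trajectory of an evaluation as TSV."""
    if result.trajectory is None:
        raise ValueError("evaluation was run without record_trajectory=True")
    header = "step\t" + "\t".join(TRAJECTORY_COLUMNS)
    rows = [header]
    for t, row in enumerate(result.trajectory):
        rows.append(str(t) + "\t" + "\t".join(f"{v:.6g}" for v in row))
    Path(path).write_text("\n".join(rows) + "\n")
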