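"""Core agent-based simulation loop.

The engine follows the classic initialize-then-iterate structure of
agent-based tissue simulators.  A simulation holds a population of agents,
a list of *operations* and a shared seeded random generator.  Operations
come in two kinds:

* ``per-agent`` operations run once per live agent per due iteration
  (op-major order: an operation is applied to every agent, in ascending
  agent-id order, before the next operation starts);
* ``standalone`` operations run once per due iteration (substance
  diffusion updates, data collection, ...).

Each operation carries an execution *frequency* ``f``: it fires on
iterations ``0, f, 2f, ...``, which allows coarse processes to run on a
slower clock than the mechanical/biological core loop.

Agent creation and removal are *deferred*: behaviors queue them on an
:class:`ExecutionContext`, and the queue is committed at the end of the
iteration.  An agent created at iteration ``i`` is therefore invisible to
every neighborhood query and per-agent operation at iteration ``i`` and
becomes visible at ``i + 1``.  Agent ids are never reused, even after
removal.

Execution is strictly sequential and deterministic: a full run is a pure
function of the scenario configuration and the seed.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

OPEN = "open"
TOROIDAL = "toroidal"


@dataclass
class SimulationParams:
    """Global engine settings.

    ``time_step`` is the simulated time advanced per iteration, in whatever
    unit the scenario adopts (hours for the spheroid, days for the epidemic,
    minutes are equally fine); all rates in a scenario must use the same
    unit.  ``bounds`` is an axis-aligned box given as (min, max) corner
    3-vectors.  In ``toroidal`` mode positions wrap around the box; in
    ``open`` mode they are clamped to it.
    """

    time_step: float = 1.0
    n_iterations: int = 0
    bounds: tuple = ((0.0, 0.0, 0.0), (100.0, 100.0, 100.0))
    boundary_mode: str = OPEN
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        lo, hi = np.asarray(self.bounds[0], float), np.asarray(self.bounds[1], float)
        if not np.all(lo < hi):
            raise ValueError("bounds min must be < max on each axis")
        if self.boundary_mode not in (OPEN, TOROIDAL):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.bounds[0], float)

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.bounds[1], float)

    @property
    def lengths(self) -> np.ndarray:
        return self.hi - self.lo


@dataclass
class Behavior:
    """A per-agent update rule, attachable and removable at run time.

    ``run(agent, sim)`` must not mutate the committed population directly;
    creations and removals go through ``sim.ctx``.  The two flags control
    what happens to the behavior when its agent divides: whether a copy is
    attached to the new agent and whether the original is removed from the
    mother.
    """

    name: str
    run: Callable
    copy_on_division: bool = False
    remove_from_mother: bool = False


class Agent:
    """Base agent: identity, 3-D position, diameter, attached behaviors."""

    __slots__ = ("id", "position", "diameter", "behaviors", "alive")

    def __init__(self, position, diameter: float = 1.0,
                 behaviors: Sequence[Behavior] = (), agent_id: int | None = None):
        if diameter <= 0:
            raise ValueError("diameter must be > 0")
        self.id: int | None = agent_id
        self.position = np.asarray(position, dtype=float).copy()
        self.diameter = float(diameter)
        self.behaviors: list[Behavior] = list(behaviors)
        self.alive = True

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<{type(self).__name__} id={self.id} pos={np.round(self.position, 3)}>"


def transfer_behaviors(mother_behaviors: Sequence[Behavior]) -> tuple[list[Behavior], list[Behavior]]:
    """Split a mother's behavior list at a division event.

    Returns ``(mother_after, daughter)``: the daughter receives a copy of
    every behavior flagged ``copy_on_division``; the mother keeps every
    behavior not flagged ``remove_from_mother``.  Order is preserved.
    """
    daughter = [copy.copy(b) for b in mother_behaviors if b.copy_on_division]
    mother = [b for b in mother_behaviors if not b.remove_from_mother]
    return mother, daughter


@dataclass
class Operation:
    """A scheduled engine task.

    ``kind`` is ``"per-agent"`` (procedure(agent, sim)) or ``"standalone"``
    (procedure(sim)).  ``frequency=f`` executes the operation every f-th
    iteration, starting at iteration 0.
    """

    name: str
    kind: str
    procedure: Callable
    frequency: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("per-agent", "standalone"):
            raise ValueError(f"unknown operation kind {self.kind!r}")
        if int(self.frequency) < 1:
            raise ValueError("operation frequency must be >= 1")
        self.frequency = int(self.frequency)


def is_due(op: Operation, iteration: int) -> bool:
    """True iff ``op`` executes at ``iteration`` (fires at 0, f, 2f, ...)."""
    if op.frequency < 1:
        raise ValueError("operation frequency must be >= 1")
    return iteration % op.frequency == 0


class ExecutionContext:
    """Staging area enforcing visible-next-iteration agent lifecycle."""

    def __init__(self) -> None:
        self.pending_additions: list[Agent] = []
        self.pending_removals: set[int] = set()

    def clear(self) -> None:
        self.pending_additions = []
        self.pending_removals = set()


class BehaviorError(RuntimeError):
    """A behavior or per-agent operation raised; carries agent context."""


class Simulation:
    """Owns the population, the operation schedule and the shared RNG.

    Behaviors draw randomness from ``sim.rng`` (a single
    ``numpy.random.Generator``); the draw order is fixed by the
    deterministic execution order, so identical (config, seed) pairs give
    bit-identical runs.
    """

    def __init__(self, params: SimulationParams):
        self.params = params
        self.rng = np.random.default_rng(params.rng_seed)
        self.population: dict[int, Agent] = {}
        self.operations: list[Operation] = []
        self.ctx = ExecutionContext()
        self.iteration = 0
        self.environment = None  # rebuilt each iteration by step_once
        self.substances: dict[str, object] = {}
        self._next_id = 0
        self._used_ids: set[int] = set()
        # the built-in per-agent operation running each agent's behaviors
        self.operations.append(Operation("behaviors", "per-agent", self._run_behaviors))

    # -- id management -------------------------------------------------
    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        self._used_ids.add(i)
        return i

    # -- population setup ----------------------------------------------
    def add_agent(self, agent: Agent) -> Agent:
        """Immediately insert an agent (initialization phase only)."""
        if agent.id is None:
            agent.id = self.new_id()
        elif agent.id in self._used_ids and agent.id in self.population:
            raise ValueError(f"agent id {agent.id} already in use")
        else:
            self._used_ids.add(agent.id)
            self._next_id = max(self._next_id, agent.id + 1)
        self.population[agent.id] = agent
        return agent

    # -- deferred lifecycle ---------------------------------------------
    def queue_new_agent(self, agent: Agent) -> Agent:
        """Queue an agent for insertion at the end of this iteration."""
        if agent.id is None:
            agent.id = self.new_id()
        elif agent.id in self._used_ids:
            raise ValueError(f"agent id {agent.id} already used; ids are never reused")
        else:
            self._used_ids.add(agent.id)
            self._next_id = max(self._next_id, agent.id + 1)
        self.ctx.pending_additions.append(agent)
        return agent

    def queue_removal(self, agent_id: int) -> None:
        self.ctx.pending_removals.add(agent_id)

    def commit(self) -> None:
        """Apply queued additions/removals; wrap or clamp positions."""
        for agent in self.ctx.pending_additions:
            self.population[agent.id] = agent
        for agent_id in self.ctx.pending_removals:
            if agent_id in self.population:
                self.population[agent_id].alive = False
                del self.population[agent_id]
            else:
                warnings.warn(f"removal of unknown agent id {agent_id} ignored",
                              stacklevel=2)
        self.ctx.clear()
        lo, hi, lengths = self.params.lo, self.params.hi, self.params.lengths
        if self.params.boundary_mode == TOROIDAL:
            for agent in self.population.values():
                agent.position = lo + np.mod(agent.position - lo, lengths)
        else:
            for agent in self.population.values():
                np.clip(agent.position, lo, hi, out=agent.position)

    # -- operation schedule ----------------------------------------------
    def add_operation(self, op: Operation) -> None:
        self.operations.append(op)

    def schedule(self, name: str, kind: str, procedure: Callable, frequency: int = 1) -> Operation:
        op = Operation(name, kind, procedure, frequency)
        self.operations.append(op)
        return op

    # -- execution --------------------------------------------------------
    def _run_behaviors(self, agent: Agent, sim: "Simulation") -> None:
        for behavior in list(agent.behaviors):
            try:
                behavior.run(agent, sim)
            except Exception as exc:
                raise BehaviorError(
                    f"behavior {behavior.name!r} failed on agent {agent.id} "
                    f"at iteration {sim.iteration}: {exc}") from exc

    def rebuild_environment(self):
        from . import environment as _env

        if self.population:
            self.environment = _env.build_grid(
                self.population.values(),
                bounds=self.params.bounds,
                mode=self.params.boundary_mode,
            )
        else:
            self.environment = None
        return self.environment

    def step_once(self) -> None:
        """One iteration: rebuild index, run due ops, commit the context."""
        self.rebuild_environment()
        due = [op for op in self.operations if is_due(op, self.iteration)]
        for op in due:
            if op.kind == "per-agent":
                for agent_id in sorted(self.population):
                    agent = self.population.get(agent_id)
                    if agent is None or not agent.alive:
                        continue
                    try:
                        op.procedure(agent, self)
                    except BehaviorError:
                        raise
                    except Exception as exc:
                        raise BehaviorError(
                            f"operation {op.name!r} failed on agent {agent_id} "
                            f"at iteration {self.iteration}: {exc}") from exc
        for op in due:
            if op.kind == "standalone":
                op.procedure(self)
        self.commit()
        self.iteration += 1

    def run(self, n_iterations: int | None = None) -> None:
        n = self.params.n_iterations if n_iterations is None else n_iterations
        for _ in range(n):
            self.step_once()

    # -- helpers ---------------------------------------------------------
    def agents(self) -> Iterable[Agent]:
        return self.population.values()

    @property
    def time(self) -> float:
        return self.iteration * self.params.time_step
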