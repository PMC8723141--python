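"""Pairwise sphere-sphere mechanics with overdamped displacement updates.

Cells are modeled as soft spheres.  When two spheres overlap by
``delta = (r_a + r_b) - |p_a - p_b| > 0`` they repel along the line of
centers with a linear-spring force of magnitude ``k * delta`` (an optional
linear adhesion term pulls slightly-separated pairs together).  Motion is
overdamped: the displacement of an agent over a step is ``F/zeta * dt``,
clamped to ``max_displacement_per_step`` so that arbitrarily stiff
contacts cannot destabilize the integration.

Displacements for the whole population are computed from the pre-step
configuration and applied synchronously, matching the engine rule that an
iteration sees the committed state of the previous one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .engine import OPEN, TOROIDAL, Agent, Simulation
from .environment import UniformGridEnvironment, _toroidal_delta


@dataclass
class MechanicsParams:
    repulsion_stiffness: float = 2.0       # force / length
    viscosity: float = 1.0                 # force * time / length
    max_displacement_per_step: float = 3.0  # length
    adhesion_coefficient: float = 0.0      # force / length

    def __post_init__(self) -> None:
        if self.repulsion_stiffness <= 0 or self.viscosity <= 0 \
                or self.max_displacement_per_step <= 0:
            raise ValueError("stiffness, viscosity and max displacement must be > 0")


def pairwise_force(a: Agent, b: Agent, params: MechanicsParams,
                   mode: str = OPEN, lengths=None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Force exerted on ``a`` by ``b``; antisymmetric by construction."""
    delta_vec = np.asarray(a.position, float) - np.asarray(b.position, float)
    if mode == TOROIDAL and lengths is not None:
        L = np.asarray(lengths, float)
        delta_vec = delta_vec - L * np.round(delta_vec / L)
    dist = float(np.linalg.norm(delta_vec))
    overlap = 0.5 * (a.diameter + b.diameter) - dist
    if dist == 0.0:
        # coincident centers: deterministic direction seeded from the ids
        warnings.warn(f"agents {a.id} and {b.id} have coincident centers; "
                      "applying a seeded random separation direction")
        local = np.random.default_rng((min(a.id, b.id), max(a.id, b.id))) \
            if rng is None else rng
        direction = local.normal(size=3)
        direction /= np.linalg.norm(direction)
        return params.repulsion_stiffness * overlap * direction
    direction = delta_vec / dist
    if overlap > 0:
        return params.repulsion_stiffness * overlap * direction
    if params.adhesion_coefficient > 0:
        # weak attraction for slightly separated pairs (within 20% of contact)
        gap = -overlap
        reach = 0.2 * 0.5 * (a.diameter + b.diameter)
        if gap < reach:
            return -params.adhesion_coefficient * gap * direction
    return np.zeros(3)


def compute_displacements(agents, grid: UniformGridEnvironment,
                          params: MechanicsParams, dt: float,
                          mode: str = OPEN, lengths=None) -> dict[int, np.ndarray]:
    """Overdamped displacement per agent from the pre-step configuration."""
    agents = {a.id: a for a in agents}
    radius = float(np.min(grid.box_lengths))
    out: dict[int, np.ndarray] = {}
    for agent_id, agent in agents.items():
        force = np.zeros(3)
        for other_id in grid.neighbors_within(agent, radius):
            force += pairwise_force(agent, agents[other_id], params, mode, lengths)
        disp = force / params.viscosity * dt
        norm = float(np.linalg.norm(disp))
        if norm > params.max_displacement_per_step:
            disp *= params.max_displacement_per_step / norm
        out[agent_id] = disp
    return out


def apply_displacements(agents, displacements: dict[int, np.ndarray],
                        bounds, mode: str = OPEN) -> None:
    """Move agents in place, wrapping (toroidal) or clamping (open)."""
    agents = list(agents)
    if len(displacements) != len(agents):
        raise ValueError(f"got {len(displacements)} displacements "
                         f"for {len(agents)} agents")
    lo = np.asarray(bounds[0], float)
    hi = np.asarray(bounds[1], float)
    for agent in agents:
        agent.position = agent.position + displacements[agent.id]
        if mode == TOROIDAL:
            agent.position = lo + np.mod(agent.position - lo, hi - lo)
        else:
            np.clip(agent.position, lo, hi, out=agent.position)


def mechanical_relaxation_op(params: MechanicsParams):
    """Standalone engine operation resolving overlaps once per due iteration."""

    def _op(sim: Simulation) -> None:
        if not sim.population or sim.environment is None:
            return
        agents = list(sim.population.values())
        disp = compute_displacements(agents, sim.environment, params,
                                     sim.params.time_step,
                                     sim.params.boundary_mode,
                                     sim.params.lengths)
        apply_displacements(agents, disp, sim.params.bounds,
                            sim.params.boundary_mode)

    return _op


def total_overlap_sq(agents, mode: str = OPEN, lengths=None) -> float:
    """Sum of squared pairwise overlaps (a Lyapunov-style diagnostic)."""
    agents = list(agents)
    total = 0.0
    for i, a in enumerate(agents):
        for b in agents[i + 1:]:
            delta = np.asarray(a.position) - np.asarray(b.position)
            if mode == TOROIDAL and lengths is not None:
                delta = _toroidal_delta(delta, np.asarray(lengths, float))
            overlap = 0.5 * (a.diameter + b.diameter) - np.linalg.norm(delta)
            if overlap > 0:
                total += overlap**2
    return float(total)
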