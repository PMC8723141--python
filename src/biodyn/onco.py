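"""Tumor spheroid growth scenario.

Cancer cells are soft spheres with four behaviors: volume growth at a
constant rate, division once a threshold diameter is reached, Brownian
migration, and stochastic apoptosis.  At division the mother's volume V
is split exactly between mother and daughter, ``u V`` to the daughter and
``(1 - u) V`` to the mother with ``u ~ Uniform(0.45, 0.55)``; the
daughter is placed one mother-radius away in a uniform random direction
and the overlap is resolved by the mechanical relaxation operation.
Migration adds an independent Gaussian increment of variance
``sigma^2 dt`` per coordinate per step.

The readout mirrors wet-lab spheroid assays: the spheroid "diameter" is
the equivalent-sphere diameter of the convex hull enclosing all cells,
``d = (6 V_hull / pi)^(1/3)``, sampled on a fixed cadence (daily by
default, with time in hours).

Default rate parameters are qualitative-regime choices for an
MCF-7-like spheroid, not measured constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .engine import Agent, Behavior, Operation, Simulation, SimulationParams, transfer_behaviors
from .mechanics import MechanicsParams, mechanical_relaxation_op


@dataclass
class TumorCellParams:
    volume_growth_rate: float = 30.0       # um^3 / h
    division_diameter: float = 14.0        # um
    division_volume_ratio_range: tuple[float, float] = (0.45, 0.55)
    migration_sigma: float = 0.5           # um / sqrt(h)
    p_apoptosis: float = 0.0               # per step
    initial_diameter: float = 10.0         # um

    def __post_init__(self) -> None:
        lo, hi = self.division_volume_ratio_range
        if not (0 < lo <= hi < 1) or abs((lo + hi) / 2 - 0.5) > 1e-9:
            raise ValueError("division volume ratio range must lie in (0,1) "
                             "and be symmetric about 0.5")
        if self.division_diameter <= self.initial_diameter:
            raise ValueError("division_diameter must exceed initial_diameter")
        if not 0 <= self.p_apoptosis <= 1:
            raise ValueError("p_apoptosis must be in [0, 1]")


def sphere_volume(diameter: float) -> float:
    return math.pi / 6.0 * diameter**3


def sphere_diameter(volume: float) -> float:
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


class TumorCell(Agent):
    """Spherical cell; ``diameter`` tracks ``volume`` exactly."""

    __slots__ = ("volume",)

    def __init__(self, position, diameter: float, behaviors=(), agent_id=None):
        super().__init__(position, diameter, behaviors, agent_id)
        self.volume = sphere_volume(diameter)

    def set_volume(self, volume: float) -> None:
        self.volume = float(volume)
        self.diameter = sphere_diameter(volume)


# ---------------------------------------------------------------------------
# behaviors
# ---------------------------------------------------------------------------

def growth_and_division(cell: TumorCell, sim: Simulation, params: TumorCellParams) -> None:
    """Linear volume growth; threshold-triggered volume-conserving division."""
    cell.set_volume(cell.volume + params.volume_growth_rate * sim.params.time_step)
    if cell.diameter < params.division_diameter:
        return
    lo, hi = params.division_volume_ratio_range
    u = sim.rng.uniform(lo, hi)
    mother_volume = cell.volume
    daughter_volume = u * mother_volume
    direction = sim.rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    mother_behaviors, daughter_behaviors = transfer_behaviors(cell.behaviors)
    daughter = TumorCell(cell.position + direction * cell.diameter / 2.0,
                         sphere_diameter(daughter_volume))
    daughter.set_volume(daughter_volume)
    daughter.behaviors = daughter_behaviors
    cell.behaviors = mother_behaviors
    cell.set_volume(mother_volume - daughter_volume)
    sim.queue_new_agent(daughter)


def brownian_increments(rng: np.random.Generator, n: int, sigma: float, dt: float) -> np.ndarray:
    """(n, 3) Gaussian steps with per-coordinate variance sigma^2 * dt."""
    return rng.normal(0.0, sigma * math.sqrt(dt), size=(n, 3))


def brownian_migration(cell: TumorCell, sim: Simulation, params: TumorCellParams) -> None:
    if params.migration_sigma == 0:
        return
    cell.position = cell.position + brownian_increments(
        sim.rng, 1, params.migration_sigma, sim.params.time_step)[0]


def apoptosis(cell: TumorCell, sim: Simulation, params: TumorCellParams) -> None:
    """Queue removal with probability p_apoptosis (effective next commit)."""
    if params.p_apoptosis > 0 and sim.rng.random() < params.p_apoptosis:
        sim.queue_removal(cell.id)


def tumor_cell_behaviors(params: TumorCellParams) -> list[Behavior]:
    """Standard behavior set; growth/division and migration are inherited
    by daughters, apoptosis as well."""
    return [
        Behavior("growth_division", lambda a, s: growth_and_division(a, s, params),
                 copy_on_division=True),
        Behavior("migration", lambda a, s: brownian_migration(a, s, params),
                 copy_on_division=True),
        Behavior("apoptosis", lambda a, s: apoptosis(a, s, params),
                 copy_on_division=True),
    ]


# ---------------------------------------------------------------------------
# readouts
# ---------------------------------------------------------------------------

def convex_hull_diameter(positions) -> float:
    """Equivalent-sphere diameter of the convex hull of the cell centers.

    ``d = (6 V / pi)^(1/3)`` where V is the hull volume; requires at least
    4 points in general position.
    """
    pts = np.asarray(positions, float)
    if pts.ndim != 2 or pts.shape[0] < 4 or pts.shape[1] != 3:
        raise ValueError("convex hull diameter needs >= 4 three-dimensional points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError(f"degenerate point set (coplanar or collinear): {exc}") from exc
    return sphere_diameter(hull.volume)


def seed_spheroid(n_cells: int, params: TumorCellParams, rng: np.random.Generator,
                  center=(0.0, 0.0, 0.0), packing_fraction: float = 0.3) -> list[TumorCell]:
    """Place cells uniformly in a ball sized for the target packing fraction."""
    total_cell_volume = n_cells * sphere_volume(params.initial_diameter)
    ball_radius = (3.0 * total_cell_volume / (4.0 * math.pi * packing_fraction)) ** (1.0 / 3.0)
    cells = []
    center = np.asarray(center, float)
    for _ in range(n_cells):
        while True:
            p = rng.uniform(-ball_radius, ball_radius, 3)
            if np.dot(p, p) <= ball_radius**2:
                break
        cells.append(TumorCell(center + p, params.initial_diameter))
    return cells


def build_spheroid_simulation(n_cells: int, params: TumorCellParams | None = None,
                              mech: MechanicsParams | None = None,
                              seed: int = 0, time_step: float = 1.0,
                              box_half_side: float = 400.0) -> Simulation:
    """Assemble the spheroid scenario (time unit: hours)."""
    params = params or TumorCellParams()
    mech = mech or MechanicsParams(repulsion_stiffness=2.0, viscosity=2.0,
                                   max_displacement_per_step=3.0)
    b = box_half_side
    sim = Simulation(SimulationParams(
        time_step=time_step, bounds=((-b, -b, -b), (b, b, b)),
        boundary_mode="open", rng_seed=seed))
    for cell in seed_spheroid(n_cells, params, sim.rng, center=(0, 0, 0)):
        cell.behaviors = tumor_cell_behaviors(params)
        sim.add_agent(cell)
    sim.add_operation(Operation("mechanics", "standalone",
                                mechanical_relaxation_op(mech)))
    return sim


def spheroid_growth_curve(sim: Simulation, n_steps: int,
                          cadence_hours: float = 24.0):
    """Run and sample (t_hours, n_cells, diameter_um) at a fixed cadence."""
    import pandas as pd

    cadence_steps = max(int(round(cadence_hours / sim.params.time_step)), 1)
    rows = []

    def sample() -> None:
        positions = [c.position for c in sim.population.values()]
        diameter = convex_hull_diameter(positions) if len(positions) >= 4 else float("nan")
        rows.append({"t": sim.time, "n_cells": len(positions), "diameter_um": diameter})

    sample()
    for k in range(n_steps):
        sim.step_once()
        if (k + 1) % cadence_steps == 0:
            sample()
    return pd.DataFrame(rows)
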