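"""Spatial SIR epidemic model and its mean-field ODE comparator.

Agents ("persons") carry one of three states — susceptible, infected,
recovered — and move randomly in a toroidal box.  Per time step:

1. every person takes a random step: uniform direction, length uniform on
   ``[0, max_step]``, wrapped periodically;
2. every susceptible with at least one infected person within the
   infection radius becomes infected with probability ``p_infection``
   (one Bernoulli draw per susceptible per step, regardless of how many
   infected neighbors there are);
3. every person already infected at the start of the step recovers with
   probability ``p_recovery``.

State updates within a step are synchronous: infectiousness is evaluated
on the set of people infected at the start of the step.

The comparator is the Kermack–McKendrick ODE system

    dS/dt = -beta S I / N,   dI/dt = beta S I / N - gamma I,
    dR/dt = gamma I,

with ``beta = R0 * gamma`` and ``gamma = 1 / T_R`` (recovery duration).
The ABM maps one iteration to one day and sets
``p_recovery = gamma * dt``; the remaining free parameters (infection
radius, infection probability, maximum step length) are calibrated
against the ODE trajectories with particle swarm optimization.

Two execution paths produce the same model: a per-agent path built on the
generic engine (used for the lifecycle/visibility contracts and small
scenarios) and a vectorized path over numpy arrays with a periodic
kd-tree for the infection queries (used for calibration and multi-seed
validation).  They share the per-step semantics above and are
cross-checked statistically in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .engine import TOROIDAL, Agent, Operation, Simulation, SimulationParams
from .pso import PsoResult, calibrate_pso

SUSCEPTIBLE, INFECTED, RECOVERED = 0, 1, 2
_STATE_NAMES = {SUSCEPTIBLE: "susceptible", INFECTED: "infected", RECOVERED: "recovered"}


# ---------------------------------------------------------------------------
# parameters and trajectories
# ---------------------------------------------------------------------------

@dataclass
class SirOdeParams:
    """Mean-field SIR rates; ``beta = R0/T_R``, ``gamma = 1/T_R``."""

    beta: float
    gamma: float
    n_total: float
    i0: float

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.gamma <= 0:
            raise ValueError("beta and gamma must be > 0")

    @classmethod
    def from_r0(cls, r0: float, recovery_days: float, n_total: float, i0: float) -> "SirOdeParams":
        gamma = 1.0 / recovery_days
        return cls(beta=r0 * gamma, gamma=gamma, n_total=n_total, i0=i0)

    @property
    def r0(self) -> float:
        return self.beta / self.gamma

    @property
    def recovery_days(self) -> float:
        return 1.0 / self.gamma


@dataclass
class SirAbmParams:
    """Agent-based SIR scenario parameters (toroidal box of side ``box_side``)."""

    n_total: int = 2010
    n_infected_initial: int = 10
    infection_radius: float = 8.0
    p_infection: float = 0.5
    p_recovery: float = 0.125
    max_step: float = 25.0
    box_side: float = 100.0
    dt: float = 1.0  # days per iteration

    def __post_init__(self) -> None:
        for name in ("p_infection", "p_recovery"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_infected_initial > self.n_total:
            raise ValueError("n_infected_initial cannot exceed n_total")


@dataclass
class SirTrajectory:
    """Time series of compartment counts; S+I+R = N at every time point."""

    t: np.ndarray
    S: np.ndarray
    I: np.ndarray
    R: np.ndarray

    @property
    def n_total(self) -> float:
        return float(self.S[0] + self.I[0] + self.R[0])

    @property
    def attack_fraction(self) -> float:
        """Fraction of the initially susceptible pool ever infected."""
        return float((self.S[0] - self.S[-1]) / self.n_total)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, "S": self.S, "I": self.I, "R": self.R})


def count_states(population) -> tuple[int, int, int]:
    """(S, I, R) counts over an iterable of person agents."""
    s = i = r = 0
    for person in population:
        if person.state == SUSCEPTIBLE:
            s += 1
        elif person.state == INFECTED:
            i += 1
        else:
            r += 1
    return s, i, r


# ---------------------------------------------------------------------------
# ODE comparator and final-size analytics
# ---------------------------------------------------------------------------

def sir_ode_solve(params: SirOdeParams, horizon: float, dt: float = 0.05) -> SirTrajectory:
    """Classic fixed-step RK4 integration of the SIR system."""
    n_steps = int(round(horizon / dt))
    beta, gamma, N = params.beta, params.gamma, params.n_total

    def f(y: np.ndarray) -> np.ndarray:
        S, I, _ = y
        inc = beta * S * I / N
        return np.array([-inc, inc - gamma * I, gamma * I])

    y = np.array([N - params.i0, params.i0, 0.0])
    out = np.empty((n_steps + 1, 3))
    out[0] = y
    for k in range(n_steps):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise FloatingPointError("SIR ODE state became non-finite")
        out[k + 1] = y
    t = np.arange(n_steps + 1) * dt
    return SirTrajectory(t, out[:, 0], out[:, 1], out[:, 2])


def analytic_final_size(r0: float, tol: float = 1e-12) -> float:
    """Attack fraction z solving z = 1 - exp(-R0 z), by bisection.

    For ``r0 <= 1`` the only root is 0 (no major outbreak).
    """
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    if r0 <= 1.0:
        return 0.0

    def g(z: float) -> float:
        return 1.0 - np.exp(-r0 * z) - z

    lo, hi = tol, 1.0
    # g(lo) > 0 for r0 > 1 (slope at 0 is r0 - 1 > 0); g(1) < 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# engine-integrated path
# ---------------------------------------------------------------------------

class Person(Agent):
    """Point-like agent with an SIR state."""

    __slots__ = ("state", "infected_at")

    def __init__(self, position, state: int = SUSCEPTIBLE, agent_id: int | None = None):
        # persons are treated as points; nominal diameter keeps the grid sane
        super().__init__(position, diameter=1.0, agent_id=agent_id)
        self.state = state
        self.infected_at = -1


def movement_behavior(person: Person, sim: Simulation, params: SirAbmParams) -> None:
    """Random walk: uniform direction, step length uniform on [0, max_step]."""
    if params.max_step <= 0:
        return
    direction = sim.rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    step = sim.rng.uniform(0.0, params.max_step)
    lo, lengths = sim.params.lo, sim.params.lengths
    person.position = lo + np.mod(person.position + direction * step - lo, lengths)


def _refresh_infection_cache(sim: Simulation, params: SirAbmParams) -> None:
    """Rebuild the spatial index on post-movement positions, once per step,
    and snapshot who is infectious at the start of the infection sweep.

    The grid is sized by the infection radius (persons are points, so the
    auto box size would be too small for the epidemiological contact
    radius)."""
    cache = getattr(sim, "_sir_cache", None)
    if cache is None or cache["iteration"] != sim.iteration:
        from . import environment as _env

        sim.environment = _env.build_grid(
            sim.population.values(), box_length=params.infection_radius,
            bounds=sim.params.bounds, mode=sim.params.boundary_mode)
        infectious = {p.id for p in sim.population.values() if p.state == INFECTED}
        sim._sir_cache = {"iteration": sim.iteration, "infectious": infectious}


def infection_behavior(person: Person, sim: Simulation, params: SirAbmParams) -> None:
    """One Bernoulli draw if any start-of-step infected is within radius."""
    if person.state != SUSCEPTIBLE:
        return
    _refresh_infection_cache(sim, params)
    infectious = sim._sir_cache["infectious"]
    if not infectious:
        return
    neighbor_ids = sim.environment.neighbors_within(person, params.infection_radius)
    if any(nid in infectious for nid in neighbor_ids):
        if sim.rng.random() < params.p_infection:
            person.state = INFECTED
            person.infected_at = sim.iteration


def recovery_behavior(person: Person, sim: Simulation, params: SirAbmParams) -> None:
    """Infected at the start of the step recover with p_recovery."""
    if person.state != INFECTED or person.infected_at == sim.iteration:
        return
    if params.p_recovery <= 0:
        return
    if sim.rng.random() < params.p_recovery:
        person.state = RECOVERED


def build_sir_simulation(params: SirAbmParams, seed: int = 0,
                         n_iterations: int = 0) -> Simulation:
    """Assemble the engine-integrated spatial SIR scenario."""
    L = params.box_side
    sim = Simulation(SimulationParams(
        time_step=params.dt, n_iterations=n_iterations,
        bounds=((0.0, 0.0, 0.0), (L, L, L)),
        boundary_mode=TOROIDAL, rng_seed=seed))
    for i in range(params.n_total):
        person = Person(sim.rng.uniform(0.0, L, 3))
        if i < params.n_infected_initial:
            person.state = INFECTED
        sim.add_agent(person)
    sim.add_operation(Operation(
        "movement", "per-agent", lambda a, s: movement_behavior(a, s, params)))
    sim.add_operation(Operation(
        "infection", "per-agent", lambda a, s: infection_behavior(a, s, params)))
    sim.add_operation(Operation(
        "recovery", "per-agent", lambda a, s: recovery_behavior(a, s, params)))
    return sim


def run_sir_engine(params: SirAbmParams, n_steps: int, seed: int = 0) -> SirTrajectory:
    """Run the engine-integrated path and collect (t, S, I, R)."""
    sim = build_sir_simulation(params, seed=seed)
    counts = [count_states(sim.population.values())]
    for _ in range(n_steps):
        sim.step_once()
        counts.append(count_states(sim.population.values()))
    arr = np.array(counts, float)
    t = np.arange(n_steps + 1) * params.dt
    return SirTrajectory(t, arr[:, 0], arr[:, 1], arr[:, 2])


# ---------------------------------------------------------------------------
# vectorized path
# ---------------------------------------------------------------------------

def run_sir_abm(params: SirAbmParams, n_steps: int, seed: int = 0) -> SirTrajectory:
    """Vectorized spatial SIR run (periodic kd-tree infection queries)."""
    rng = np.random.default_rng(seed)
    N, L = params.n_total, params.box_side
    pos = rng.uniform(0.0, L, (N, 3))
    state = np.full(N, SUSCEPTIBLE, np.int8)
    state[: params.n_infected_initial] = INFECTED

    counts = np.empty((n_steps + 1, 3), np.int64)
    for k in range(n_steps + 1):
        counts[k] = [(state == SUSCEPTIBLE).sum(), (state == INFECTED).sum(),
                     (state == RECOVERED).sum()]
        if k == n_steps:
            break
        if params.max_step > 0:
            direction = rng.normal(size=(N, 3))
            direction /= np.linalg.norm(direction, axis=1)[:, None]
            step = rng.uniform(0.0, params.max_step, N)
            pos = np.mod(pos + direction * step[:, None], L)
        sus = np.flatnonzero(state == SUSCEPTIBLE)
        inf = np.flatnonzero(state == INFECTED)
        new_infected = np.empty(0, np.int64)
        if len(sus) and len(inf):
            tree = cKDTree(pos[inf], boxsize=L)
            dist, _ = tree.query(pos[sus], k=1,
                                 distance_upper_bound=params.infection_radius)
            exposed = sus[np.isfinite(dist)]
            if len(exposed):
                draws = rng.random(len(exposed))
                new_infected = exposed[draws < params.p_infection]
        recovering = inf[rng.random(len(inf)) < params.p_recovery] if len(inf) else inf
        state[new_infected] = INFECTED
        state[recovering] = RECOVERED
    t = np.arange(n_steps + 1) * params.dt
    return SirTrajectory(t, counts[:, 0].astype(float), counts[:, 1].astype(float),
                         counts[:, 2].astype(float))


def mean_trajectory(params: SirAbmParams, n_steps: int, seeds: Sequence[int]) -> SirTrajectory:
    """Mean compartment counts over independent seeds."""
    runs = [run_sir_abm(params, n_steps, s) for s in seeds]
    S = np.mean([r.S for r in runs], axis=0)
    I = np.mean([r.I for r in runs], axis=0)
    R = np.mean([r.R for r in runs], axis=0)
    return SirTrajectory(runs[0].t, S, I, R)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def abm_vs_ode_objective(ode: SirOdeParams, template: SirAbmParams,
                         n_steps: int, seeds: Sequence[int]):
    """Normalized squared-error objective over (radius, p_infection, max_step).

    The score is the time-summed squared difference between the ABM mean
    S, I, R curves and the RK4 ODE solution, divided by N^2.
    """
    reference = sir_ode_solve(ode, horizon=n_steps * template.dt, dt=0.05)
    t_abm = np.arange(n_steps + 1) * template.dt
    ref = np.stack([np.interp(t_abm, reference.t, curve)
                    for curve in (reference.S, reference.I, reference.R)])
    N = template.n_total

    def objective(theta: np.ndarray) -> float:
        radius, p_inf, max_step = theta
        params = replace(template, infection_radius=float(radius),
                         p_infection=float(min(max(p_inf, 0.0), 1.0)),
                         max_step=float(max_step))
        total = 0.0
        for s in seeds:
            run = run_sir_abm(params, n_steps, s)
            sim_curves = np.stack([run.S, run.I, run.R])
            total += float(np.sum(((sim_curves - ref) / N) ** 2))
        return total / len(seeds)

    return objective


def calibrate_sir_abm(ode: SirOdeParams, template: SirAbmParams, n_steps: int,
                      swarm_size: int = 30, n_iterations: int = 100,
                      seed: int = 0, n_seeds_per_eval: int = 2,
                      bounds: Sequence[tuple[float, float]] | None = None
                      ) -> tuple[SirAbmParams, PsoResult]:
    """Fit (infection_radius, p_infection, max_step) to the ODE curves."""
    if bounds is None:
        L = template.box_side
        bounds = [(1.0, 0.2 * L), (0.01, 1.0), (1.0, 0.4 * L)]
    eval_seeds = [seed * 1000 + j for j in range(n_seeds_per_eval)]
    objective = abm_vs_ode_objective(ode, template, n_steps, eval_seeds)
    result = calibrate_pso(objective, bounds, swarm_size=swarm_size,
                           n_iterations=n_iterations, seed=seed)
    radius, p_inf, max_step = result.best_position
    fitted = replace(template, infection_radius=float(radius),
                     p_infection=float(p_inf), max_step=float(max_step))
    return fitted, result


# ---------------------------------------------------------------------------
# disease presets
# ---------------------------------------------------------------------------

#: literature-derived disease characteristics: basic reproduction number
#: and recovery duration in days
DISEASES = {
    "measles": {"r0": 12.9, "recovery_days": 8.0, "n_total": 2010,
                "n_infected_initial": 10, "horizon_days": 100},
    "influenza": {"r0": 1.3, "recovery_days": 4.1, "n_total": 2020,
                  "n_infected_initial": 20, "horizon_days": 1000},
}


def disease_ode_params(disease: str) -> SirOdeParams:
    d = DISEASES[disease]
    return SirOdeParams.from_r0(d["r0"], d["recovery_days"], d["n_total"],
                                d["n_infected_initial"])


def disease_abm_template(disease: str, box_side: float = 100.0, dt: float = 1.0) -> SirAbmParams:
    """ABM scenario skeleton for a preset disease.

    ``p_recovery = gamma * dt``; the spatial parameters start from a
    dilute-limit estimate (``p_infection * N * v_r / L^3 = beta * dt``
    with ``v_r`` the infection-sphere volume) and are meant to be refined
    by calibration.  The default step length of 0.8 L re-mixes the
    population almost completely every day, which is the well-mixed
    regime the mean-field comparator assumes; smaller steps introduce
    spatial correlations that depress the effective reproduction number.
    """
    d = DISEASES[disease]
    gamma = 1.0 / d["recovery_days"]
    beta_dt = d["r0"] * gamma * dt
    radius = 5.0
    sphere = 4.0 / 3.0 * np.pi * radius**3
    p_inf = min(beta_dt * box_side**3 / (sphere * d["n_total"]), 1.0)
    return SirAbmParams(
        n_total=d["n_total"], n_infected_initial=d["n_infected_initial"],
        infection_radius=radius, p_infection=p_inf, p_recovery=gamma * dt,
        max_step=0.8 * box_side, box_side=box_side, dt=dt)
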