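"""Pyramidal-cell dendritic growth.

A pyramidal cell starts as a 10 um soma with four 0.5 um dendritic
stubs: one apical dendrite pointing along +z and three basal dendrites
with random directions in the -z hemisphere.  Dendrites are chains of
cylindrical *neurite elements* forming a rooted tree anchored at the
soma (each daughter's proximal point coincides with its parent's distal
point; dendrites attach at the soma center).

Each terminal element with active growth elongates every step.  The
growth direction is a normalized weighted sum of three unit vectors:

* the local gradient of a chemical guidance cue (a static Gaussian
  concentration profile along z),
* the element's previous direction (persistence),
* a uniform random direction (exploration),

with weights that differ between apical and basal dendrites — stronger
gradient following makes the apical dendrite long and straight, stronger
randomness disperses the basal arbor.  The diameter tapers by a fixed
amount per unit length grown; when it reaches the minimum diameter the
element stops growing permanently.  Terminals also bifurcate with a
small per-step probability, producing two daughters with reduced
diameter whose directions straddle the parent direction symmetrically in
a random plane.

Growing tips are discretized into stored segments of at most
``segment_length`` (1 um by default): when a tip fills its segment, a
continuation element is queued and growth transfers to it, so each step
adds exactly ``elongation_speed * dt`` of dendrite regardless of how the
path is chopped into segments.

Morphometrics (branch points per dendritic tree, total tree length) and
plain-text SWC input/output round out the module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .engine import Agent, Behavior, Simulation, SimulationParams, transfer_behaviors
from .fields import GaussianField

logger = logging.getLogger(__name__)

APICAL = "apical"
BASAL = "basal"
SWC_SOMA, SWC_BASAL, SWC_APICAL = 1, 3, 4
_KIND_TO_SWC = {BASAL: SWC_BASAL, APICAL: SWC_APICAL}
_SWC_TO_KIND = {SWC_BASAL: BASAL, SWC_APICAL: APICAL}


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class GrowthParams:
    """Per-dendrite-kind growth rule parameters."""

    elongation_speed: float = 1.0      # um per unit time
    w_gradient: float = 0.5
    w_previous: float = 0.5
    w_random: float = 0.3
    taper: float = 0.01                # diameter loss per um grown
    min_diameter: float = 0.5          # um; growth halts here
    p_branch: float = 0.006            # per step
    branch_diameter_ratio: float = 0.85
    branch_angle_deg: float = 30.0
    initial_diameter: float = 2.0      # um
    substance: str = "guidance_cue"

    def __post_init__(self) -> None:
        if self.w_gradient < 0 or self.w_previous < 0 or self.w_random < 0:
            raise ValueError("direction weights must be >= 0")
        if self.w_gradient + self.w_previous + self.w_random == 0:
            raise ValueError("at least one direction weight must be positive")
        if self.min_diameter <= 0:
            raise ValueError("min_diameter must be > 0")
        if not 0 < self.branch_diameter_ratio <= 1:
            raise ValueError("branch_diameter_ratio must be in (0, 1]")


@dataclass
class NeuriteGrowthParams:
    apical: GrowthParams = field(default_factory=lambda: GrowthParams(
        elongation_speed=1.0, w_gradient=0.9, w_previous=0.6, w_random=0.15,
        taper=0.006, min_diameter=0.5, p_branch=0.04,
        branch_diameter_ratio=0.8, initial_diameter=2.0,
        substance="apical_cue"))
    basal: GrowthParams = field(default_factory=lambda: GrowthParams(
        elongation_speed=0.6, w_gradient=0.3, w_previous=0.5, w_random=0.6,
        taper=0.010, min_diameter=0.4, p_branch=0.05,
        branch_diameter_ratio=0.8, initial_diameter=1.5,
        substance="basal_cue"))
    segment_length: float = 1.0  # um; stored-segment discretization

    def for_kind(self, kind: str) -> GrowthParams:
        return self.apical if kind == APICAL else self.basal


@dataclass
class PyramidalCellInit:
    soma_diameter: float = 10.0          # um
    initial_dendrite_length: float = 0.5  # um
    n_basal: int = 3
    n_apical: int = 1
    apical_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# agents
# ---------------------------------------------------------------------------

class Soma(Agent):
    __slots__ = ("daughter_ids",)

    def __init__(self, position, diameter: float, agent_id=None):
        super().__init__(position, diameter, agent_id=agent_id)
        self.daughter_ids: list[int] = []


class NeuriteElement(Agent):
    """Cylindrical dendrite segment in a soma-rooted tree."""

    __slots__ = ("kind", "proximal", "distal", "parent_id", "daughter_ids",
                 "is_terminal", "growth_active")

    def __init__(self, kind: str, proximal, distal, diameter: float,
                 parent_id: int, agent_id=None):
        proximal = np.asarray(proximal, float).copy()
        distal = np.asarray(distal, float).copy()
        super().__init__(0.5 * (proximal + distal), diameter, agent_id=agent_id)
        self.kind = kind
        self.proximal = proximal
        self.distal = distal
        self.parent_id = parent_id
        self.daughter_ids: list[int] = []
        self.is_terminal = True
        self.growth_active = True

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.distal - self.proximal))

    @property
    def direction(self) -> np.ndarray:
        d = self.distal - self.proximal
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([0.0, 0.0, 1.0])

    def _sync_center(self) -> None:
        self.position = 0.5 * (self.proximal + self.distal)


# ---------------------------------------------------------------------------
# growth rules
# ---------------------------------------------------------------------------

def growth_direction(tip: NeuriteElement, guidance_field, params: GrowthParams,
                     rng: np.random.Generator) -> np.ndarray:
    """Normalized weighted sum of gradient, persistence and random terms."""
    g = np.zeros(3)
    if guidance_field is not None and params.w_gradient > 0:
        g = np.asarray(guidance_field.gradient(tip.distal), float)
        norm = np.linalg.norm(g)
        g = g / norm if norm > 0 else np.zeros(3)
    p = tip.direction
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    v = params.w_gradient * g + params.w_previous * p + params.w_random * u
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        logger.warning("degenerate growth direction on element %s; keeping "
                       "previous direction", tip.id)
        return p
    return v / norm


def elongate_and_taper(tip: NeuriteElement, direction: np.ndarray,
                       params: GrowthParams, dt: float) -> None:
    """Advance the distal point; shrink the diameter; halt at the floor."""
    if not tip.growth_active:
        return
    advance = params.elongation_speed * dt
    tip.distal = tip.distal + np.asarray(direction, float) * advance
    tip._sync_center()
    tip.diameter = max(tip.diameter - params.taper * advance, params.min_diameter)
    if tip.diameter <= params.min_diameter:
        tip.growth_active = False
        tip.behaviors = [b for b in tip.behaviors if b.name != "neurite_growth"]


def _perpendicular_unit(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        u = rng.normal(size=3)
        u -= np.dot(u, direction) * direction
        n = np.linalg.norm(u)
        if n > 1e-8:
            return u / n


def branch(tip: NeuriteElement, sim: Simulation, params: GrowthParams,
           dt: float) -> tuple[NeuriteElement, NeuriteElement]:
    """Bifurcate: two reduced-diameter daughters straddle the tip direction."""
    p = tip.direction
    n = _perpendicular_unit(p, sim.rng)
    half = math.radians(params.branch_angle_deg) / 2.0
    directions = (math.cos(half) * p + math.sin(half) * n,
                  math.cos(half) * p - math.sin(half) * n)
    _, daughter_behaviors = transfer_behaviors(tip.behaviors)
    tip.behaviors = [b for b in tip.behaviors if b.name != "neurite_growth"]
    diameter = max(params.branch_diameter_ratio * tip.diameter, params.min_diameter)
    advance = params.elongation_speed * dt
    daughters = []
    for d in directions:
        el = NeuriteElement(tip.kind, tip.distal, tip.distal + d * advance,
                            diameter, tip.parent_id)
        el.parent_id = tip.id
        el.behaviors = [b for b in daughter_behaviors]
        if diameter <= params.min_diameter:
            el.growth_active = False
            el.behaviors = [b for b in el.behaviors if b.name != "neurite_growth"]
        sim.queue_new_agent(el)
        tip.daughter_ids.append(el.id)
        daughters.append(el)
    tip.is_terminal = False
    tip.growth_active = False
    return daughters[0], daughters[1]


def _continue_segment(tip: NeuriteElement, direction: np.ndarray,
                      sim: Simulation, params: GrowthParams, dt: float) -> NeuriteElement:
    """Freeze a full segment and queue its continuation element."""
    _, daughter_behaviors = transfer_behaviors(tip.behaviors)
    tip.behaviors = [b for b in tip.behaviors if b.name != "neurite_growth"]
    advance = params.elongation_speed * dt
    diameter = max(tip.diameter - params.taper * advance, params.min_diameter)
    el = NeuriteElement(tip.kind, tip.distal, tip.distal + direction * advance,
                        diameter, tip.id)
    el.behaviors = [b for b in daughter_behaviors]
    if diameter <= params.min_diameter:
        el.growth_active = False
        el.behaviors = [b for b in el.behaviors if b.name != "neurite_growth"]
    sim.queue_new_agent(el)
    tip.daughter_ids.append(el.id)
    tip.is_terminal = False
    tip.growth_active = False
    return el


def neurite_growth_behavior(growth: NeuriteGrowthParams) -> Behavior:
    """Behavior driving elongation, tapering and branching of terminals.

    Copied to daughters and removed from the mother whenever growth
    transfers to a new element (branching or segment continuation).
    """

    def run(tip: NeuriteElement, sim: Simulation) -> None:
        if not (tip.is_terminal and tip.growth_active):
            return
        params = growth.for_kind(tip.kind)
        dt = sim.params.time_step
        if params.p_branch > 0 and sim.rng.random() < params.p_branch:
            branch(tip, sim, params, dt)
            return
        guidance = sim.substances.get(params.substance)
        direction = growth_direction(tip, guidance, params, sim.rng)
        if tip.length + params.elongation_speed * dt > growth.segment_length:
            _continue_segment(tip, direction, sim, params, dt)
        else:
            elongate_and_taper(tip, direction, params, dt)

    return Behavior("neurite_growth", run, copy_on_division=True,
                    remove_from_mother=True)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_pyramidal_cell(sim: Simulation, position,
                        init: PyramidalCellInit | None = None,
                        growth: NeuriteGrowthParams | None = None) -> Soma:
    """Create one soma plus its apical and basal dendritic stubs."""
    init = init or PyramidalCellInit()
    growth = growth or NeuriteGrowthParams()
    position = np.asarray(position, float)
    soma = Soma(position, init.soma_diameter)
    sim.add_agent(soma)

    def make(kind: str, direction: np.ndarray) -> None:
        params = growth.for_kind(kind)
        el = NeuriteElement(kind, position,
                            position + direction * init.initial_dendrite_length,
                            params.initial_diameter, soma.id)
        el.behaviors = [neurite_growth_behavior(growth)]
        sim.add_agent(el)
        soma.daughter_ids.append(el.id)

    apical_dir = np.asarray(init.apical_direction, float)
    apical_dir /= np.linalg.norm(apical_dir)
    for _ in range(init.n_apical):
        make(APICAL, apical_dir)
    for _ in range(init.n_basal):
        while True:  # uniform direction in the -z hemisphere
            d = sim.rng.normal(size=3)
            d /= np.linalg.norm(d)
            if d[2] < 0:
                break
        make(BASAL, d)
    return soma


def default_guidance_fields() -> dict[str, GaussianField]:
    """Two static Gaussian cues along z: one above (apical), one below."""
    return {
        "apical_cue": GaussianField("apical_cue", amplitude=1.0, axis="z",
                                    mean=300.0, sigma=150.0),
        "basal_cue": GaussianField("basal_cue", amplitude=1.0, axis="z",
                                   mean=-80.0, sigma=80.0),
    }


def build_pyramidal_simulation(n_cells: int = 1, seed: int = 0,
                               init: PyramidalCellInit | None = None,
                               growth: NeuriteGrowthParams | None = None,
                               spacing: float = 120.0,
                               time_step: float = 1.0) -> tuple[Simulation, list[Soma]]:
    """Cells on a horizontal grid under shared z-axis guidance cues.

    Neurite-neurite mechanics are off: growth is guidance-only.
    """
    side = max(int(math.ceil(math.sqrt(n_cells))), 1)
    extent = max(side * spacing, 400.0)
    sim = Simulation(SimulationParams(
        time_step=time_step,
        bounds=((-extent, -extent, -400.0), (extent, extent, 400.0)),
        boundary_mode="open", rng_seed=seed))
    sim.substances.update(default_guidance_fields())
    somas = []
    for i in range(n_cells):
        row, col = divmod(i, side)
        pos = (col * spacing - (side - 1) * spacing / 2,
               row * spacing - (side - 1) * spacing / 2, 0.0)
        somas.append(init_pyramidal_cell(sim, pos, init, growth))
    return sim, somas


# ---------------------------------------------------------------------------
# morphology container, morphometrics, SWC
# ---------------------------------------------------------------------------

@dataclass
class NeuriteRecord:
    kind: str
    proximal: np.ndarray
    distal: np.ndarray
    diameter: float
    parent_id: int | None   # None when attached to the soma
    daughter_ids: list[int] = field(default_factory=list)


@dataclass
class CellMorphology:
    soma_position: np.ndarray
    soma_diameter: float
    elements: dict[int, NeuriteRecord] = field(default_factory=dict)

    def roots(self) -> list[int]:
        return sorted(i for i, e in self.elements.items() if e.parent_id is None)


def extract_morphology(sim: Simulation, soma: Soma) -> CellMorphology:
    """Collect one cell's dendritic tree out of a running simulation."""
    morphology = CellMorphology(soma.position.copy(), soma.diameter)
    frontier = list(soma.daughter_ids)
    while frontier:
        eid = frontier.pop()
        el = sim.population[eid]
        morphology.elements[eid] = NeuriteRecord(
            el.kind, el.proximal.copy(), el.distal.copy(), el.diameter,
            None if el.parent_id == soma.id else el.parent_id,
            list(el.daughter_ids))
        frontier.extend(el.daughter_ids)
    return morphology


def _validate_tree(morphology: CellMorphology) -> None:
    elements = morphology.elements
    for eid, el in elements.items():
        for did in el.daughter_ids:
            if did not in elements:
                raise ValueError(f"element {eid} references missing daughter {did}")
        if el.parent_id is not None and el.parent_id not in elements:
            raise ValueError(f"element {eid} has orphan parent reference {el.parent_id}")
    # cycle/connectivity check by walking up from every node
    for eid in elements:
        seen = set()
        node = eid
        while node is not None:
            if node in seen:
                raise ValueError(f"cycle detected through element {eid}")
            seen.add(node)
            node = elements[node].parent_id


def morphometrics(morphology: CellMorphology):
    """Per-dendritic-tree branch-point counts and total lengths.

    A branch point is an element with exactly two daughters.  Returns a
    DataFrame with one row per dendritic tree (root stub) and columns
    ``tree_kind``, ``n_branch_points``, ``total_length_um``.
    """
    import pandas as pd

    _validate_tree(morphology)
    elements = morphology.elements
    rows = []
    for root in morphology.roots():
        n_branch = 0
        total_length = 0.0
        stack = [root]
        while stack:
            eid = stack.pop()
            el = elements[eid]
            total_length += float(np.linalg.norm(el.distal - el.proximal))
            if len(el.daughter_ids) == 2:
                n_branch += 1
            stack.extend(el.daughter_ids)
        rows.append({"tree_kind": elements[root].kind,
                     "n_branch_points": n_branch,
                     "total_length_um": total_length})
    return pd.DataFrame(rows)


def population_morphometrics(morphologies: Iterable[CellMorphology]):
    """Cell-level averages (over each cell's dendritic trees) per cell."""
    import pandas as pd

    rows = []
    for idx, morphology in enumerate(morphologies):
        per_tree = morphometrics(morphology)
        rows.append({"cell_id": idx,
                     "mean_branch_points": per_tree["n_branch_points"].mean(),
                     "mean_tree_length_um": per_tree["total_length_um"].mean()})
    return pd.DataFrame(rows)


def swc_export(morphology: CellMorphology) -> str:
    """Serialize to SWC (index, type, x, y, z, radius, parent)."""
    _validate_tree(morphology)
    lines = ["# SWC export (biodyn)", "# index type x y z radius parent"]

    def fmt(i: int, t: int, p: np.ndarray, radius: float, parent: int) -> str:
        return f"{i} {t} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {radius:.6f} {parent}"

    lines.append(fmt(1, SWC_SOMA, morphology.soma_position,
                     morphology.soma_diameter / 2.0, -1))
    index_of: dict[int, int] = {}
    next_index = 2
    stack = [(eid, 1) for eid in reversed(morphology.roots())]
    while stack:
        eid, parent_index = stack.pop()
        el = morphology.elements[eid]
        index_of[eid] = next_index
        lines.append(fmt(next_index, _KIND_TO_SWC[el.kind], el.distal,
                         el.diameter / 2.0, parent_index))
        for did in reversed(sorted(el.daughter_ids)):
            stack.append((did, next_index))
        next_index += 1
    return "\n".join(lines) + "\n"


def swc_import(text: str) -> CellMorphology:
    """Parse SWC text back into a morphology (soma row required first)."""
    nodes: dict[int, tuple[int, np.ndarray, float, int]] = {}
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"SWC row {line_no}: expected 7 columns, got {len(parts)}")
        idx, swc_type = int(parts[0]), int(parts[1])
        xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
        radius, parent = float(parts[5]), int(parts[6])
        nodes[idx] = (swc_type, xyz, radius, parent)

    soma_rows = [i for i, n in nodes.items() if n[0] == SWC_SOMA]
    if len(soma_rows) != 1:
        raise ValueError(f"expected exactly one soma row, found {len(soma_rows)}")
    soma_idx = soma_rows[0]
    soma_type, soma_xyz, soma_radius, _ = nodes[soma_idx]
    morphology = CellMorphology(soma_xyz, soma_radius * 2.0)
    for idx, (swc_type, xyz, radius, parent) in sorted(nodes.items()):
        if idx == soma_idx:
            continue
        if swc_type not in _SWC_TO_KIND:
            raise ValueError(f"SWC row with index {idx}: unsupported type {swc_type}")
        if parent not in nodes:
            raise ValueError(f"SWC row with index {idx} references missing parent {parent}")
        proximal = nodes[parent][1]
        morphology.elements[idx] = NeuriteRecord(
            _SWC_TO_KIND[swc_type], proximal.copy(), xyz.copy(), radius * 2.0,
            None if parent == soma_idx else parent)
    for idx, el in morphology.elements.items():
        if el.parent_id is not None:
            morphology.elements[el.parent_id].daughter_ids.append(idx)
    for el in morphology.elements.values():
        el.daughter_ids.sort()
    return morphology
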