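"""Fixed-radius neighborhood search over a uniform grid.

The simulation space is divided into equal cubic boxes and each agent is
assigned to the box containing its center of mass.  A neighborhood query
then only needs to scan the agent's own box plus its 26 face/edge/corner
neighbors (27 boxes in total), which is exhaustive as long as the query
radius does not exceed the box edge length.  The box edge defaults to the
largest agent diameter in the population, so every possible mechanical
contact is always covered.

Boxes are half-open ``[lo, hi)`` per axis, so a position exactly on a box
boundary belongs to exactly one box.  Neighbors at a distance exactly
equal to the radius are included.  In ``toroidal`` mode box indices wrap
around and distances use the per-axis minimum image
``min(|d|, L - |d|)``; the grid dimensions are then chosen so that the
boxes tile the periodic domain exactly.

A deliberately naive ``brute_force_neighbors`` (direct O(n^2) pairwise
distances) serves as the correctness oracle for the grid, and a kd-tree
backend (:class:`KDTreeEnvironment`, backed by ``scipy.spatial.cKDTree``)
offers the same query contract behind a different index.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .engine import OPEN, TOROIDAL, Agent


def _toroidal_delta(delta: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    d = np.abs(delta)
    return np.minimum(d, lengths - d)


def pairwise_distance(p: np.ndarray, q: np.ndarray, mode: str = OPEN,
                      lengths: np.ndarray | None = None) -> float:
    """Distance between two points, minimum-image in toroidal mode."""
    delta = np.asarray(p, float) - np.asarray(q, float)
    if mode == TOROIDAL:
        delta = _toroidal_delta(delta, np.asarray(lengths, float))
    return float(np.linalg.norm(delta))


class UniformGridEnvironment:
    """Uniform-grid spatial index over a fixed axis-aligned box."""

    def __init__(self, box_length: float, origin: np.ndarray, dims: np.ndarray,
                 mode: str, domain_lengths: np.ndarray,
                 box_lengths: np.ndarray | None = None):
        self.box_length = float(box_length)
        self.origin = np.asarray(origin, float)
        self.dims = np.asarray(dims, int)
        self.mode = mode
        self.domain_lengths = np.asarray(domain_lengths, float)
        # per-axis effective box edge (toroidal tiling may stretch it)
        self.box_lengths = (np.full(3, self.box_length)
                            if box_lengths is None else np.asarray(box_lengths, float))
        self.box_contents: dict[tuple[int, int, int], list[int]] = {}
        self._positions: dict[int, np.ndarray] = {}
        self.boxes_scanned = 0  # boxes visited by the most recent query

    # -- construction ---------------------------------------------------
    def _box_index(self, position: np.ndarray) -> tuple[int, int, int]:
        rel = (np.asarray(position, float) - self.origin) / self.box_lengths
        idx = np.floor(rel).astype(int)
        if self.mode == TOROIDAL:
            idx = np.mod(idx, self.dims)
        else:
            idx = np.clip(idx, 0, self.dims - 1)
        return tuple(int(i) for i in idx)

    def insert(self, agent_id: int, position: np.ndarray) -> None:
        key = self._box_index(position)
        self.box_contents.setdefault(key, []).append(agent_id)
        self._positions[agent_id] = np.asarray(position, float)

    # -- queries ----------------------------------------------------------
    def neighbors_within(self, query: Agent | int, radius: float,
                         position: np.ndarray | None = None) -> list[int]:
        """Ids of all agents with center-to-center distance <= radius.

        The query agent itself is excluded.  Raises if ``radius`` exceeds
        the box edge, because the 27-box stencil would then be incomplete.
        """
        if isinstance(query, Agent):
            qid, qpos = query.id, query.position
        else:
            qid = query
            qpos = self._positions[qid] if position is None else np.asarray(position, float)
        min_edge = float(np.min(self.box_lengths))
        if radius > min_edge * (1 + 1e-12):
            raise ValueError(
                f"query radius {radius} exceeds box length {min_edge}; "
                "the 27-box stencil requires radius <= box_length")
        center = self._box_index(qpos)
        found: list[int] = []
        scanned = 0
        for offset in itertools.product((-1, 0, 1), repeat=3):
            key = tuple(c + o for c, o in zip(center, offset))
            if self.mode == TOROIDAL:
                key = tuple(int(k) % int(d) for k, d in zip(key, self.dims))
            elif any(k < 0 or k >= d for k, d in zip(key, self.dims)):
                continue
            scanned += 1
            for agent_id in self.box_contents.get(key, ()):
                if agent_id == qid:
                    continue
                d = pairwise_distance(qpos, self._positions[agent_id],
                                      self.mode, self.domain_lengths)
                if d <= radius:
                    found.append(agent_id)
        self.boxes_scanned = scanned
        # toroidal wrap on tiny grids can visit a box twice via two offsets
        seen: set[int] = set()
        unique = [i for i in found if not (i in seen or seen.add(i))]
        return unique

    def occupancy_histogram(self) -> dict[int, int]:
        """Number of boxes per occupancy count (diagnostics)."""
        hist: dict[int, int] = {}
        for ids in self.box_contents.values():
            hist[len(ids)] = hist.get(len(ids), 0) + 1
        return hist


def build_grid(agents: Iterable[Agent], box_length: float | None = None,
               bounds: Sequence = ((0, 0, 0), (100, 100, 100)),
               mode: str = OPEN) -> UniformGridEnvironment:
    """Index a population on a uniform grid.

    If ``box_length`` is omitted it is set to the largest agent diameter,
    which guarantees that a contact-radius query never violates the
    ``radius <= box_length`` completeness constraint.
    """
    agents = list(agents)
    if box_length is None:
        if not agents:
            raise ValueError("auto box size is undefined for an empty population; "
                             "pass box_length explicitly")
        box_length = max(a.diameter for a in agents)
    if box_length <= 0:
        raise ValueError("box_length must be > 0")
    lo = np.asarray(bounds[0], float)
    hi = np.asarray(bounds[1], float)
    lengths = hi - lo
    if mode == TOROIDAL:
        # boxes must tile the periodic domain exactly: per axis use the
        # largest count of equal boxes with edge >= box_length
        dims = np.maximum(np.floor(lengths / box_length).astype(int), 1)
        box_lengths = lengths / dims
    else:
        dims = np.maximum(np.ceil(lengths / box_length - 1e-12).astype(int), 1)
        box_lengths = np.full(3, float(box_length))
    grid = UniformGridEnvironment(box_length, lo, dims, mode, lengths, box_lengths)
    for agent in agents:
        grid.insert(agent.id, agent.position)
    return grid


def brute_force_neighbors(agents: Iterable[Agent], query: Agent, radius: float,
                          mode: str = OPEN,
                          lengths: np.ndarray | Sequence | None = None) -> list[int]:
    """O(n^2)-style direct neighbor search: the oracle for the grid."""
    lengths = None if lengths is None else np.asarray(lengths, float)
    out = []
    for agent in agents:
        if agent.id == query.id:
            continue
        if pairwise_distance(agent.position, query.position, mode, lengths) <= radius:
            out.append(agent.id)
    return out


class KDTreeEnvironment:
    """kd-tree backend with the same fixed-radius query contract.

    Uses a periodic tree in toroidal mode.  There is no radius constraint;
    the grid remains the engine default.
    """

    def __init__(self, agents: Iterable[Agent], bounds: Sequence, mode: str = OPEN):
        agents = list(agents)
        self.ids = np.array([a.id for a in agents], dtype=int)
        lo = np.asarray(bounds[0], float)
        self.lengths = np.asarray(bounds[1], float) - lo
        self.mode = mode
        pos = np.array([a.position for a in agents], float)
        if mode == TOROIDAL:
            pos = np.mod(pos - lo, self.lengths)
            self.tree = cKDTree(pos, boxsize=self.lengths)
        else:
            self.tree = cKDTree(pos)
        self._lo = lo
        self._pos = pos

    def neighbors_within(self, query: Agent, radius: float) -> list[int]:
        q = np.asarray(query.position, float)
        if self.mode == TOROIDAL:
            q = np.mod(q - self._lo, self.lengths)
        idx = self.tree.query_ball_point(q, radius)
        return [int(self.ids[i]) for i in idx if self.ids[i] != query.id]
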