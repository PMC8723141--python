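"""Global-best particle swarm optimization.

Plain PSO with the constriction-derived coefficients of Clerc & Kennedy
(inertia ``w = 0.7298``, cognitive/social weights
``c1 = c2 = 1.49618``).  Each particle keeps a personal best; the swarm
keeps a global best; velocities follow

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)

with positions clamped to the search box.  The run is deterministic for a
given seed.  Non-finite objective values reset the particle uniformly
inside the bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass
class PsoResult:
    best_position: np.ndarray
    best_score: float
    history: list[float] = field(default_factory=list)  # gbest score per iteration
    n_evaluations: int = 0


def calibrate_pso(objective: Callable[[np.ndarray], float],
                  bounds: Sequence[tuple[float, float]],
                  swarm_size: int = 30,
                  n_iterations: int = 100,
                  seed: int = 0,
                  w: float = 0.7298,
                  c1: float = 1.49618,
                  c2: float = 1.49618) -> PsoResult:
    """Minimize ``objective`` over a box; returns the best-ever position."""
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(lo < hi)):
        raise ValueError("bounds must be finite with lo < hi per dimension")
    ndim = len(bounds)
    span = hi - lo

    x = lo + rng.random((swarm_size, ndim)) * span
    v = (rng.random((swarm_size, ndim)) - 0.5) * span * 0.1
    n_evals = 0

    def _eval(xi: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        return float(objective(xi))

    scores = np.array([_eval(xi) for xi in x])
    for i in range(swarm_size):
        if not np.isfinite(scores[i]):
            x[i] = lo + rng.random(ndim) * span
            scores[i] = _eval(x[i])
    pbest = x.copy()
    pbest_scores = scores.copy()
    g = int(np.argmin(pbest_scores))
    gbest = pbest[g].copy()
    gbest_score = float(pbest_scores[g])
    history = [gbest_score]

    for _ in range(n_iterations):
        r1 = rng.random((swarm_size, ndim))
        r2 = rng.random((swarm_size, ndim))
        v = w * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)
        x = np.clip(x + v, lo, hi)
        for i in range(swarm_size):
            s = _eval(x[i])
            if not np.isfinite(s):
                x[i] = lo + rng.random(ndim) * span
                v[i] = 0.0
                s = _eval(x[i])
            if s < pbest_scores[i]:
                pbest[i] = x[i].copy()
                pbest_scores[i] = s
                if s < gbest_score:
                    gbest = x[i].copy()
                    gbest_score = s
        history.append(gbest_score)

    return PsoResult(gbest, gbest_score, history, n_evals)
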