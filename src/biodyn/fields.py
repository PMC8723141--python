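"""Extracellular scalar substances.

Two kinds of substance are supported:

* :class:`GaussianField` — a static guidance cue whose concentration
  follows a Gaussian profile along one axis,
  ``c(p) = A * exp(-(p_axis - mean)^2 / (2 sigma^2))``.  Such cues drive
  chemotactic neurite growth and never change during a simulation, so
  they need no numerical update.
* :class:`DiffusionGrid` — an explicit finite-difference lattice evolving
  under isotropic diffusion with linear decay,
  ``dc/dt = D lap(c) - mu c``, integrated with the forward-time
  centered-space (FTCS) 7-point stencil and zero-flux (closed) boundaries.
  With ``mu = 0`` the scheme conserves total mass exactly (to round-off).

Point queries on the lattice use trilinear interpolation of the eight
surrounding voxel values; gradients are central differences of the
interpolated field with step equal to the voxel spacing.  Queries outside
the lattice are clamped to the boundary value (logged once per grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class GaussianField:
    """Static Gaussian concentration profile along one axis."""

    substance_name: str
    amplitude: float
    axis: str = "z"
    mean: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.axis not in _AXES:
            raise ValueError(f"axis must be one of {sorted(_AXES)}")

    def value(self, point) -> float:
        u = np.asarray(point, float)[_AXES[self.axis]]
        return float(self.amplitude * np.exp(-((u - self.mean) ** 2) / (2 * self.sigma**2)))

    def gradient(self, point) -> np.ndarray:
        u = np.asarray(point, float)[_AXES[self.axis]]
        g = np.zeros(3)
        g[_AXES[self.axis]] = (
            -self.amplitude * (u - self.mean) / self.sigma**2
            * np.exp(-((u - self.mean) ** 2) / (2 * self.sigma**2))
        )
        return g


class DiffusionGrid:
    """Explicit FTCS diffusion lattice with zero-flux boundaries."""

    def __init__(self, substance_name: str, shape, spacing: float,
                 diffusion_coefficient: float, decay_rate: float = 0.0,
                 origin=(0.0, 0.0, 0.0)):
        shape = tuple(int(s) for s in shape)
        if any(s < 3 for s in shape):
            raise ValueError("lattice must have at least 3 voxels per axis")
        if spacing <= 0:
            raise ValueError("spacing must be > 0")
        self.substance_name = substance_name
        self.concentrations = np.zeros(shape, float)
        self.spacing = float(spacing)
        self.diffusion_coefficient = float(diffusion_coefficient)
        self.decay_rate = float(decay_rate)
        self.origin = np.asarray(origin, float)
        self._warned_out_of_bounds = False

    # -- bookkeeping -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.concentrations.shape

    def total_mass(self) -> float:
        """Integral of the concentration field: sum(c) * dx^3."""
        return float(self.concentrations.sum() * self.spacing**3)

    def max_stable_dt(self) -> float:
        """Largest FTCS-stable time step, D*dt/dx^2 <= 1/6."""
        if self.diffusion_coefficient == 0:
            return np.inf
        return self.spacing**2 / (6.0 * self.diffusion_coefficient)

    # -- point access ----------------------------------------------------
    def _fractional_index(self, point) -> np.ndarray:
        # voxel values live at voxel centers: center of voxel i is at
        # origin + (i + 0.5) * dx
        rel = (np.asarray(point, float) - self.origin) / self.spacing - 0.5
        clipped = np.clip(rel, 0.0, np.asarray(self.shape) - 1.0)
        if not self._warned_out_of_bounds and np.any(clipped != rel):
            logger.warning("query outside diffusion grid %r clamped to boundary",
                           self.substance_name)
            self._warned_out_of_bounds = True
        return clipped

    def value(self, point) -> float:
        """Trilinear interpolation of the 8 voxels surrounding ``point``."""
        f = self._fractional_index(point)
        i0 = np.minimum(np.floor(f).astype(int), np.asarray(self.shape) - 2)
        t = f - i0
        c = self.concentrations
        out = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = ((t[0] if dx else 1 - t[0])
                         * (t[1] if dy else 1 - t[1])
                         * (t[2] if dz else 1 - t[2]))
                    out += w * c[i0[0] + dx, i0[1] + dy, i0[2] + dz]
        return float(out)

    def gradient(self, point) -> np.ndarray:
        """Central difference of the interpolated field, step = spacing."""
        p = np.asarray(point, float)
        g = np.zeros(3)
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = self.spacing
            g[axis] = (self.value(p + e) - self.value(p - e)) / (2 * self.spacing)
        return g

    # -- dynamics --------------------------------------------------------
    def step(self, dt: float) -> None:
        """One FTCS update c' = c + dt*(D lap c - mu c), zero-flux walls."""
        D, mu, dx = self.diffusion_coefficient, self.decay_rate, self.spacing
        if D * dt / dx**2 > 1.0 / 6.0 + 1e-15:
            raise ValueError(
                f"FTCS unstable: D*dt/dx^2 = {D * dt / dx**2:.4g} > 1/6; "
                f"use dt <= {self.max_stable_dt():.6g}")
        c = self.concentrations
        # zero-flux: ghost layer mirrors the edge value
        p = np.pad(c, 1, mode="edge")
        lap = (p[2:, 1:-1, 1:-1] + p[:-2, 1:-1, 1:-1]
               + p[1:-1, 2:, 1:-1] + p[1:-1, :-2, 1:-1]
               + p[1:-1, 1:-1, 2:] + p[1:-1, 1:-1, :-2]
               - 6.0 * c) / dx**2
        self.concentrations = c + dt * (D * lap - mu * c)

    def deposit(self, point, amount: float) -> None:
        """Add ``amount`` of substance to the voxel containing ``point``."""
        if amount < 0:
            raise ValueError("deposit amount must be >= 0")
        rel = (np.asarray(point, float) - self.origin) / self.spacing
        idx = np.clip(np.floor(rel).astype(int), 0, np.asarray(self.shape) - 1)
        self.concentrations[tuple(idx)] += amount / self.spacing**3

    # -- export ----------------------------------------------------------
    def to_dataframe(self):
        """Long-format (x, y, z, value) table of the lattice."""
        import pandas as pd

        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        centers = self.origin + (np.stack([ii, jj, kk], axis=-1) + 0.5) * self.spacing
        return pd.DataFrame({
            "x": centers[..., 0].ravel(),
            "y": centers[..., 1].ravel(),
            "z": centers[..., 2].ravel(),
            "value": self.concentrations.ravel(),
        })
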