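"""Random fitness landscapes over a bounded two-dimensional morphospace.

The landscape is a scalar "fitness" field over the morphospace: its value at a
point sets how many offspring (1-4) an organism living there produces.  The
field originates as a coarse 12x12 matrix of random fitness levels which is
expanded to the full morphospace by bilinear interpolation.  Two dynamic
regimes are supported:

``shifting``
    Every ``lambda_shift`` generations the coarse matrix is translated by one
    column (the last column is discarded, a fresh random column enters at the
    front), moving the landscape gradually along the trait-x axis.

``feedback``
    Each generation, every coarse cell loses fitness in proportion to the
    number of organisms occupying it (resource depletion); the total amount
    subtracted is returned in equal shares to all 144 cells, so the grand sum
    of fitness over the landscape is conserved.

``static``
    The field never changes (useful as a control and in tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "VALID_MODES",
    "LandscapeConfig",
    "FitnessGrid",
    "Landscape",
    "init_grid",
    "shift_grid",
    "apply_feedback",
    "offspring_count",
]

VALID_MODES = ("shifting", "feedback", "static")


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the fitness landscape and its dynamics.

    Attributes
    ----------
    mode:
        One of ``shifting``, ``feedback`` or ``static``.
    lambda_shift:
        Generations between columnwise shifts in ``shifting`` mode.
    feedback_coefficient:
        Fitness decrement per organism per coarse cell in ``feedback`` mode.
    fitness_range:
        (min, max) of freshly drawn coarse fitness levels; also the clamp
        range for realized offspring counts.
    extent:
        Side length of the square morphospace, in trait units.
    coarse_size:
        Number of coarse grid nodes per axis.
    """

    mode: str = "shifting"
    lambda_shift: int = 2
    feedback_coefficient: float = 0.0071
    fitness_range: tuple[float, float] = (1.0, 4.0)
    extent: float = 45.0
    coarse_size: int = 12

    def __post_init__(self) -> None:
        if self.mode not in VALID_MODES:
            raise ValueError(f"mode must be one of {VALID_MODES}, got {self.mode!r}")
        if self.lambda_shift < 1:
            raise ValueError("lambda_shift must be >= 1")
        if self.feedback_coefficient < 0:
            raise ValueError("feedback_coefficient must be >= 0")
        lo, hi = self.fitness_range
        if not lo < hi:
            raise ValueError("fitness_range must satisfy min < max")
        if self.extent <= 0:
            raise ValueError("extent must be positive")
        if self.coarse_size < 2:
            raise ValueError("coarse_size must be >= 2")


@dataclass(frozen=True)
class FitnessGrid:
    """Coarse matrix of fitness levels.

    ``values[row, col]`` is the level at node (y=row, x=col); columns map to
    the trait-x axis so a columnwise shift moves the landscape along x.
    """

    values: np.ndarray
    generation_stamp: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("grid values must be a square 2-D matrix")
        object.__setattr__(self, "values", v)

    @property
    def total(self) -> float:
        """Grand sum over all coarse elements (conserved under feedback)."""
        return float(self.values.sum())


def init_grid(rng: np.random.Generator, config: LandscapeConfig) -> FitnessGrid:
    """Draw a fresh coarse grid, i.i.d. uniform over ``config.fitness_range``."""
    lo, hi = config.fitness_range
    values = rng.uniform(lo, hi, size=(config.coarse_size, config.coarse_size))
    return FitnessGrid(values=values, generation_stamp=0)


def shift_grid(
    grid: FitnessGrid, rng: np.random.Generator, config: LandscapeConfig
) -> FitnessGrid:
    """Translate the coarse matrix one column in +x, refreshing column 0.

    Columns ``0..n-2`` of the input become columns ``1..n-1`` of the output
    (the last column is discarded); column 0 is refilled with fresh uniform
    draws over ``config.fitness_range``.
    """
    lo, hi = config.fitness_range
    n = grid.values.shape[0]
    out = np.empty_like(grid.values)
    out[:, 1:] = grid.values[:, :-1]
    out[:, 0] = rng.uniform(lo, hi, size=n)
    return FitnessGrid(values=out, generation_stamp=grid.generation_stamp + 1)


def apply_feedback(
    grid: FitnessGrid, positions: np.ndarray, config: LandscapeConfig
) -> FitnessGrid:
    """Deplete coarse cells by local organism density, conserving the total.

    Each cell loses ``feedback_coefficient * count`` where ``count`` is the
    number of organisms binned to it; the total subtracted amount is added
    back in equal shares to every cell, so ``grid.total`` is invariant.
    Organisms at position (x, y) bin to cell
    ``(floor(y / (extent/coarse_size)), floor(x / (extent/coarse_size)))``,
    clamped to the grid.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    cs = config.coarse_size
    if positions.size == 0:
        return grid
    cell = config.extent / cs
    ix = np.clip((positions[:, 0] // cell).astype(np.intp), 0, cs - 1)
    iy = np.clip((positions[:, 1] // cell).astype(np.intp), 0, cs - 1)
    counts = np.zeros((cs, cs))
    np.add.at(counts, (iy, ix), 1.0)
    decrement = config.feedback_coefficient * counts
    refund = decrement.sum() / (cs * cs)
    values = grid.values - decrement + refund
    return FitnessGrid(values=values, generation_stamp=grid.generation_stamp + 1)


def offspring_count(fitness, fitness_range: tuple[float, float] = (1.0, 4.0)):
    """Realize a fitness level as an integer brood size.

    Rounds half away from zero, then clamps to the integer fitness range
    (1-4 by default).  Accepts scalars or arrays.
    """
    f = np.asarray(fitness, dtype=float)
    rounded = np.sign(f) * np.floor(np.abs(f) + 0.5)
    lo = int(round(fitness_range[0]))
    hi = int(round(fitness_range[1]))
    out = np.clip(rounded, lo, hi).astype(int)
    if np.isscalar(fitness) or out.ndim == 0:
        return int(out)
    return out


class Landscape:
    """Continuous bilinear interpolant of a coarse fitness grid.

    The coarse nodes per axis sit at ``i * extent / (coarse_size - 1)``,
    ``i = 0..coarse_size-1``, spanning the full morphospace; ``fitness_at``
    evaluates the continuous interpolant directly (the discrete 45x45
    expanded matrix is a sampled view of it, available via ``sample_field``).
    """

    def __init__(self, grid: FitnessGrid, config: LandscapeConfig):
        if grid.values.shape[0] != config.coarse_size:
            raise ValueError("grid shape does not match config.coarse_size")
        self.grid = grid
        self.config = config
        self.extent = config.extent
        self.node_positions = np.linspace(0.0, config.extent, config.coarse_size)
        self._interp = RegularGridInterpolator(
            (self.node_positions, self.node_positions),
            grid.values,
            method="linear",
            bounds_error=True,
        )

    def fitness_at(self, coords):
        """Fitness level at one point (shape ``(2,)``) or many (``(n, 2)``).

        Raises ``ValueError`` for coordinates outside ``[0, extent]^2``.
        """
        pts = np.asarray(coords, dtype=float)
        scalar = pts.ndim == 1
        pts = np.atleast_2d(pts)
        if pts.shape[1] != 2:
            raise ValueError("coordinates must have two trait components")
        if np.any(pts < 0.0) or np.any(pts > self.extent):
            raise ValueError("coordinate outside morphospace bounds")
        # grid rows are y, columns are x -> query as (y, x)
        vals = self._interp(pts[:, ::-1])
        return float(vals[0]) if scalar else vals

    def with_grid(self, grid: FitnessGrid) -> "Landscape":
        """Return a new landscape over the same config but a new grid."""
        return Landscape(grid, self.config)

    def advance(
        self,
        rng: np.random.Generator,
        generation: int,
        positions: np.ndarray,
    ) -> "Landscape":
        """Apply one generation of landscape dynamics.

        In ``shifting`` mode, shifts the grid when
        ``generation % lambda_shift == 0``; in ``feedback`` mode, applies the
        density feedback using ``positions`` (the survivors of the
        generation); ``static`` returns ``self`` unchanged.
        """
        cfg = self.config
        if cfg.mode == "shifting":
            if generation % cfg.lambda_shift == 0:
                return self.with_grid(shift_grid(self.grid, rng, cfg))
            return self
        if cfg.mode == "feedback":
            return self.with_grid(apply_feedback(self.grid, positions, cfg))
        return self

    def sample_field(self, n: int = 45):
        """Sample the interpolant on an ``n x n`` lattice over the morphospace.

        Returns ``(xs, ys, values)`` with ``values[i, j]`` the fitness at
        ``(x=xs[j], y=ys[i])``; this is the discrete expanded matrix view.
        """
        xs = np.linspace(0.0, self.extent, n)
        ys = np.linspace(0.0, self.extent, n)
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        return xs, ys, self.fitness_at(pts).reshape(n, n)
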