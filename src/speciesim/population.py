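"""Organisms, assortative mating, mutation kernels, culling and the
per-generation update.

Organisms are points in the bounded morphospace.  Each generation every
organism mates with its Euclidean nearest neighbour and produces a brood whose
size is set by the local fitness; offspring coordinates fall, per axis, inside
the parental coordinate interval extended by the maximum mutation size ``mu``
on each side.  A random fraction of the offspring die, the rest are thinned so
that no two survivors sit closer than the overpopulation radius, and the
parents vanish.

Two mutation kernels are provided: ``uniform`` draws the offspring coordinate
uniformly over the mu-extended parental interval; ``normal`` draws it as the
parental midpoint plus a zero-mean normal offset of standard deviation
``b * (span + 2 mu)``, truncated (by redraw) to the same interval.  Under both
kernels mu is a hard bound on how far an offspring can land outside its
parents' coordinate range.

The per-generation random-number draws occur in a fixed order so that a run is
bitwise reproducible from its seed: (competition-mode mu inheritance) ->
kernel coordinate draws (with any out-of-bounds redraws) -> death fraction rho
-> death victim choice -> thinning order -> landscape refresh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .landscape import Landscape, offspring_count

__all__ = [
    "ExtinctionError",
    "ReproductionConfig",
    "Organism",
    "PopulationState",
    "init_population",
    "assign_mates",
    "draw_offspring_coord_uniform",
    "draw_offspring_coord_normal",
    "reproduce",
    "random_death",
    "thin_overcrowded",
    "step_generation",
    "nearest_neighbors",
]

# below this size nearest-neighbour search is brute force with exact
# (distance, id) tie-breaking; above it a cKDTree is used
_BRUTE_MAX = 128

VALID_KERNELS = ("uniform", "normal")


class ExtinctionError(RuntimeError):
    """Raised when fewer than two organisms remain: no mating is possible."""


@dataclass(frozen=True)
class ReproductionConfig:
    """Parameters of mating, mutation and culling.

    ``mu`` is the global maximum mutation size (trait units); it is ignored in
    ``competition_mode``, where each organism carries its own heritable mu.
    ``b`` is the width parameter of the normal kernel.  ``overpop_radius`` is
    the minimum spacing enforced by thinning and ``death_fraction_max`` the
    upper bound of the per-generation random death fraction rho ~ U(0, max).
    """

    mu: float = 0.35
    kernel: str = "uniform"
    b: float = 0.1581
    extent: float = 45.0
    overpop_radius: float = 0.25
    death_fraction_max: float = 0.70
    competition_mode: bool = False
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.kernel not in VALID_KERNELS:
            raise ValueError(f"kernel must be one of {VALID_KERNELS}")
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if not 0 <= self.death_fraction_max <= 1:
            raise ValueError("death_fraction_max must be in [0, 1]")
        if self.overpop_radius <= 0:
            raise ValueError("overpop_radius must be > 0")
        if self.extent <= 0:
            raise ValueError("extent must be > 0")


@dataclass
class Organism:
    """A single organism: a labelled point in morphospace."""

    id: int
    coords: tuple[float, float]
    mu: float = 0.0
    parent_ids: tuple[int, ...] = ()
    labeled: bool = False


@dataclass
class PopulationState:
    """One generation of organisms, stored columnwise for speed.

    ``ids`` are unique, strictly increasing within the state; ``coords`` is an
    ``(n, 2)`` float array; ``mu`` and ``labeled`` are per-organism columns.
    ``next_id`` is the first id free for the next generation.
    """

    generation: int
    ids: np.ndarray
    coords: np.ndarray
    mu: np.ndarray
    labeled: np.ndarray
    next_id: int

    @property
    def size(self) -> int:
        return len(self.ids)

    @property
    def extinct(self) -> bool:
        """True when no further generation can be produced (< 2 organisms)."""
        return self.size < 2

    def organisms(self) -> list[Organism]:
        """Materialize the state as a list of :class:`Organism`."""
        return [
            Organism(
                id=int(i),
                coords=(float(x), float(y)),
                mu=float(m),
                labeled=bool(l),
            )
            for i, (x, y), m, l in zip(self.ids, self.coords, self.mu, self.labeled)
        ]

    @classmethod
    def from_organisms(
        cls, organisms: list[Organism], generation: int = 0
    ) -> "PopulationState":
        organisms = sorted(organisms, key=lambda o: o.id)
        ids = np.array([o.id for o in organisms], dtype=np.int64)
        if len(np.unique(ids)) != len(ids):
            raise ValueError("organism ids must be unique")
        coords = np.array([o.coords for o in organisms], dtype=float)
        mu = np.array([o.mu for o in organisms], dtype=float)
        labeled = np.array([o.labeled for o in organisms], dtype=bool)
        next_id = int(ids.max()) + 1 if len(ids) else 0
        return cls(generation, ids, coords, mu, labeled, next_id)


def init_population(
    n: int, rng: np.random.Generator, config: ReproductionConfig
) -> PopulationState:
    """Found a generation-0 population of ``n`` organisms placed uniformly.

    In competition mode each founder's mu is drawn i.i.d. uniform on [0, 1];
    otherwise all organisms share ``config.mu``.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    coords = rng.uniform(0.0, config.extent, size=(n, 2))
    if config.competition_mode:
        mu = rng.uniform(0.0, 1.0, size=n)
    else:
        mu = np.full(n, config.mu)
    return PopulationState(
        generation=0,
        ids=np.arange(n, dtype=np.int64),
        coords=coords,
        mu=mu,
        labeled=np.zeros(n, dtype=bool),
        next_id=n,
    )


# ---------------------------------------------------------------------------
# nearest neighbours and mate assignment


def nearest_neighbors(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second nearest *other* organism for every row of ``coords``.

    Returns index arrays ``(nn, nn2)``; ``nn2`` is ``-1`` when only two
    organisms exist.  For small populations a brute-force search breaks exact
    distance ties by the lower index (equivalently, the lower id when rows are
    id-ordered); large populations use a cKDTree, where exact ties are
    measure-zero.
    """
    n = len(coords)
    if n < 2:
        raise ExtinctionError("at least two organisms are required for mating")
    if n == 2:
        return np.array([1, 0]), np.array([-1, -1])
    if n <= _BRUTE_MAX:
        diff = coords[:, None, :] - coords[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.fill_diagonal(d2, np.inf)
        order = np.argsort(d2, axis=1, kind="stable")
        return order[:, 0], order[:, 1]
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=3)
    rows = np.arange(n)
    not_self = idx != rows[:, None]
    first = not_self.argmax(axis=1)
    not_self[rows, first] = False
    second = not_self.argmax(axis=1)
    return idx[rows, first], idx[rows, second]


def assign_mates(organisms: list[Organism]) -> dict[int, int]:
    """Map every organism id to the id of its nearest other organism.

    The relation need not be symmetric; exact distance ties are broken in
    favour of the lowest id.  Raises :class:`ExtinctionError` for fewer than
    two organisms.
    """
    if len(organisms) < 2:
        raise ExtinctionError("at least two organisms are required for mating")
    organisms = sorted(organisms, key=lambda o: o.id)
    coords = np.array([o.coords for o in organisms], dtype=float)
    nn, _ = nearest_neighbors(coords)
    return {o.id: organisms[j].id for o, j in zip(organisms, nn)}


# ---------------------------------------------------------------------------
# mutation kernels


def _redraw_or_clip(out, bad_fn, draw_fn, lo, hi, max_redraws):
    """Redraw flagged entries up to ``max_redraws`` times, then clip."""
    for _ in range(max_redraws):
        bad = bad_fn(out)
        k = int(bad.sum())
        if k == 0:
            return out
        out[bad] = draw_fn(bad, k)
    np.clip(out, lo, hi, out=out)
    return out


def _draw_uniform_coords(p1, p2, mu, rng, extent, max_redraws=100):
    """Vectorized uniform-kernel draw for broods; arrays shaped ``(m, 2)``."""
    mu = np.asarray(mu, dtype=float)[:, None]
    lo = np.minimum(p1, p2) - mu
    span = np.abs(p1 - p2) + 2.0 * mu
    out = lo + rng.random(p1.shape) * span

    def bad_fn(o):
        return (o < 0.0) | (o > extent)

    def draw_fn(bad, k):
        return lo[bad] + rng.random(k) * span[bad]

    # the draw already lies in the mu-extended interval; only the morphospace
    # bounds can be violated.  Clipping to [0, extent] cannot leave the
    # mu-extended interval because both parents are in bounds.
    return _redraw_or_clip(out, bad_fn, draw_fn, 0.0, extent, max_redraws)


def _draw_normal_coords(p1, p2, mu, b, rng, extent, max_redraws=100):
    """Vectorized normal-kernel draw: midpoint + N(0, b^2) * (span + 2 mu)."""
    mu = np.asarray(mu, dtype=float)[:, None]
    mid = 0.5 * (p1 + p2)
    width = np.abs(p1 - p2) + 2.0 * mu
    lo = np.maximum(np.minimum(p1, p2) - mu, 0.0)
    hi = np.minimum(np.maximum(p1, p2) + mu, extent)
    out = mid + rng.normal(0.0, b, size=p1.shape) * width

    def bad_fn(o):
        return (o < lo) | (o > hi)

    def draw_fn(bad, k):
        return mid[bad] + rng.normal(0.0, b, size=k) * width[bad]

    return _redraw_or_clip(out, bad_fn, draw_fn, lo, hi, max_redraws)


def draw_offspring_coord_uniform(
    p1, p2, mu: float, rng: np.random.Generator, extent: float = 45.0
) -> np.ndarray:
    """Draw one offspring coordinate under the uniform mutation kernel.

    Per axis, ``c = (min(c1, c2) - mu) + r * (|c1 - c2| + 2 mu)`` with
    ``r ~ U(0, 1)``; axes falling outside the morphospace are redrawn, then
    clipped as a last resort.
    """
    p1 = np.asarray(p1, dtype=float)[None, :]
    p2 = np.asarray(p2, dtype=float)[None, :]
    return _draw_uniform_coords(p1, p2, np.array([mu]), rng, extent)[0]


def draw_offspring_coord_normal(
    p1,
    p2,
    mu: float,
    b: float,
    rng: np.random.Generator,
    extent: float = 45.0,
) -> np.ndarray:
    """Draw one offspring coordinate under the normal mutation kernel.

    Per axis, ``c = midpoint + eps * (|c1 - c2| + 2 mu)`` with
    ``eps ~ N(0, b^2)``, redrawn until it falls inside both the mu-extended
    parental interval and the morphospace.
    """
    p1 = np.asarray(p1, dtype=float)[None, :]
    p2 = np.asarray(p2, dtype=float)[None, :]
    return _draw_normal_coords(p1, p2, np.array([mu]), b, rng, extent)[0]


# ---------------------------------------------------------------------------
# reproduction and culling


def _reproduce_arrays(
    state: PopulationState,
    landscape: Landscape,
    config: ReproductionConfig,
    rng: np.random.Generator,
    nn: np.ndarray | None = None,
):
    """Produce the offspring arrays for one generation.

    Returns ``(coords, mu, labeled, parent1_idx, parent2_idx)`` where the
    parent index arrays point into ``state``.
    """
    n = state.size
    if n < 2:
        raise ExtinctionError("at least two organisms are required for mating")
    if nn is None:
        nn, _ = nearest_neighbors(state.coords)
    fitness = landscape.fitness_at(state.coords)
    counts = offspring_count(fitness, landscape.config.fitness_range)
    p1 = np.repeat(np.arange(n), counts)
    p2 = nn[p1]
    if config.competition_mode:
        take_first = rng.random(len(p1)) < 0.5
        child_mu = np.where(take_first, state.mu[p1], state.mu[p2])
    else:
        child_mu = np.full(len(p1), config.mu)
    c1 = state.coords[p1]
    c2 = state.coords[p2]
    if config.kernel == "uniform":
        coords = _draw_uniform_coords(
            c1, c2, child_mu, rng, config.extent, config.max_redraws
        )
    else:
        coords = _draw_normal_coords(
            c1, c2, child_mu, config.b, rng, config.extent, config.max_redraws
        )
    labeled = state.labeled[p1] | state.labeled[p2]
    return coords, child_mu, labeled, p1, p2


def reproduce(
    state: PopulationState,
    landscape: Landscape,
    config: ReproductionConfig,
    rng: np.random.Generator,
) -> list[Organism]:
    """Produce the full brood of the current generation as organisms.

    Each organism mates with its nearest neighbour and produces
    ``offspring_count(fitness_at(coords))`` offspring; offspring inherit the
    lineage label from either parent, and in competition mode the mu of one
    parent chosen by a fair coin.
    """
    coords, child_mu, labeled, p1, p2 = _reproduce_arrays(
        state, landscape, config, rng
    )
    ids = state.next_id + np.arange(len(p1))
    return [
        Organism(
            id=int(i),
            coords=(float(x), float(y)),
            mu=float(m),
            parent_ids=(int(state.ids[a]), int(state.ids[b])),
            labeled=bool(l),
        )
        for i, (x, y), m, a, b, l in zip(ids, coords, child_mu, p1, p2, labeled)
    ]


def _death_mask(
    n: int,
    rng: np.random.Generator,
    death_fraction_max: float,
    rho: float | None = None,
) -> np.ndarray:
    """Boolean survival mask after random death of ``round(rho * n)``."""
    if rho is None:
        rho = rng.uniform(0.0, death_fraction_max)
    k = int(round(rho * n))
    mask = np.ones(n, dtype=bool)
    if k > 0:
        victims = rng.choice(n, size=k, replace=False)
        mask[victims] = False
    return mask


def random_death(
    offspring: list[Organism],
    rng: np.random.Generator,
    config: ReproductionConfig,
    rho: float | None = None,
) -> list[Organism]:
    """Remove ``round(rho * N)`` organisms chosen uniformly without
    replacement, with ``rho ~ U(0, death_fraction_max)`` drawn once (or forced
    via ``rho`` for testing)."""
    mask = _death_mask(len(offspring), rng, config.death_fraction_max, rho)
    return [o for o, keep in zip(offspring, mask) if keep]


def _thin_mask(
    coords: np.ndarray,
    radius: float,
    rng: np.random.Generator,
    order: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy overcrowding thinning in (uniformly random) ``order``.

    An organism is kept iff no already-kept organism lies strictly closer
    than ``radius``; keeping an organism eliminates all of its not-yet-kept
    neighbours within the radius, which is equivalent.
    """
    n = len(coords)
    if order is None:
        order = rng.permutation(n)
    if n < 2:
        return np.ones(n, dtype=bool)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < radius]
    alive = np.ones(n, dtype=bool)
    if len(pairs) == 0:
        return alive
    # CSR-style adjacency over conflicting pairs only
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    sorter = np.argsort(src, kind="stable")
    src, dst = src[sorter], dst[sorter]
    indptr = np.searchsorted(src, np.arange(n + 1))
    for i in order:
        if alive[i]:
            alive[dst[indptr[i] : indptr[i + 1]]] = False
    return alive


def thin_overcrowded(
    offspring: list[Organism],
    radius: float,
    rng: np.random.Generator,
    order: np.ndarray | None = None,
) -> list[Organism]:
    """Thin organisms so that all surviving pairs are >= ``radius`` apart."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    coords = np.array([o.coords for o in offspring], dtype=float)
    if len(coords) == 0:
        return []
    mask = _thin_mask(coords, radius, rng, order)
    return [o for o, keep in zip(offspring, mask) if keep]


def step_generation(
    state: PopulationState,
    landscape: Landscape,
    config: ReproductionConfig,
    rng: np.random.Generator,
    nn: np.ndarray | None = None,
) -> tuple[PopulationState, Landscape]:
    """Advance one generation: mate, reproduce, cull, thin, update landscape.

    The parents vanish; the returned state holds only the surviving
    offspring.  Raises :class:`ExtinctionError` when fewer than two parents
    exist; the returned state may itself be extinct (fewer than two
    survivors), which callers should check before stepping again.
    ``nn`` may carry precomputed nearest-neighbour indices for the parents.
    """
    coords, child_mu, labeled, p1, p2 = _reproduce_arrays(
        state, landscape, config, rng, nn=nn
    )
    mask = _death_mask(len(coords), rng, config.death_fraction_max)
    coords, child_mu, labeled = coords[mask], child_mu[mask], labeled[mask]
    if len(coords):
        keep = _thin_mask(coords, config.overpop_radius, rng)
        coords, child_mu, labeled = coords[keep], child_mu[keep], labeled[keep]
    new_landscape = landscape.advance(rng, state.generation, coords)
    m = len(coords)
    new_state = PopulationState(
        generation=state.generation + 1,
        ids=state.next_id + np.arange(m, dtype=np.int64),
        coords=coords,
        mu=child_mu,
        labeled=labeled,
        next_id=state.next_id + m,
    )
    return new_state, new_landscape
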