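"""Simulation driver and the measurement layer: per-generation order
parameters, mu sweeps, lineage tracing and mu-competition summaries.

A run records, for every generation, the population size, the number of
species clusters, the within-cluster diversity and the largest realized brood
size; lineage runs additionally track the fraction of organisms descended
from a single labelled founder, and competition runs the distribution of the
heritable per-organism mu.  Sweep utilities repeat seeded runs over a grid of
mu values and aggregate the per-run summaries with across-replicate means and
standard deviations, mirroring how the model's order parameters (population,
cluster count, diversity, population-cluster correlation) are reported as
functions of mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landscape import Landscape, LandscapeConfig, init_grid, offspring_count
from .population import (
    ReproductionConfig,
    init_population,
    nearest_neighbors,
    step_generation,
)
from .species import cluster_labels, diversity_from_labels

__all__ = [
    "SimulationConfig",
    "RunRecord",
    "RunSummary",
    "SweepSummary",
    "LineageTrace",
    "OptimalMu",
    "CompetitionSummary",
    "make_config",
    "run_simulation",
    "summarize_run",
    "population_cluster_correlation",
    "trace_lineage",
    "run_lineage",
    "lineage_histograms",
    "sweep_mu",
    "find_optimal_mu",
    "run_competition",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one simulation run (landscape + reproduction +
    run length), independent of the seed."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    reproduction: ReproductionConfig = field(default_factory=ReproductionConfig)
    n_init: int = 300
    generations: int = 1000
    label_founder: bool = False
    record_mu_every: int | None = None
    snapshot_every: int | None = None

    def to_dict(self) -> dict:
        l, r = self.landscape, self.reproduction
        return {
            "landscape": {
                "mode": l.mode,
                "lambda": l.lambda_shift,
                "feedback_coefficient": l.feedback_coefficient,
                "extent": l.extent,
                "coarse_size": l.coarse_size,
                "fitness_min": l.fitness_range[0],
                "fitness_max": l.fitness_range[1],
            },
            "reproduction": {
                "mu": r.mu,
                "kernel": r.kernel,
                "b": r.b,
                "overpop_radius": r.overpop_radius,
                "death_fraction_max": r.death_fraction_max,
                "competition": r.competition_mode,
            },
            "run": {
                "n_init": self.n_init,
                "generations": self.generations,
                "label_founder": self.label_founder,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        l = d.get("landscape", {})
        r = d.get("reproduction", {})
        run = d.get("run", {})
        landscape = LandscapeConfig(
            mode=l.get("mode", "shifting"),
            lambda_shift=int(l.get("lambda", 2)),
            feedback_coefficient=float(l.get("feedback_coefficient", 0.0071)),
            fitness_range=(
                float(l.get("fitness_min", 1.0)),
                float(l.get("fitness_max", 4.0)),
            ),
            extent=float(l.get("extent", 45.0)),
            coarse_size=int(l.get("coarse_size", 12)),
        )
        reproduction = ReproductionConfig(
            mu=float(r.get("mu", 0.35)),
            kernel=r.get("kernel", "uniform"),
            b=float(r.get("b", 0.1581)),
            extent=landscape.extent,
            overpop_radius=float(r.get("overpop_radius", 0.25)),
            death_fraction_max=float(r.get("death_fraction_max", 0.70)),
            competition_mode=bool(r.get("competition", False)),
        )
        return cls(
            landscape=landscape,
            reproduction=reproduction,
            n_init=int(run.get("n_init", 300)),
            generations=int(run.get("generations", 1000)),
            label_founder=bool(run.get("label_founder", False)),
        )


def make_config(
    landscape_mode: str = "shifting",
    kernel: str = "uniform",
    mu: float = 0.35,
    *,
    competition: bool = False,
    n_init: int = 300,
    generations: int = 1000,
    label_founder: bool = False,
    record_mu_every: int | None = None,
    snapshot_every: int | None = None,
    extent: float = 45.0,
    **reproduction_kwargs,
) -> SimulationConfig:
    """Convenience constructor covering the model's standard variants."""
    return SimulationConfig(
        landscape=LandscapeConfig(mode=landscape_mode, extent=extent),
        reproduction=ReproductionConfig(
            mu=mu,
            kernel=kernel,
            extent=extent,
            competition_mode=competition,
            **reproduction_kwargs,
        ),
        n_init=n_init,
        generations=generations,
        label_founder=label_founder,
        record_mu_every=record_mu_every,
        snapshot_every=snapshot_every,
    )


# ---------------------------------------------------------------------------
# records


@dataclass
class RunRecord:
    """Per-generation time series plus metadata of one simulation run.

    ``series`` holds one row per recorded generation with columns
    ``generation, population, n_clusters, diversity, max_brood,
    labeled_fraction`` and, for competition runs, ``n_distinct_mu, modal_mu,
    modal_mu_fraction``.  ``extinct_at`` is the generation at which fewer
    than two organisms remained (None when the run completed).
    """

    mu: float | str
    kernel: str
    landscape_mode: str
    seed: int | None
    series: pd.DataFrame
    extinct_at: int | None = None
    mu_snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    snapshots: pd.DataFrame | None = None


@dataclass(frozen=True)
class RunSummary:
    mean_population: float
    mean_clusters: float
    mean_diversity: float


@dataclass
class SweepSummary:
    """Across-replicate aggregation of runs over a grid of mu values.

    ``table`` holds one row per mu with mean/sd of population, cluster count,
    diversity and population-cluster correlation, plus the replicate count.
    """

    table: pd.DataFrame


@dataclass
class LineageTrace:
    """Fraction of organisms descended from the single labelled founder."""

    mu: float
    ratio_series: np.ndarray
    max_ratio: float


@dataclass(frozen=True)
class OptimalMu:
    """Argmax of the across-replicate mean cluster count over a mu grid."""

    mu: float
    mean_clusters: float
    interior: bool  # False when the maximum sits at an end of the grid


@dataclass
class CompetitionSummary:
    """Outcome of a heritable-mu competition run."""

    dominant_mu: float | None
    dominance_generation: int | None
    mu_snapshots: dict[int, np.ndarray]
    series: pd.DataFrame
    extinct_at: int | None


# ---------------------------------------------------------------------------
# the simulation loop


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# histogram resolution at which competition dominance is assessed: carriers
# of nearby mu values pool into bins of width 1/_DOMINANCE_BINS on [0, 1]
_DOMINANCE_BINS = 10


def _modal_fraction(mu: np.ndarray, bins: int = _DOMINANCE_BINS):
    """Modal exact value and modal histogram bin of a mu distribution.

    Returns ``(modal value, value fraction, n distinct, bin left edge,
    bin fraction)``; the bin view pools carriers of nearby mu values, which
    is the resolution at which a dominant mutation size is visible in a
    histogram of the population.
    """
    values, counts = np.unique(mu, return_counts=True)
    k = int(np.argmax(counts))
    hist, edges = np.histogram(mu, bins=bins, range=(0.0, 1.0))
    j = int(np.argmax(hist))
    return (
        float(values[k]),
        float(counts[k] / len(mu)),
        len(values),
        float(edges[j]),
        float(hist[j] / len(mu)),
    )


def run_simulation(config: SimulationConfig, seed=None) -> RunRecord:
    """Run one seeded simulation, measuring every generation.

    For each generation the parents are measured (population, species
    clusters via the mating graph, within-cluster diversity, largest brood
    size implied by the current landscape) and then advanced.  The run stops
    after ``config.generations`` steps or as soon as fewer than two organisms
    remain, whichever comes first.
    """
    rng = _as_rng(seed)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else None
    lc, rc = config.landscape, config.reproduction
    landscape = Landscape(init_grid(rng, lc), lc)
    state = init_population(config.n_init, rng, rc)
    if config.label_founder:
        state.labeled[rng.integers(state.size)] = True

    rows = []
    mu_snapshots: dict[int, np.ndarray] = {}
    snapshot_frames = []
    extinct_at = None
    competition = rc.competition_mode

    for g in range(config.generations + 1):
        n = state.size
        if n == 0:
            extinct_at = g
            break
        nn = nn2 = None
        if n >= 2:
            nn, nn2 = nearest_neighbors(state.coords)
            labels = cluster_labels(nn, nn2)
            n_clusters = int(labels.max()) + 1
            diversity = diversity_from_labels(state.coords, labels)
        else:
            n_clusters, diversity = 1, float("nan")
        brood = offspring_count(
            landscape.fitness_at(state.coords), lc.fitness_range
        )
        row = {
            "generation": g,
            "population": n,
            "n_clusters": n_clusters,
            "diversity": diversity,
            "max_brood": int(np.max(brood)),
            "labeled_fraction": float(state.labeled.mean()),
        }
        if competition:
            modal_mu, modal_frac, distinct, bin_left, bin_frac = _modal_fraction(
                state.mu
            )
            row.update(
                n_distinct_mu=distinct,
                modal_mu=modal_mu,
                modal_mu_fraction=modal_frac,
                modal_bin_left=bin_left,
                modal_bin_fraction=bin_frac,
            )
        rows.append(row)
        if config.record_mu_every and g % config.record_mu_every == 0:
            mu_snapshots[g] = state.mu.copy()
        if config.snapshot_every and g % config.snapshot_every == 0:
            snapshot_frames.append(
                pd.DataFrame(
                    {
                        "generation": g,
                        "id": state.ids,
                        "x": state.coords[:, 0],
                        "y": state.coords[:, 1],
                        "mu": state.mu,
                        "labeled": state.labeled,
                    }
                )
            )
        if n < 2:
            extinct_at = g
            break
        if g == config.generations:
            break
        state, landscape = step_generation(state, landscape, rc, rng, nn=nn)

    series = pd.DataFrame(rows)
    return RunRecord(
        mu="competition" if competition else rc.mu,
        kernel=rc.kernel,
        landscape_mode=lc.mode,
        seed=seed_repr,
        series=series,
        extinct_at=extinct_at,
        mu_snapshots=mu_snapshots,
        snapshots=pd.concat(snapshot_frames, ignore_index=True)
        if snapshot_frames
        else None,
    )


# ---------------------------------------------------------------------------
# order parameters


def summarize_run(series: pd.DataFrame) -> RunSummary:
    """Means over generations with population > 0 only.

    The diversity mean skips generations where diversity is undefined (all
    clusters singletons).  All-extinct series yield NaN summaries.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    alive = series[series["population"] > 0]
    if len(alive) == 0:
        return RunSummary(float("nan"), float("nan"), float("nan"))
    div = alive["diversity"].dropna()
    return RunSummary(
        mean_population=float(alive["population"].mean()),
        mean_clusters=float(alive["n_clusters"].mean()),
        mean_diversity=float(div.mean()) if len(div) else float("nan"),
    )


def population_cluster_correlation(series: pd.DataFrame) -> float:
    """Pearson correlation between the population and cluster-count series.

    Computed over generations with population > 0; NaN when fewer than three
    such generations exist or either series is constant.
    """
    alive = series[series["population"] > 0]
    if len(alive) < 3:
        return float("nan")
    p = alive["population"].to_numpy(dtype=float)
    c = alive["n_clusters"].to_numpy(dtype=float)
    if np.std(p) == 0.0 or np.std(c) == 0.0:
        return float("nan")
    return float(np.corrcoef(p, c)[0, 1])


# ---------------------------------------------------------------------------
# lineage tracing


def trace_lineage(record: RunRecord) -> LineageTrace:
    """Extract the labelled-lineage trace from a run with a labelled founder."""
    ratios = record.series["labeled_fraction"].to_numpy(dtype=float)
    if len(ratios) == 0 or ratios[0] <= 0:
        raise ValueError("run does not carry a labelled founder")
    return LineageTrace(
        mu=record.mu if isinstance(record.mu, float) else float("nan"),
        ratio_series=ratios,
        max_ratio=float(ratios.max()),
    )


def run_lineage(config: SimulationConfig, seed=None) -> LineageTrace:
    """Run one simulation with a single random labelled founder and trace it."""
    if not config.label_founder:
        config = replace(config, label_founder=True)
    return trace_lineage(run_simulation(config, seed))


def lineage_histograms(
    traces: Iterable[LineageTrace],
    low_range: tuple[float, float] = (0.2, 0.35),
    high_range: tuple[float, float] = (0.36, 0.5),
    bins: int = 10,
):
    """Histograms of max labelled ratio for a low and a high band of mu.

    Returns ``(low_counts, high_counts, bin_edges)`` with ``bins`` equal bins
    on [0, 1].
    """
    traces = list(traces)
    edges = np.linspace(0.0, 1.0, bins + 1)

    def hist(lo, hi):
        vals = [t.max_ratio for t in traces if lo <= t.mu <= hi]
        counts, _ = np.histogram(vals, bins=edges)
        return counts

    return hist(*low_range), hist(*high_range), edges


# ---------------------------------------------------------------------------
# sweeps and competition


def _spawn_seeds(seed, n: int) -> list[np.random.SeedSequence]:
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return base.spawn(n)


def sweep_mu(
    mu_grid: Sequence[float],
    reps: int,
    base_config: SimulationConfig,
    seed=None,
) -> SweepSummary:
    """Run ``reps`` independent seeded simulations at every mu on the grid.

    Per mu, aggregates the per-run summaries (population, clusters,
    diversity, population-cluster correlation) with across-replicate means
    and sample standard deviations (0 for a single replicate).  Correlation
    means skip runs where the correlation is undefined.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    mu_grid = sorted(float(m) for m in mu_grid)
    seeds = _spawn_seeds(seed, len(mu_grid) * reps)
    rows = []
    for i, mu in enumerate(mu_grid):
        pops, clus, divs, corrs, extinct = [], [], [], [], 0
        for r in range(reps):
            cfg = replace(
                base_config,
                reproduction=replace(base_config.reproduction, mu=mu),
            )
            rec = run_simulation(cfg, np.random.default_rng(seeds[i * reps + r]))
            s = summarize_run(rec.series)
            pops.append(s.mean_population)
            clus.append(s.mean_clusters)
            divs.append(s.mean_diversity)
            corrs.append(population_cluster_correlation(rec.series))
            extinct += rec.extinct_at is not None

        def agg(vals):
            vals = np.asarray(vals, dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                return float("nan"), float("nan")
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            return float(vals.mean()), sd

        mp, sp = agg(pops)
        mc, sc = agg(clus)
        md, sd_ = agg(divs)
        mr, sr = agg(corrs)
        rows.append(
            {
                "mu": mu,
                "mean_population": mp,
                "sd_population": sp,
                "mean_clusters": mc,
                "sd_clusters": sc,
                "mean_diversity": md,
                "sd_diversity": sd_,
                "mean_corr": mr,
                "sd_corr": sr,
                "n_reps": reps,
                "n_extinct": extinct,
            }
        )
    return SweepSummary(table=pd.DataFrame(rows))


def find_optimal_mu(summary: SweepSummary) -> OptimalMu:
    """mu maximizing the across-replicate mean cluster count.

    Ties are broken in favour of the smaller mu; ``interior`` is False when
    the maximum sits at an end of the grid (no interior maximum).
    """
    t = summary.table
    if len(t) < 3:
        raise ValueError("at least three mu values are required")
    k = int(np.nanargmax(t["mean_clusters"].to_numpy()))
    return OptimalMu(
        mu=float(t["mu"].iloc[k]),
        mean_clusters=float(t["mean_clusters"].iloc[k]),
        interior=0 < k < len(t) - 1,
    )


def run_competition(
    config: SimulationConfig | None = None,
    generations: int = 1000,
    record_every: int = 10,
    dominance_threshold: float = 0.5,
    seed=None,
) -> CompetitionSummary:
    """Run one heritable-mu competition simulation.

    Founder mu values are drawn uniformly on [0, 1]; each offspring inherits
    the mu of one parent chosen by a fair coin, so extinct mu values never
    reappear.  Reports the most-carried mu value at the final generation and
    the first generation at which the modal mu histogram bin's carriers
    exceed ``dominance_threshold`` of the population (None when the run ends
    before dominance).  Dominance is assessed at histogram-bin resolution
    (bins of width 0.1 on [0, 1]) because the surviving carriers concentrate
    on a narrow band of mu long before drift singles out one exact founder
    value; the per-value fractions remain available in the series.
    """
    if config is None:
        config = make_config(
            "shifting", "uniform", competition=True, generations=generations
        )
    if not config.reproduction.competition_mode:
        raise ValueError("competition mode must be enabled in the config")
    if not config.record_mu_every:
        config = replace(config, record_mu_every=record_every)
    record = run_simulation(config, seed)
    s = record.series
    dominant_mu = None
    if len(s) and s["population"].iloc[-1] > 0:
        dominant_mu = float(s["modal_mu"].iloc[-1])
    over = s[s["modal_bin_fraction"] > dominance_threshold]
    dominance_generation = int(over["generation"].iloc[0]) if len(over) else None
    return CompetitionSummary(
        dominant_mu=dominant_mu,
        dominance_generation=dominance_generation,
        mu_snapshots=record.mu_snapshots,
        series=s,
        extinct_at=record.extinct_at,
    )
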