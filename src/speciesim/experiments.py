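"""The five standard experiments, end to end, plus deterministic
micro-fixtures for tests.

The model's standard study design crosses the two landscape dynamics with the
two mutation kernels (experiments 1-4, each a sweep over a mu grid) and adds
a fifth experiment in which mu is a heritable per-organism trait competing on
the shifting landscape with uniform mutations.  Each experiment runs at
either ``full`` scale (1000 generations, 300 founders, 5 replicates per mu,
mu step 0.05) or the reduced ``desk`` scale (300 generations, 3 replicates,
mu step 0.1) and writes its CSV artifacts with a JSON sidecar carrying the
configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .analysis import (
    SimulationConfig,
    make_config,
    run_competition,
    sweep_mu,
)
from .io import write_competition_csv, write_sidecar, write_sweep_csv
from .population import Organism

__all__ = [
    "EXPERIMENTS",
    "ExperimentSpec",
    "Fixture",
    "run_experiment",
    "make_fixture",
    "mu_grid_for",
]

# name -> (landscape mode, mutation kernel, competition?)
EXPERIMENTS: dict[str, tuple[str, str, bool]] = {
    "exp1_shift_uniform": ("shifting", "uniform", False),
    "exp2_feedback_uniform": ("feedback", "uniform", False),
    "exp3_shift_normal": ("shifting", "normal", False),
    "exp4_feedback_normal": ("feedback", "normal", False),
    "exp5_competition": ("shifting", "uniform", True),
}

_SCALES = {
    # generations, reps, mu grid step multiplier
    "full": {"generations": 1000, "reps": 5, "mu_step": 0.05},
    "desk": {"generations": 300, "reps": 3, "mu_step": 0.1},
}


@dataclass(frozen=True)
class ExperimentSpec:
    """One named experiment plus scale and config overrides."""

    name: str
    overrides: dict = field(default_factory=dict)
    scale: str = "desk"

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from "
                f"{sorted(EXPERIMENTS)}"
            )
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {sorted(_SCALES)}")


def mu_grid_for(kernel: str, step: float = 0.05) -> np.ndarray:
    """Default mu grid: 0.05-1.0 for the uniform kernel, 0.05-1.5 for the
    normal kernel (whose transitions occur at larger mu)."""
    top = 1.0 if kernel == "uniform" else 1.5
    n = int(round((top - 0.05) / step)) + 1
    return np.round(0.05 + step * np.arange(n), 10)


def _base_config(spec: ExperimentSpec) -> SimulationConfig:
    mode, kernel, competition = EXPERIMENTS[spec.name]
    scale = _SCALES[spec.scale]
    cfg = make_config(
        mode,
        kernel,
        competition=competition,
        generations=scale["generations"],
        **{
            k: v
            for k, v in spec.overrides.items()
            if k in ("n_init", "b", "overpop_radius", "death_fraction_max")
        },
    )
    if "generations" in spec.overrides:
        cfg = replace(cfg, generations=int(spec.overrides["generations"]))
    return cfg


def run_experiment(spec: ExperimentSpec, out_dir, seed: int = 0) -> Path:
    """Run one experiment end to end; returns the output directory.

    Sweep experiments write ``sweep_summary.csv``; the competition experiment
    writes one ``competition_rep<k>.csv`` mu histogram per replicate.  Every
    artifact set gets a ``sidecar.json`` with config, seed and scale.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create output directory {out_dir}: {err}") from err
    mode, kernel, competition = EXPERIMENTS[spec.name]
    scale = _SCALES[spec.scale]
    cfg = _base_config(spec)
    if competition:
        reps = int(spec.overrides.get("reps", scale["reps"]))
        seeds = np.random.SeedSequence(seed).spawn(reps)
        dominant = []
        for k, s in enumerate(seeds):
            summary = run_competition(
                replace(cfg, record_mu_every=10),
                seed=np.random.default_rng(s),
            )
            write_competition_csv(summary, out_dir / f"competition_rep{k}.csv")
            summary.series.to_csv(
                out_dir / f"competition_rep{k}_series.csv", index=False
            )
            dominant.append(
                {
                    "rep": k,
                    "dominant_mu": summary.dominant_mu,
                    "dominance_generation": summary.dominance_generation,
                    "extinct_at": summary.extinct_at,
                }
            )
        write_sidecar(
            cfg,
            seed,
            out_dir / "sidecar.json",
            experiment=spec.name,
            scale=spec.scale,
            replicates=dominant,
        )
    else:
        grid = spec.overrides.get("mu_grid")
        if grid is None:
            grid = mu_grid_for(kernel, scale["mu_step"])
        reps = int(spec.overrides.get("reps", scale["reps"]))
        summary = sweep_mu(list(grid), reps, cfg, seed=seed)
        write_sweep_csv(summary, out_dir / "sweep_summary.csv")
        write_sidecar(
            cfg,
            seed,
            out_dir / "sidecar.json",
            experiment=spec.name,
            scale=spec.scale,
            mu_grid=[float(m) for m in grid],
            reps=reps,
        )
    return out_dir


# ---------------------------------------------------------------------------
# deterministic micro-fixtures


@dataclass(frozen=True)
class Fixture:
    """Hand-placed organism configuration with oracle-verified expectations."""

    name: str
    organisms: tuple
    expected: dict


def _org(i, x, y):
    return Organism(id=i, coords=(float(x), float(y)))


_FIXTURES = {}


def _register(name, organisms, expected):
    _FIXTURES[name] = Fixture(name, tuple(organisms), expected)


# Two tight pairs far apart.  Mates stay within each pair, but every
# organism's second-nearest neighbour lies in the other pair, so the
# second-neighbour edges bridge the pairs into a single cluster.
_register(
    "two-pairs",
    [_org(0, 10.0, 10.0), _org(1, 10.1, 10.0), _org(2, 30.0, 30.0), _org(3, 30.1, 30.0)],
    {
        "mates": {0: 1, 1: 0, 2: 3, 3: 2},
        "n_clusters": 1,
    },
)

# Three tight triplets, mutually far apart: both the mate and the
# second-nearest neighbour of every organism stay inside its triplet, so the
# partition has three clusters.  Each triplet is a right triangle with legs
# 0.6, so its mean pairwise distance is (0.6 + 0.6 + 0.6*sqrt(2)) / 3.
_TRIPLET_OFFSETS = [(0.0, 0.0), (0.6, 0.0), (0.0, 0.6)]
_register(
    "three-triplets",
    [
        _org(3 * k + j, cx + dx, cy + dy)
        for k, (cx, cy) in enumerate([(5.0, 5.0), (25.0, 5.0), (15.0, 35.0)])
        for j, (dx, dy) in enumerate(_TRIPLET_OFFSETS)
    ],
    {
        "n_clusters": 3,
        "diversity": (0.6 + 0.6 + 0.6 * np.sqrt(2.0)) / 3.0,
    },
)

# Five organisms on a line spaced 0.2 apart (below the 0.25 overpopulation
# limit).  Greedy thinning in identity order keeps ids 0, 2, 4.
_register(
    "line-of-five",
    [_org(i, 10.0 + 0.2 * i, 10.0) for i in range(5)],
    {
        "survivors_identity_order": [0, 2, 4],
        "radius": 0.25,
    },
)


def make_fixture(name: str) -> Fixture:
    """Return a named deterministic fixture; raises listing known names."""
    try:
        return _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
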