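"""CSV/JSON/YAML writers and readers for runs, sweeps, partitions and grids.

All artifacts are plain text: per-run time series, sweep summary tables,
competition mu histograms, organism snapshots, cluster partitions, coarse
fitness grids, and a JSON sidecar recording the configuration and seed of
every run so outputs are reproducible from the sidecar alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import CompetitionSummary, RunRecord, SimulationConfig, SweepSummary
from .landscape import FitnessGrid
from .population import Organism, assign_mates
from .species import find_clusters

__all__ = [
    "write_series_csv",
    "write_sweep_csv",
    "write_competition_csv",
    "write_snapshot_csv",
    "write_partition_csv",
    "write_grid_csv",
    "write_sidecar",
    "load_config",
    "read_snapshot_csv",
    "partitions_from_snapshot",
]


def write_series_csv(record: RunRecord, path) -> Path:
    path = Path(path)
    record.series.to_csv(path, index=False)
    return path


def write_sweep_csv(summary: SweepSummary, path) -> Path:
    path = Path(path)
    summary.table.to_csv(path, index=False)
    return path


def write_competition_csv(
    summary: CompetitionSummary, path, bins: int = 20
) -> Path:
    """Histogram of mu carriers per recorded generation:
    ``generation,mu_bin_left,count`` rows with ``bins`` equal bins on [0, 1]."""
    edges = np.linspace(0.0, 1.0, bins + 1)
    rows = []
    for gen in sorted(summary.mu_snapshots):
        counts, _ = np.histogram(summary.mu_snapshots[gen], bins=edges)
        for left, count in zip(edges[:-1], counts):
            rows.append(
                {"generation": gen, "mu_bin_left": round(float(left), 10), "count": int(count)}
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_snapshot_csv(record: RunRecord, path) -> Path:
    """Organism snapshot table ``generation,id,x,y,mu,labeled``."""
    if record.snapshots is None:
        raise ValueError("run was not configured to record snapshots")
    path = Path(path)
    record.snapshots.to_csv(path, index=False)
    return path


def write_partition_csv(partitions, path) -> Path:
    """``generation,id,cluster`` rows for one or more cluster partitions."""
    try:
        iter(partitions)
    except TypeError:
        partitions = [partitions]
    rows = [
        {"generation": p.generation, "id": oid, "cluster": lab}
        for p in partitions
        for oid, lab in sorted(p.assignment.items())
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_grid_csv(grid: FitnessGrid, path, generation: int = 0) -> Path:
    """Coarse grid as ``generation,row,col,value`` rows."""
    n = grid.values.shape[0]
    rows = [
        {
            "generation": generation,
            "row": r,
            "col": c,
            "value": grid.values[r, c],
        }
        for r in range(n)
        for c in range(n)
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_sidecar(config: SimulationConfig, seed, path, **extra) -> Path:
    """JSON sidecar with the full configuration, seed and any extra metadata."""
    payload = {"config": config.to_dict(), "seed": seed, **extra}
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path


def load_config(path) -> SimulationConfig:
    """Load a YAML configuration file (nested landscape/reproduction/run keys)."""
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh) or {})


def read_snapshot_csv(path) -> pd.DataFrame:
    """Read an organism snapshot table; requires generation, id, x, y."""
    df = pd.read_csv(path)
    missing = {"generation", "id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"snapshot table lacks columns: {sorted(missing)}")
    return df


def partitions_from_snapshot(df: pd.DataFrame):
    """Run the species measurement layer on a snapshot table.

    Yields one :class:`~speciesim.species.ClusterPartition` per generation;
    generations with a single organism form one singleton cluster.
    """
    for gen, sub in df.groupby("generation", sort=True):
        organisms = [
            Organism(id=int(r.id), coords=(float(r.x), float(r.y)))
            for r in sub.itertuples()
        ]
        mates = assign_mates(organisms) if len(organisms) > 1 else None
        yield find_clusters(organisms, mates, generation=int(gen))
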