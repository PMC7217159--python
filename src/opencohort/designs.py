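"""Trial design schematics for longitudinal cluster randomized trials.

A design is a binary sequences-by-periods treatment schematic together with
the number of clusters following each sequence and the (constant) number of
participants measured per cluster-period.  Periods are discrete and indexed
1..T in all user-facing I/O.
"""

from __future__ import annotations

import json
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidDesignError

__all__ = [
    "TrialDesign",
    "stepped_wedge",
    "parallel_design",
    "cluster_crossover",
    "expand_to_clusters",
    "design_totals",
    "DesignTotals",
    "read_design",
    "write_design",
]


@dataclass(frozen=True)
class TrialDesign:
    """A longitudinal cluster randomized trial design.

    Parameters
    ----------
    schematic
        S x T matrix of treatment indicators (0 = control, 1 = intervention),
        one row per treatment sequence.
    clusters_per_sequence
        Number of clusters assigned to each sequence (length S, entries >= 1).
    m
        Number of participants measured in each cluster in each period.
    label
        Free-text description.
    """

    schematic: np.ndarray
    clusters_per_sequence: tuple[int, ...]
    m: int
    label: str = ""

    def __post_init__(self) -> None:
        X = np.asarray(self.schematic)
        if X.ndim != 2:
            raise InvalidDesignError("schematic must be a 2-d matrix")
        if not np.isin(X, (0, 1)).all():
            raise InvalidDesignError("schematic entries must be 0 or 1")
        X = X.astype(np.int64)
        X.setflags(write=False)
        object.__setattr__(self, "schematic", X)
        S, T = X.shape
        if T < 2:
            raise InvalidDesignError(f"designs need at least two periods, got T={T}")
        if S < 1:
            raise InvalidDesignError("designs need at least one sequence")
        cps = tuple(int(c) for c in self.clusters_per_sequence)
        if len(cps) != S:
            raise InvalidDesignError(
                f"clusters_per_sequence has length {len(cps)}, expected {S}"
            )
        if any(c < 1 for c in cps):
            raise InvalidDesignError("every sequence needs at least one cluster")
        object.__setattr__(self, "clusters_per_sequence", cps)
        if int(self.m) < 1:
            raise InvalidDesignError("cluster-period size m must be >= 1")
        object.__setattr__(self, "m", int(self.m))

    @property
    def n_sequences(self) -> int:
        return self.schematic.shape[0]

    @property
    def n_periods(self) -> int:
        return self.schematic.shape[1]

    @property
    def n_clusters(self) -> int:
        """Total number of clusters K."""
        return sum(self.clusters_per_sequence)

    def with_clusters_per_sequence(self, clusters_per_sequence) -> "TrialDesign":
        """Return a copy with a different cluster allocation."""
        return TrialDesign(self.schematic, tuple(clusters_per_sequence), self.m, self.label)


def stepped_wedge(n_sequences: int, clusters_per_sequence=None, m: int = 1,
                  label: str = "stepped wedge") -> TrialDesign:
    """Construct the standard stepped wedge design with T = S + 1 periods.

    Sequence s (1-based) switches from control to intervention after period s:
    X_st = 1 for t > s, 0 otherwise.  All clusters start in the control
    condition and all finish in the intervention condition.
    """
    S = int(n_sequences)
    if S < 2:
        raise InvalidDesignError("a stepped wedge needs at least two sequences")
    T = S + 1
    t = np.arange(1, T + 1)
    s = np.arange(1, S + 1)
    X = (t[None, :] > s[:, None]).astype(int)
    if clusters_per_sequence is None:
        clusters_per_sequence = (1,) * S
    return TrialDesign(X, tuple(clusters_per_sequence), m, label)


def parallel_design(n_periods: int, clusters_per_arm: tuple[int, int] = (1, 1),
                    m: int = 1, label: str = "parallel") -> TrialDesign:
    """Two-sequence parallel design measured over ``n_periods`` periods:
    one arm always treated, the other never."""
    T = int(n_periods)
    X = np.vstack([np.ones(T, dtype=int), np.zeros(T, dtype=int)])
    return TrialDesign(X, tuple(clusters_per_arm), m, label)


def cluster_crossover(clusters_per_sequence: tuple[int, int] = (1, 1),
                      m: int = 1, label: str = "cluster crossover") -> TrialDesign:
    """Two-period, two-sequence cluster crossover (AB / BA)."""
    X = np.array([[0, 1], [1, 0]])
    return TrialDesign(X, tuple(clusters_per_sequence), m, label)


def expand_to_clusters(design: TrialDesign) -> np.ndarray:
    """Expand the schematic to a K x T matrix with one row per cluster.

    Sequence rows are repeated ``clusters_per_sequence[s]`` times, preserving
    sequence order then cluster order (sequence-major, stable).
    """
    return np.repeat(design.schematic, design.clusters_per_sequence, axis=0)


DesignTotals = namedtuple("DesignTotals", ["grand", "per_period", "per_cluster"])


def design_totals(Xc: np.ndarray) -> DesignTotals:
    """Grand, per-period (column) and per-cluster (row) totals of a binary
    cluster-by-period treatment matrix; the ingredients of the design effect."""
    Xc = np.asarray(Xc)
    return DesignTotals(
        grand=int(Xc.sum()),
        per_period=Xc.sum(axis=0).astype(int),
        per_cluster=Xc.sum(axis=1).astype(int),
    )


def write_design(design: TrialDesign, csv_path, config_path=None) -> None:
    """Write the schematic as CSV (columns period_1..period_T, one row per
    sequence) plus an optional JSON/YAML sidecar with the cluster allocation
    and cluster-period size."""
    T = design.n_periods
    df = pd.DataFrame(design.schematic, columns=[f"period_{t}" for t in range(1, T + 1)])
    df.to_csv(csv_path, index=False)
    if config_path is not None:
        meta = {
            "clusters_per_sequence": list(design.clusters_per_sequence),
            "m": design.m,
            "label": design.label,
        }
        config_path = Path(config_path)
        with open(config_path, "w") as fh:
            if config_path.suffix in (".yml", ".yaml"):
                yaml.safe_dump(meta, fh)
            else:
                json.dump(meta, fh, indent=2)


def read_design(csv_path, config_path=None, clusters_per_sequence=None,
                m=None, label="") -> TrialDesign:
    """Read a schematic CSV (as written by :func:`write_design`).

    Cluster allocation and m come from the sidecar config if given, and may be
    overridden by the keyword arguments.
    """
    df = pd.read_csv(csv_path)
    cols = [c for c in df.columns if c.startswith("period_")]
    if not cols:
        raise InvalidDesignError("schematic CSV must have period_1..period_T columns")
    X = df[cols].to_numpy()
    if config_path is not None:
        with open(config_path) as fh:
            meta = yaml.safe_load(fh)  # YAML is a superset of JSON
        clusters_per_sequence = clusters_per_sequence or meta.get("clusters_per_sequence")
        m = m or meta.get("m")
        label = label or meta.get("label", "")
    if clusters_per_sequence is None:
        clusters_per_sequence = (1,) * X.shape[0]
    if m is None:
        m = 1
    return TrialDesign(X, tuple(clusters_per_sequence), m, label)
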