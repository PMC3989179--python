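"""Barcode-gap discovery and recursive single-linkage partitioning.

A "barcode gap" is a discontinuity in the ranked distribution of pairwise
genetic distances separating intraspecific from interspecific comparisons.
Given a prior maximum intraspecific divergence P, the scan walks the sorted
distinct distances d(1) <= d(2) <= ... and looks for the first rank i with
d(i) >= P whose gap g(i) = d(i+1) - d(i) is significant.  The operational
significance test used here is

    g(i) > X * w(i)   and   g(i) > d(i)

where w(i) is the mean of the preceding min(W, i-1) gaps (for the first gap,
the mean of all other gaps) and X is the relative gap width.  The second
condition requires a qualifying gap to at least double the distance at which
it occurs — a genuine change of divergence scale, in line with the empirical
observation that interspecific divergences run >= 2.5x intraspecific ones —
which keeps sampling jitter inside a dense intraspecific cloud from being
read as structure.

Haplotypes are then partitioned by single linkage: connected components of the
graph joining pairs at or below d(significant_index).  The procedure recurses
inside every resulting group, and the whole analysis is swept over a geometric
series of priors from Pmin to Pmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .k2p import DistanceMatrix

__all__ = [
    "InsufficientVariationError",
    "SweepConfig",
    "GapScan",
    "Partition",
    "SweepResult",
    "priors",
    "find_significant_gap",
    "partition_once",
    "abgd_partition",
    "prior_sweep",
    "sweep_table",
    "distance_histogram",
]


class InsufficientVariationError(ValueError):
    """Fewer than two distinct distance values: no gap can be sought."""


@dataclass(frozen=True)
class SweepConfig:
    """Settings of the prior sweep.

    pmin, pmax
        Smallest/largest prior maximum intraspecific divergence; priors are
        spaced geometrically (the defaults span two orders of magnitude).
    steps
        Number of priors (>= 4; the stability rule needs runs of three).
    x
        Relative gap width: a candidate gap must exceed ``x`` times the local
        gap scale.
    bins
        Histogram bin count for the diagnostic pairwise-distance histogram.
    window
        Number of preceding gaps over which the local gap scale is averaged.
    degenerate_mean
        A dataset whose mean pairwise distance does not exceed this value has
        too little variation for gap-based delimitation and is flagged
        degenerate (treated as a single species).
    """

    pmin: float = 0.001
    pmax: float = 0.2
    steps: int = 20
    x: float = 1.5
    bins: int = 20
    window: int = 10
    degenerate_mean: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.pmin < self.pmax < 1.0):
            raise ValueError("require 0 < pmin < pmax < 1")
        if self.steps < 4:
            raise ValueError("steps must be >= 4 (stability needs runs of 3)")
        if self.x <= 0:
            raise ValueError("relative gap width x must be positive")
        if self.window < 1:
            raise ValueError("window must be >= 1")


def priors(config: SweepConfig) -> np.ndarray:
    """Geometric series of priors P_k = pmin * (pmax/pmin)^(k/(steps-1))."""
    k = np.arange(config.steps)
    return config.pmin * (config.pmax / config.pmin) ** (k / (config.steps - 1))


@dataclass
class GapScan:
    """Result of one gap search over sorted distinct distances."""

    distances: np.ndarray  # sorted distinct values
    prior: float
    significant_index: int | None  # 0-based rank of the last pre-gap distance
    threshold: float | None  # d[significant_index]; connect pairs <= threshold

    @property
    def found(self) -> bool:
        return self.significant_index is not None


@dataclass
class Partition:
    """Assignment of every haplotype to exactly one group (ids 1..n_groups)."""

    assignment: dict[str, int]

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def groups(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for label, g in self.assignment.items():
            out.setdefault(g, set()).add(label)
        return {g: frozenset(v) for g, v in out.items()}

    def refines(self, other: "Partition") -> bool:
        """True iff every group of self is a subset of one group of other."""
        other_of = other.assignment
        rep: dict[int, int] = {}
        for label, g in self.assignment.items():
            og = other_of[label]
            if rep.setdefault(g, og) != og:
                return False
        return True

    @staticmethod
    def from_components(labels: Sequence[str], comp: np.ndarray) -> "Partition":
        """Relabel raw component indices to contiguous ids 1.. ordered by the
        smallest contained haplotype index (deterministic tie rule)."""
        first_seen: dict[int, int] = {}
        for c in comp:
            if int(c) not in first_seen:
                first_seen[int(c)] = len(first_seen) + 1
        return Partition({l: first_seen[int(c)] for l, c in zip(labels, comp)})


def find_significant_gap(
    values: np.ndarray | Sequence[float], prior: float, config: SweepConfig | None = None
) -> GapScan:
    """Locate the first significant gap at or above the prior.

    ``values`` are pairwise distances (duplicates allowed; distinct sorted
    values are scanned).  Raises :class:`InsufficientVariationError` when
    fewer than two distinct values exist.
    """
    config = config or SweepConfig()
    vals = np.unique(np.asarray(values, dtype=float))
    if vals.size < 2:
        raise InsufficientVariationError(
            f"only {vals.size} distinct distance value(s)"
        )
    gaps = np.diff(vals)
    for i in range(gaps.size):
        if vals[i] < prior:
            continue
        if i == 0:
            others = gaps[1:]
            w = float(others.mean()) if others.size else 0.0
        else:
            w = float(gaps[max(0, i - config.window) : i].mean())
        if gaps[i] > config.x * w and gaps[i] > vals[i]:
            return GapScan(
                distances=vals,
                prior=prior,
                significant_index=i,
                threshold=float(vals[i]),
            )
    return GapScan(distances=vals, prior=prior, significant_index=None, threshold=None)


def partition_once(dm: DistanceMatrix, threshold: float) -> Partition:
    """Single-linkage partition: connected components joining pairs with
    d <= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = csr_matrix(dm.d <= threshold)
    _, comp = connected_components(adj, directed=False)
    return Partition.from_components(dm.labels, comp)


def _recursive_split(
    dm: DistanceMatrix, members: list[int], prior: float, config: SweepConfig
) -> list[list[int]]:
    """Re-run gap-find/partition inside a group; returns final leaf groups."""
    if len(members) <= 2:
        # a gap needs >= 2 distinct distances; pairs and singletons never split
        return [members]
    sub = dm.d[np.ix_(members, members)]
    vals = sub[np.triu_indices(len(members), k=1)]
    try:
        scan = find_significant_gap(vals, prior, config)
    except InsufficientVariationError:
        return [members]
    if not scan.found:
        return [members]
    adj = csr_matrix(sub <= scan.threshold)
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp <= 1:
        return [members]
    children: dict[int, list[int]] = {}
    for local, c in enumerate(comp):
        children.setdefault(int(c), []).append(members[local])
    out: list[list[int]] = []
    for child in children.values():
        out.extend(_recursive_split(dm, child, prior, config))
    return out


def abgd_partition(
    dm: DistanceMatrix, prior: float, config: SweepConfig | None = None
) -> tuple[Partition, Partition]:
    """One gap-find/partition pass on the whole matrix (initial) plus repeated
    re-partitioning within every group until nothing splits (recursive).

    "Insufficient variation" inside a group is a no-split outcome, not an
    exception; if the whole dataset lacks variation the single-group partition
    is returned for both.
    """
    config = config or SweepConfig()
    labels = dm.labels
    one_group = Partition({l: 1 for l in labels})
    try:
        scan = find_significant_gap(dm.condensed(), prior, config)
    except InsufficientVariationError:
        return one_group, one_group
    if not scan.found:
        return one_group, one_group
    initial = partition_once(dm, scan.threshold)
    leaf_groups: list[list[int]] = []
    for gid, group_labels in sorted(initial.groups().items()):
        members = sorted(labels.index(l) for l in group_labels)
        leaf_groups.extend(_recursive_split(dm, members, prior, config))
    # group ids ordered by smallest contained haplotype index
    leaf_groups.sort(key=min)
    assignment: dict[str, int] = {}
    for gid, members in enumerate(leaf_groups, start=1):
        for idx in members:
            assignment[labels[idx]] = gid
    return initial, Partition(assignment)


@dataclass
class SweepResult:
    """Initial and recursive partitions at every prior of the sweep."""

    priors: np.ndarray
    initial: list[Partition]
    recursive: list[Partition]
    labels: list[str]
    degenerate: bool = False

    def __len__(self) -> int:
        return len(self.priors)

    def counts(self) -> list[tuple[float, int, int]]:
        return [
            (float(p), i.n_groups, r.n_groups)
            for p, i, r in zip(self.priors, self.initial, self.recursive)
        ]

    def to_json(self) -> str:
        return json.dumps(
            {
                "degenerate": self.degenerate,
                "sweep": [
                    {"prior": p, "n_initial": ni, "n_recursive": nr}
                    for p, ni, nr in self.counts()
                ],
            },
            indent=2,
        )


def prior_sweep(dm: DistanceMatrix, config: SweepConfig | None = None) -> SweepResult:
    """Evaluate :func:`abgd_partition` at every prior of the geometric series.

    Datasets with fewer than two distinct distances, or whose mean pairwise
    distance is at or below ``config.degenerate_mean`` (too little variation
    for gap-based delimitation), are flagged degenerate and returned as a
    single group at every prior.
    """
    config = config or SweepConfig()
    ps = priors(config)
    vals = dm.condensed()
    if np.unique(vals).size < 2 or float(vals.mean()) <= config.degenerate_mean:
        one = Partition({l: 1 for l in dm.labels})
        return SweepResult(
            priors=ps,
            initial=[one] * config.steps,
            recursive=[one] * config.steps,
            labels=list(dm.labels),
            degenerate=True,
        )
    initial: list[Partition] = []
    recursive: list[Partition] = []
    for p in ps:
        ini, rec = abgd_partition(dm, float(p), config)
        initial.append(ini)
        recursive.append(rec)
    return SweepResult(
        priors=ps, initial=initial, recursive=recursive, labels=list(dm.labels)
    )


def sweep_table(sweep: SweepResult) -> pd.DataFrame:
    """Tidy table: one row per prior with initial/recursive group counts."""
    return pd.DataFrame(
        sweep.counts(), columns=["prior", "n_initial", "n_recursive"]
    )


def distance_histogram(
    dm: DistanceMatrix, config: SweepConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Diagnostic histogram of pairwise distances (counts, bin edges), the
    usual visual companion to a gap scan."""
    config = config or SweepConfig()
    return np.histogram(dm.condensed(), bins=config.bins)
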