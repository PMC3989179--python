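"""Stability-based selection of a primary species hypothesis (PSH).

A prior sweep yields one partition per prior; very small priors oversplit and
very large ones lump everything.  The selection rule picks the smallest number
of groups that is stable over three or more successive priors.  Where the
initial and recursive partitions disagree at a prior, the smaller count (and
its partition) is used.  The trivial all-in-one count of 1 — which every
dataset reaches at large priors — is excluded from the candidates unless it is
the only stable count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

from .barcode_gap import Partition, SweepResult

__all__ = [
    "NoStablePSHError",
    "PriorCount",
    "StableRun",
    "PSHSelection",
    "per_prior_count",
    "select_psh",
]


class NoStablePSHError(ValueError):
    """No group count is stable over the required number of successive priors."""


@dataclass(frozen=True)
class PriorCount:
    prior: float
    count: int
    partition: Partition


@dataclass(frozen=True)
class StableRun:
    """A maximal run of consecutive priors sharing one group count."""

    count: int
    start: int  # index into the sweep
    length: int
    priors: tuple[float, ...]


@dataclass
class PSHSelection:
    """The chosen primary species hypothesis.

    ``stable_prior_max`` is the largest prior of the chosen stable run — the
    "maximum prior intraspecific divergence over which stable".  The reported
    partition is the one at the run's smallest prior.  ``alternatives`` lists
    the other qualifying stable counts.
    """

    chosen_count: int
    stable_prior_max: float | None
    stable_prior_min: float | None
    chosen_partition: Partition
    run: StableRun | None
    alternatives: list[StableRun]
    degenerate: bool = False
    trivial_count_excluded: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "chosen_count": self.chosen_count,
                "stable_prior_max": self.stable_prior_max,
                "run_priors": list(self.run.priors) if self.run else [],
                "alternatives": [
                    {"count": r.count, "priors": list(r.priors)}
                    for r in self.alternatives
                ],
                "degenerate": self.degenerate,
                "trivial_count_excluded": self.trivial_count_excluded,
            },
            indent=2,
        )


def per_prior_count(sweep: SweepResult) -> list[PriorCount]:
    """Group count per prior: the smaller of the initial and recursive counts,
    carrying the partition that attains it (order of priors preserved)."""
    out = []
    for p, ini, rec in zip(sweep.priors, sweep.initial, sweep.recursive):
        if ini.n_groups <= rec.n_groups:
            out.append(PriorCount(float(p), ini.n_groups, ini))
        else:
            out.append(PriorCount(float(p), rec.n_groups, rec))
    return out


def _maximal_runs(counts: Sequence[PriorCount]) -> list[StableRun]:
    runs: list[StableRun] = []
    start = 0
    for i in range(1, len(counts) + 1):
        if i == len(counts) or counts[i].count != counts[start].count:
            runs.append(
                StableRun(
                    count=counts[start].count,
                    start=start,
                    length=i - start,
                    priors=tuple(c.prior for c in counts[start:i]),
                )
            )
            start = i
    return runs


def select_psh(sweep: SweepResult, min_run: int = 3) -> PSHSelection:
    """Apply the stability criterion to a sweep.

    Among counts whose maximal run spans at least ``min_run`` successive
    priors, return the smallest (excluding the trivial count 1 unless nothing
    else qualifies); ties on count go to the run starting at the lower prior.
    Degenerate sweeps (too little variation to analyse) yield a flagged
    single-species selection.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if len(sweep) < min_run:
        raise NoStablePSHError(
            f"sweep has {len(sweep)} priors but min_run={min_run}"
        )
    if sweep.degenerate:
        return PSHSelection(
            chosen_count=1,
            stable_prior_max=None,
            stable_prior_min=None,
            chosen_partition=sweep.initial[0],
            run=None,
            alternatives=[],
            degenerate=True,
        )
    counts = per_prior_count(sweep)
    runs = _maximal_runs(counts)
    qualifying = [r for r in runs if r.length >= min_run]
    if not qualifying:
        raise NoStablePSHError(
            "no group count is stable over "
            f"{min_run} or more successive priors"
        )
    nontrivial = [r for r in qualifying if r.count != 1]
    trivial_excluded = bool(nontrivial) and len(nontrivial) < len(qualifying)
    candidates = nontrivial or qualifying
    # smallest count wins; ties go to the earlier (lower-prior) run
    chosen = min(candidates, key=lambda r: (r.count, r.start))
    alternatives = [r for r in qualifying if r is not chosen]
    return PSHSelection(
        chosen_count=chosen.count,
        stable_prior_max=chosen.priors[-1],
        stable_prior_min=chosen.priors[0],
        chosen_partition=counts[chosen.start].partition,
        run=chosen,
        alternatives=alternatives,
        trivial_count_excluded=trivial_excluded,
    )
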