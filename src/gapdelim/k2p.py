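"""Kimura two-parameter (K2P) distances with pairwise deletion.

For a pair of aligned sequences let P be the proportion of compared sites with
a transition (A<->G, C<->T) and Q the proportion with a transversion.  The K2P
distance is

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

Sites where either sequence carries a gap or an ambiguity code are excluded for
that pair only (pairwise deletion), so each pair has its own ``sites_used``.
Pairs whose logarithm argument is non-positive are saturated: they are flagged
rather than clamped, and a matrix containing any flagged pair is refused by the
downstream modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import Alignment, HaplotypeSet

__all__ = [
    "DistanceError",
    "NoComparableSitesError",
    "SaturationError",
    "PairDistance",
    "DistanceMatrix",
    "encode",
    "k2p_pair",
    "k2p_from_proportions",
    "distance_matrix",
    "group_distance_summary",
]


class DistanceError(ValueError):
    """Base class for distance-computation failures."""


class NoComparableSitesError(DistanceError):
    """A pair shares no site at which both sequences have an unambiguous base."""


class SaturationError(DistanceError):
    """The K2P logarithm is undefined (too many differences for the model)."""


# A,C,G,T -> 0..3; everything else (gaps, IUPAC ambiguity codes) is missing.
_MISSING = np.uint8(255)
_LUT = np.full(256, _MISSING, dtype=np.uint8)
for _base, _code in zip(b"ACGT", range(4)):
    _LUT[_base] = _code
    _LUT[_base + 32] = _code  # lowercase


def encode(seq: str) -> np.ndarray:
    """Encode a sequence row as uint8 codes (A=0, C=1, G=2, T=3, missing=255)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PairDistance:
    """K2P distance for one sequence pair.

    ``saturated`` pairs carry ``d = nan``; they are reported, never clamped.
    """

    d: float
    P: float
    Q: float
    sites_used: int
    saturated: bool = False


def k2p_from_proportions(P: float, Q: float) -> float:
    """Closed-form K2P distance from transition/transversion proportions.

    Returns ``nan`` when the logarithm argument is non-positive (saturation).
    """
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return math.nan
    return -0.5 * math.log(a * math.sqrt(b))


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(transitions, transversions, sites_used) under pairwise deletion."""
    ok = (a != _MISSING) & (b != _MISSING)
    n = int(ok.sum())
    if n == 0:
        return 0, 0, 0
    aa, bb = a[ok], b[ok]
    diff = aa != bb
    # transitions stay within purines {A=0, G=2} or pyrimidines {C=1, T=3}:
    # codes share parity exactly for transitions.
    ts = int((diff & ((aa & 1) == (bb & 1))).sum())
    tv = int(diff.sum()) - ts
    return ts, tv, n


def k2p_pair(a: str | np.ndarray, b: str | np.ndarray) -> PairDistance:
    """K2P distance between two equal-length rows with pairwise deletion."""
    ea = encode(a) if isinstance(a, str) else a
    eb = encode(b) if isinstance(b, str) else b
    if ea.shape != eb.shape:
        raise DistanceError("sequences have different lengths")
    ts, tv, n = _pair_counts(ea, eb)
    if n == 0:
        raise NoComparableSitesError("no comparable sites for this pair")
    P, Q = ts / n, tv / n
    d = k2p_from_proportions(P, Q)
    if math.isnan(d):
        return PairDistance(d=math.nan, P=P, Q=Q, sites_used=n, saturated=True)
    return PairDistance(d=d, P=P, Q=Q, sites_used=n)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix over haplotype (or specimen) labels."""

    labels: list[str]
    d: np.ndarray
    sites_used: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DistanceError("matrix shape does not match labels")

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.d[iu]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=list(labels),
            d=self.d[np.ix_(idx, idx)],
            sites_used=self.sites_used[np.ix_(idx, idx)],
        )

    def to_skbio(self):
        from skbio import DistanceMatrix as SkbioDM

        return SkbioDM(self.d, ids=self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip_lower(self, path: str | Path) -> None:
        """PHYLIP-style lower-triangle export for external tree tools."""
        lines = [f"{len(self.labels)}"]
        for i, label in enumerate(self.labels):
            row = " ".join(f"{self.d[i, j]:.6f}" for j in range(i))
            lines.append(f"{label:<12s} {row}".rstrip())
        Path(path).write_text("\n".join(lines) + "\n")


def _pairwise_encoded(
    enc: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, str]]]:
    """All-pairs K2P on an (n, L) encoded matrix.

    Returns (d, sites_used, problems); problems lists (i, j, reason) for pairs
    that are saturated or share no comparable sites.
    """
    n = enc.shape[0]
    d = np.zeros((n, n), dtype=float)
    sites = np.full((n, n), enc.shape[1], dtype=int)
    problems: list[tuple[int, int, str]] = []
    valid = enc != _MISSING
    parity = enc & 1
    for i in range(n):
        ok_i = valid[i]
        for j in range(i + 1, n):
            ok = ok_i & valid[j]
            m = int(ok.sum())
            sites[i, j] = sites[j, i] = m
            if m == 0:
                problems.append((i, j, "no comparable sites"))
                d[i, j] = d[j, i] = math.nan
                continue
            diff = ok & (enc[i] != enc[j])
            ts = int((diff & (parity[i] == parity[j])).sum())
            tv = int(diff.sum()) - ts
            val = k2p_from_proportions(ts / m, tv / m)
            if math.isnan(val):
                problems.append((i, j, "K2P undefined (saturation)"))
            d[i, j] = d[j, i] = val
    return d, sites, problems


def distance_matrix(data: HaplotypeSet | Alignment) -> DistanceMatrix:
    """Full symmetric K2P matrix over a haplotype set or alignment.

    Raises :class:`SaturationError` (naming the offending pairs) if any pair is
    saturated or has no comparable sites — downstream gap detection refuses
    flagged matrices rather than working with clamped values.
    """
    if isinstance(data, HaplotypeSet):
        labels, seqs = list(data.ids), data.sequences
    else:
        labels, seqs = list(data.ids), data.sequences
    if len(labels) < 2:
        raise DistanceError("need at least 2 sequences for a distance matrix")
    enc = np.vstack([encode(s) for s in seqs])
    d, sites, problems = _pairwise_encoded(enc)
    if problems:
        desc = "; ".join(
            f"{labels[i]}~{labels[j]}: {reason}" for i, j, reason in problems[:10]
        )
        raise SaturationError(f"undefined distances for {len(problems)} pair(s): {desc}")
    return DistanceMatrix(labels=labels, d=d, sites_used=sites)


def group_distance_summary(
    dm: DistanceMatrix, partition: Mapping[str, int]
) -> pd.DataFrame:
    """Per-group mean intra- and minimum mean inter-group K2P distances.

    One row per group: ``mean_intra`` (NaN for singleton groups, flagged in
    ``intra_defined``), the minimum over other groups of the mean pairwise
    distance to that group (``min_mean_inter``) with the group attaining it,
    and the ratio ``min_mean_inter / mean_intra``.
    """
    missing = [l for l in dm.labels if l not in partition]
    if missing:
        raise DistanceError(f"partition does not cover labels: {missing[:10]}")
    groups: dict[int, list[int]] = {}
    for i, label in enumerate(dm.labels):
        groups.setdefault(partition[label], []).append(i)
    gids = sorted(groups)
    rows = []
    for g in gids:
        idx = groups[g]
        if len(idx) > 1:
            sub = dm.d[np.ix_(idx, idx)]
            intra = float(sub[np.triu_indices(len(idx), k=1)].mean())
        else:
            intra = math.nan
        best, best_g = math.inf, None
        for h in gids:
            if h == g:
                continue
            inter = float(dm.d[np.ix_(idx, groups[h])].mean())
            if inter < best:
                best, best_g = inter, h
        min_inter = best if best_g is not None else math.nan
        ratio = (
            min_inter / intra
            if not math.isnan(intra) and intra > 0 and not math.isnan(min_inter)
            else math.nan
        )
        rows.append(
            {
                "group": g,
                "n_members": len(idx),
                "mean_intra": intra,
                "intra_defined": len(idx) > 1,
                "min_mean_inter": min_inter,
                "nearest_group": best_g,
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows)
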