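"""Shared builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk except
the package's own reference tables.
"""

from __future__ import annotations

import numpy as np
import pytest

from gapdelim import Alignment, DistanceMatrix, SpecimenRecord


def make_alignment(seqs, ids=None, locus="mtCOI", morph=None) -> Alignment:
    ids = ids or [f"s{i+1}" for i in range(len(seqs))]
    morph = morph or ["unknown"] * len(seqs)
    recs = [
        SpecimenRecord(
            specimen_id=i, morphospecies_label=m, locality="loc", locus=locus
        )
        for i, m in zip(ids, morph)
    ]
    return Alignment(recs, list(seqs))


def dm_from_array(arr, labels=None) -> DistanceMatrix:
    arr = np.asarray(arr, dtype=float)
    labels = labels or [f"H{i+1}" for i in range(arr.shape[0])]
    return DistanceMatrix(
        labels=list(labels), d=arr, sites_used=np.full(arr.shape, 100, dtype=int)
    )


def clustered_dm(
    sizes, within, between, jitter=0.0, rng=None, labels=None
) -> tuple[DistanceMatrix, dict[str, int]]:
    """Block distance matrix: ``within`` inside each cluster, ``between``
    across clusters, optional uniform jitter.  Returns (matrix, truth)."""
    rng = rng or np.random.default_rng(0)
    n = sum(sizes)
    cluster = np.repeat(np.arange(len(sizes)), sizes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            base = within if cluster[i] == cluster[j] else between
            val = base + (rng.uniform(-jitter, jitter) if jitter else 0.0)
            d[i, j] = d[j, i] = max(val, 0.0)
    dm = dm_from_array(d, labels)
    truth = {dm.labels[i]: int(cluster[i]) + 1 for i in range(n)}
    return dm, truth


def random_distance_matrix(rng, n, scale=1.0) -> DistanceMatrix:
    d = rng.uniform(0, scale, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return dm_from_array(d)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
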