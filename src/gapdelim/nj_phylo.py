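"""Neighbour-joining trees, midpoint rooting, monophyly, and bootstraps.

Putative species that survive delimitation must also show evidence of
reciprocal monophyly with respect to a sister group.  Trees are built by
standard Saitou–Nei neighbour joining on K2P distances (via scikit-bio, with
negative branch lengths clamped to zero), displayed midpoint-rooted, and a
group's support is the percentage of column-resampling bootstrap replicates in
which it forms one side of a bipartition.  Support attaches to bipartitions,
not nodes, so it is rooting-invariant.  Bayesian posterior columns consumed by
the refinement stage are external fixture evidence; no MCMC is run here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skbio.tree import TreeNode, nj as _skbio_nj

from .alignment_io import Alignment, HaplotypeSet
from .k2p import DistanceMatrix, _pairwise_encoded, encode

__all__ = [
    "TreeError",
    "SupportRecord",
    "nj_tree",
    "midpoint_root",
    "is_monophyletic",
    "bipartitions",
    "bootstrap_support",
    "read_newick",
    "write_newick",
]


class TreeError(ValueError):
    pass


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree from a K2P distance matrix.

    Deterministic given input order; refuses matrices containing undefined
    (NaN) entries.  The returned tree is unrooted (trifurcating root node).
    """
    if len(dm) < 3:
        raise TreeError("neighbour joining needs at least 3 labels")
    if np.isnan(dm.d).any():
        raise TreeError("distance matrix contains undefined (flagged) entries")
    return _skbio_nj(dm.to_skbio())


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Zero-diameter trees (all branch lengths 0) cannot define a midpoint; the
    tree is returned rooted as-is.  Already-midpoint-rooted input is unchanged
    up to its branch decomposition (idempotent).
    """
    t = tree.copy()
    lengths = [n.length or 0.0 for n in t.traverse() if n.length is not None]
    if not lengths or max(lengths) == 0.0:
        return t
    tips = list(t.tips())
    if len(tips) == 2:
        # degenerate two-leaf tree: split the single path evenly
        half = sum(n.length or 0.0 for n in t.traverse() if n.length) / 2.0
        root = TreeNode()
        for tip in tips:
            child = TreeNode(name=tip.name, length=half)
            root.append(child)
        return root
    return t.root_at_midpoint()


def _clades(tree: TreeNode) -> list[frozenset[str]]:
    """Leaf sets of every node (postorder), computed once per tree."""
    sets: dict[int, frozenset[str]] = {}
    out = []
    for node in tree.postorder():
        if node.is_tip():
            s = frozenset([node.name])
        else:
            s = frozenset().union(*(sets[id(c)] for c in node.children))
        sets[id(node)] = s
        out.append(s)
    return out


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """All bipartitions of the unrooted tree, each encoded by the smaller-or-
    canonical side containing the leaf sets of every edge."""
    leaves = frozenset(n.name for n in tree.tips())
    parts: set[frozenset[str]] = set()
    for clade in _clades(tree):
        if 0 < len(clade) < len(leaves):
            parts.add(min(clade, leaves - clade, key=sorted))
    return parts


def is_monophyletic(tree: TreeNode, group: Iterable[str]) -> bool:
    """Unrooted clan test: true iff the group is exactly one side of some
    bipartition of the tree.

    Singleton groups are trivially monophyletic.  A group equal to, or not a
    subset of, the full leaf set is rejected.
    """
    group = frozenset(group)
    leaves = frozenset(n.name for n in tree.tips())
    if not group or not group <= leaves:
        raise TreeError("group must be a non-empty subset of the leaf set")
    if group == leaves:
        raise TreeError("group must be a proper subset of the leaf set")
    if len(group) == 1:
        return True
    complement = leaves - group
    for clade in _clades(tree):
        if clade == group or clade == complement:
            return True
    return False


@dataclass
class SupportRecord:
    """Bootstrap support for one group (bipartition).

    ``bi_posterior_percent`` is a slot for externally supplied Bayesian
    posterior evidence; it is never computed here.
    """

    group: frozenset[str]
    nj_bootstrap_percent: float
    n_replicates_used: int
    n_replicates_dropped: int
    bi_posterior_percent: float | None = None


def bootstrap_support(
    aln: Alignment | HaplotypeSet,
    groups: Sequence[Iterable[str]],
    reps: int = 1000,
    seed: int = 0,
) -> list[SupportRecord]:
    """Column-resampling bootstrap of NJ monophyly.

    For each pseudoreplicate, alignment columns are resampled with
    replacement, K2P distances recomputed with pairwise deletion of the
    resampled columns, an NJ tree built, and each group tested for monophyly.
    Support is the percentage of usable replicates in which the group is
    monophyletic.  Replicates with an undefined distance (saturation or no
    comparable sites) are dropped and counted.
    """
    if isinstance(aln, HaplotypeSet):
        aln = aln.to_alignment()
    labels = aln.ids
    if len(labels) < 3:
        raise TreeError("bootstrap needs at least 3 sequences")
    group_sets = [frozenset(g) for g in groups]
    label_set = set(labels)
    for g in group_sets:
        if not g or not g < label_set:
            raise TreeError(f"group {sorted(g)} is not a proper subset of labels")
    enc = np.vstack([encode(s) for s in aln.sequences])
    L = enc.shape[1]
    rng = np.random.default_rng(seed)
    from skbio import DistanceMatrix as SkbioDM

    hits = np.zeros(len(group_sets), dtype=int)
    dropped = 0
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        d, _, problems = _pairwise_encoded(enc[:, cols])
        if problems:
            dropped += 1
            continue
        tree = _skbio_nj(SkbioDM(d, ids=labels))
        clades = set(_clades(tree))
        leaves = frozenset(labels)
        for k, g in enumerate(group_sets):
            if len(g) == 1 or g in clades or (leaves - g) in clades:
                hits[k] += 1
    used = reps - dropped
    if used == 0:
        raise TreeError("every bootstrap replicate had undefined distances")
    return [
        SupportRecord(
            group=g,
            nj_bootstrap_percent=100.0 * hits[k] / used,
            n_replicates_used=used,
            n_replicates_dropped=dropped,
        )
        for k, g in enumerate(group_sets)
    ]


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
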