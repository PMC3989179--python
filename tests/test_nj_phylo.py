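"""Neighbour joining, midpoint rooting, monophyly, bootstrap support."""

import io
import itertools

import networkx as nx
import numpy as np
import pytest

from gapdelim import (
    bootstrap_support,
    collapse_haplotypes,
    distance_matrix,
    is_monophyletic,
    midpoint_root,
    nj_tree,
    simulate_dataset,
)
from gapdelim.nj_phylo import TreeError, TreeNode, bipartitions, write_newick, read_newick
from gapdelim.synthetic_data import SimConfig

from conftest import dm_from_array, make_alignment


def random_binary_tree(rng, n_leaves):
    """Random unrooted binary tree as a networkx graph with branch lengths.

    Grown by attaching each new leaf to a random existing edge; the generator
    is independent of the NJ implementation under test.
    """
    g = nx.Graph()
    g.add_node("v0")
    for i, leaf in enumerate(["L0", "L1", "L2"]):
        g.add_edge("v0", leaf, weight=float(rng.uniform(0.05, 1.0)))
    for k in range(3, n_leaves):
        u, v = list(g.edges())[int(rng.integers(g.number_of_edges()))]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"v{k}"
        split = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, mid, weight=w * split)
        g.add_edge(mid, v, weight=w * (1 - split))
        g.add_edge(mid, f"L{k}", weight=float(rng.uniform(0.05, 1.0)))
    return g


def tree_facts(g):
    """(labels, distance matrix, nontrivial bipartitions) from the graph."""
    labels = sorted(n for n in g if str(n).startswith("L"))
    paths = dict(nx.all_pairs_dijkstra_path_length(g))
    d = np.array([[paths[a][b] for b in labels] for a in labels])
    d = (d + d.T) / 2.0  # exact symmetry (summation order varies per direction)
    np.fill_diagonal(d, 0.0)
    parts = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(l for l in labels if nx.has_path(h, u, l))
        if 1 < len(side) < len(labels) - 1:
            parts.add(min(side, frozenset(labels) - side, key=sorted))
    return labels, d, parts


class TestNJ:
    def test_three_taxa_solves_three_point_equations(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        t = nj_tree(dm_from_array(d, labels=["a", "b", "c"]))
        # x_a = (d_ab + d_ac - d_bc)/2 etc.
        expect = {"a": 0.1, "b": 0.2, "c": 0.4}
        for tip in t.tips():
            assert tip.length == pytest.approx(expect[tip.name])

    def test_recovers_random_additive_trees(self, rng):
        for n in (4, 5, 6, 7, 8):
            g = random_binary_tree(rng, n)
            labels, d, true_parts = tree_facts(g)
            t = nj_tree(dm_from_array(d, labels=labels))
            got_parts = {p for p in bipartitions(t) if 1 < len(p) < n - 1}
            assert got_parts == true_parts
            tt = t.tip_tip_distances(endpoints=labels)
            assert np.allclose(tt.data, d, atol=1e-9)

    def test_taxon_order_permutation_gives_same_topology(self, rng):
        g = random_binary_tree(rng, 6)
        labels, d, _ = tree_facts(g)
        t1 = nj_tree(dm_from_array(d, labels=labels))
        perm = list(rng.permutation(len(labels)))
        t2 = nj_tree(
            dm_from_array(d[np.ix_(perm, perm)], labels=[labels[i] for i in perm])
        )
        assert bipartitions(t1) == bipartitions(t2)

    def test_refuses_undefined_matrix(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(TreeError):
            nj_tree(dm_from_array(d))

    def test_needs_three_labels(self):
        with pytest.raises(TreeError):
            nj_tree(dm_from_array(np.zeros((2, 2))))


class TestMidpointRoot:
    def test_two_leaves_split_evenly(self):
        t = TreeNode.read(io.StringIO("(a:0.1,b:0.3);"))
        r = midpoint_root(t)
        for tip in r.tips():
            assert tip.distance(r) == pytest.approx(0.2)

    def test_root_depth_is_half_diameter(self, rng):
        g = random_binary_tree(rng, 7)
        labels, d, _ = tree_facts(g)
        r = midpoint_root(nj_tree(dm_from_array(d, labels=labels)))
        diameter = d.max()  # brute force over all leaf pairs
        depths = [tip.distance(r) for tip in r.tips()]
        assert max(depths) == pytest.approx(diameter / 2)

    def test_idempotent(self, rng):
        g = random_binary_tree(rng, 6)
        labels, d, _ = tree_facts(g)
        r1 = midpoint_root(nj_tree(dm_from_array(d, labels=labels)))
        r2 = midpoint_root(r1)
        d1 = {t.name: t.distance(r1) for t in r1.tips()}
        d2 = {t.name: t.distance(r2) for t in r2.tips()}
        assert d1 == pytest.approx(d2)

    def test_zero_diameter_tree_returned_unchanged(self):
        t = TreeNode.read(io.StringIO("(a:0.0,b:0.0,c:0.0);"))
        r = midpoint_root(t)
        assert {x.name for x in r.tips()} == {"a", "b", "c"}


class TestMonophyly:
    def test_edge_side_is_monophyletic_and_complement_too(self):
        t = TreeNode.read(io.StringIO("((a:1,b:1):1,(c:1,d:1):1,e:1);"))
        assert is_monophyletic(t, {"a", "b"})
        assert is_monophyletic(t, {"c", "d", "e"})  # unrooted complement

    def test_interleaved_group_is_not(self):
        t = TreeNode.read(io.StringIO("((a:1,b:1):1,(c:1,d:1):1,e:1);"))
        assert not is_monophyletic(t, {"a", "c"})

    def test_singleton_trivially_monophyletic(self):
        t = TreeNode.read(io.StringIO("((a:1,b:1):1,c:1,d:1);"))
        assert is_monophyletic(t, {"c"})

    def test_full_or_foreign_groups_rejected(self):
        t = TreeNode.read(io.StringIO("((a:1,b:1):1,c:1,d:1);"))
        with pytest.raises(TreeError):
            is_monophyletic(t, {"a", "b", "c", "d"})
        with pytest.raises(TreeError):
            is_monophyletic(t, {"z"})

    def test_agrees_with_exhaustive_edge_enumeration(self, rng):
        for n in (5, 6, 7):
            g = random_binary_tree(rng, n)
            labels, d, _ = tree_facts(g)
            t = nj_tree(dm_from_array(d, labels=labels))
            # independent oracle: clans = edge-removal leaf sets of the graph
            clans = set()
            for u, v in g.edges():
                h = g.copy()
                h.remove_edge(u, v)
                side = frozenset(l for l in labels if nx.has_path(h, u, l))
                clans.add(side)
                clans.add(frozenset(labels) - side)
            for size in range(1, len(labels)):
                for combo in itertools.combinations(labels, size):
                    s = frozenset(combo)
                    assert is_monophyletic(t, s) == (s in clans or size == 1)


class TestBootstrap:
    def test_fixed_differences_give_full_support(self):
        base = "A" * 20
        aln = make_alignment(
            [
                base,  # a1
                base[:-1] + "G",  # a2: one private transition
                "G" * 8 + base[8:],  # b1: eight fixed transitions from the a's
                "G" * 8 + base[8:-1] + "C",  # b2: plus one private difference
            ],
            ids=["a1", "a2", "b1", "b2"],
        )
        recs = bootstrap_support(aln, [{"a1", "a2"}, {"b1", "b2"}], reps=50, seed=1)
        assert all(r.nj_bootstrap_percent == 100.0 for r in recs)

    def test_seed_reproducibility(self):
        ds = simulate_dataset(SimConfig(sample_sizes=(4, 4, 4)), 5)
        haps = collapse_haplotypes(ds.alignment)
        groups = [
            set(ds.truth[ds.truth.species == s].haplotype) for s in ("sp1", "sp2")
        ]
        r1 = bootstrap_support(haps, groups, reps=30, seed=9)
        r2 = bootstrap_support(haps, groups, reps=30, seed=9)
        assert [x.nj_bootstrap_percent for x in r1] == [
            x.nj_bootstrap_percent for x in r2
        ]

    def test_true_clades_beat_random_groups(self):
        ds = simulate_dataset(SimConfig(sample_sizes=(5, 5, 5)), 3)
        haps = collapse_haplotypes(ds.alignment)
        true_group = set(ds.truth[ds.truth.species == "sp1"].haplotype)
        rng = np.random.default_rng(0)
        random_group = set(rng.choice(haps.ids, size=len(true_group), replace=False))
        if random_group == true_group:
            random_group = set(haps.ids[: len(true_group)])
        recs = bootstrap_support(haps, [true_group, random_group], reps=50, seed=2)
        assert recs[0].nj_bootstrap_percent >= 90
        assert recs[0].nj_bootstrap_percent > recs[1].nj_bootstrap_percent

    def test_strong_clade_support_across_seeds(self):
        ds = simulate_dataset(SimConfig(sample_sizes=(6, 6)), 8)
        haps = collapse_haplotypes(ds.alignment)
        group = set(ds.truth[ds.truth.species == "sp1"].haplotype)
        high = sum(
            bootstrap_support(haps, [group], reps=50, seed=s)[0].nj_bootstrap_percent
            >= 90
            for s in range(10)
        )
        assert high >= 9


class TestNewickIO:
    def test_roundtrip(self, tmp_path, rng):
        g = random_binary_tree(rng, 6)
        labels, d, _ = tree_facts(g)
        t = nj_tree(dm_from_array(d, labels=labels))
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        back = read_newick(path)
        assert bipartitions(back) == bipartitions(t)
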