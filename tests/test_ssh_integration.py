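"""Refinement rules, fauna comparison, conflict and nuclear congruence."""

import numpy as np
import pytest

from gapdelim import (
    MergeCandidateSet,
    PSHRecord,
    RefinementError,
    SplitGroup,
    SplitPlan,
    collapse_haplotypes,
    compare_fauna,
    conflict_table,
    distance_matrix,
    load_reference_bundle,
    nuclear_congruence,
    refine,
    simulate_dataset,
)
from gapdelim.synthetic_data import SimConfig
from gapdelim.ssh_integration import SSHSpecies


def rec(psh_id, nj=100.0, haps=3, inds=5, split=None, **kw):
    return PSHRecord(
        psh_id=psh_id,
        n_haplotypes=haps,
        n_individuals=inds,
        nj_whole=nj,
        split_plan=split,
        **kw,
    )


class TestRefineRules:
    def test_monophyletic_psh_accepted_unchanged(self):
        out = refine([rec("4", nj=100.0, morph_unique_external="yes")])
        assert out.species[0].action == "accept"
        assert out.species[0].rule == "R1"
        assert out.log[0].psh_id == "4"

    def test_single_haplotype_psh_trivially_accepted(self):
        out = refine([PSHRecord("19", n_haplotypes=1, n_individuals=4)])
        assert out.species[0].action == "accept"

    def test_non_monophyletic_psh_split_along_supported_children(self):
        plan = SplitPlan(
            groups=(
                SplitGroup(("1A",), nj_support=99.0),
                SplitGroup(("1B", "1C"), nj_support=93.0),
            )
        )
        out = refine([rec("1", nj=66.0, split=plan)])
        assert [s.ssh_id for s in out.species] == ["1A", "1B+1C"]
        assert all(s.action == "split_child" and s.rule == "R2" for s in out.species)

    def test_split_plan_unused_when_whole_psh_holds(self):
        plan = SplitPlan(groups=(SplitGroup(("xA",), nj_support=99.0),))
        out = refine([rec("x", nj=98.0, split=plan)])
        assert [s.ssh_id for s in out.species] == ["x"]
        assert "unused" in out.log[0].detail

    def test_unsupported_split_group_is_an_error(self):
        plan = SplitPlan(groups=(SplitGroup(("xA",), nj_support=40.0),))
        with pytest.raises(RefinementError, match="xA"):
            refine([rec("x", nj=10.0, split=plan)])

    def test_monophyletic_union_merged(self):
        out = refine(
            [rec("9"), rec("10")],
            merges=[MergeCandidateSet(("9", "10"), joint_nj=99.0)],
        )
        assert [s.ssh_id for s in out.species] == ["9+10"]
        assert out.species[0].action == "merge" and out.species[0].rule == "R3"
        assert out.species[0].constituents == ("9", "10")

    def test_non_monophyletic_union_kept_separate(self):
        out = refine(
            [rec("7", nj=96.0), rec("8", nj=100.0)],
            merges=[MergeCandidateSet(("7", "8"), joint_nj=0.0)],
        )
        assert [s.ssh_id for s in out.species] == ["7", "8"]
        assert all(s.action == "keep" and s.rule == "R4" for s in out.species)

    def test_every_psh_lands_in_exactly_one_ssh(self):
        out = refine(
            [rec(str(i)) for i in range(1, 7)],
            merges=[MergeCandidateSet(("2", "3"), joint_nj=90.0)],
        )
        assert sorted(out.constituents()) == [str(i) for i in range(1, 7)]

    def test_support_threshold_is_respected(self):
        table = [rec("a", nj=80.0), rec("b", nj=70.0)]
        out = refine([table[0]], support_threshold=75.0)
        assert out.species[0].action == "accept"
        with pytest.raises(RefinementError, match="b"):
            refine([table[1]], support_threshold=75.0)

    def test_merge_and_split_conflict_rejected(self):
        plan = SplitPlan(groups=(SplitGroup(("aX",), nj_support=99.0),))
        with pytest.raises(RefinementError, match="both"):
            refine(
                [rec("a", split=plan), rec("b")],
                merges=[MergeCandidateSet(("a", "b"), joint_nj=90.0)],
            )

    def test_missing_joint_support_named(self):
        with pytest.raises(RefinementError, match="joint"):
            refine(
                [rec("a"), rec("b")],
                merges=[MergeCandidateSet(("a", "b"), joint_nj=None)],
            )

    def test_missing_supports_error_names_psh(self):
        bad = PSHRecord("q", n_haplotypes=4, n_individuals=6)  # all supports n/a
        with pytest.raises(RefinementError, match="q"):
            refine([bad])

    def test_deterministic(self):
        bundle = load_reference_bundle()
        a = refine(bundle.psh_table, bundle.merges).to_json()
        b = refine(bundle.psh_table, bundle.merges).to_json()
        assert a == b


class TestCompareFauna:
    def test_identical_sets_have_no_additions(self):
        ssh = [SSHSpecies(str(i), (str(i),), "accept", "R1") for i in range(3)]
        checklist = ["n0", "n1", "n2"]
        fc = compare_fauna(ssh, checklist, {str(i): [f"n{i}"] for i in range(3)})
        assert fc.additional == 0 and fc.percent_increase == 0
        assert fc.matched_known == 3 and fc.known_split == 0

    def test_one_extra_species_in_eleven(self):
        ssh = [SSHSpecies(str(i), (str(i),), "accept", "R1") for i in range(11)]
        checklist = [f"n{i}" for i in range(10)]
        name_map = {str(i): [f"n{i}"] for i in range(10)}  # ssh "10" unmatched
        fc = compare_fauna(ssh, checklist, name_map)
        assert fc.additional == 1 and fc.percent_increase == 10
        assert fc.additional_ssh_ids == ("10",)

    def test_lumped_and_split_names_counted(self):
        ssh = [
            SSHSpecies("A", ("A",), "accept", "R1"),
            SSHSpecies("B1", ("B1",), "keep", "R4"),
            SSHSpecies("B2", ("B2",), "keep", "R4"),
        ]
        checklist = ["x", "y", "z"]
        fc = compare_fauna(
            ssh, checklist, {"A": ["x", "y"], "B1": ["z"], "B2": ["z"]}
        )
        assert fc.known_lumped_pairs == 1 and fc.known_split == 1
        assert fc.names_covered == 3

    def test_duplicate_checklist_rejected(self):
        with pytest.raises(RefinementError, match="duplicate"):
            compare_fauna([], ["a", "a"], {})

    def test_unknown_mapped_name_rejected(self):
        ssh = [SSHSpecies("A", ("A",), "accept", "R1")]
        with pytest.raises(RefinementError, match="not on the checklist"):
            compare_fauna(ssh, ["x"], {"A": ["y"]})


class TestConflictTable:
    def test_one_way_conflict_with_direction(self):
        specimens = [("reticulatum", "agreste")] * 3 + [
            ("agreste", "agreste"),
            ("reticulatum", "reticulatum"),
        ]
        rep = conflict_table(specimens)
        pair = ("agreste", "reticulatum")
        assert rep.classifications[pair] == "one_way"
        # reticulatum-anatomy individuals carry agreste mtDNA
        assert rep.directions[pair] == ("reticulatum", "agreste")
        assert rep.n_specimens == 5 and rep.n_concordant == 2

    def test_no_conflicts_gives_empty_report(self):
        rep = conflict_table([("a", "a"), ("b", "b")])
        assert not rep.has_conflict and rep.classifications == {}

    def test_both_directions_is_two_way(self):
        rep = conflict_table([("a", "b")] * 2 + [("b", "a")] * 2)
        assert rep.classifications[("a", "b")] == "two_way"
        assert ("a", "b") not in rep.directions

    def test_marginals_conserved(self):
        specimens = [("a", "b")] * 4 + [("a", "a")] * 3 + [("c", "a")] * 2
        rep = conflict_table(specimens)
        assert rep.n_concordant + sum(rep.pair_counts.values()) == rep.n_specimens


class TestNuclearCongruence:
    @staticmethod
    def _groups(ds):
        return {
            s: set(ds.truth[ds.truth.species == s].haplotype)
            for s in ds.truth.species.unique()
        }

    def test_mirrored_partition_is_congruent(self):
        ds = simulate_dataset(SimConfig(sample_sizes=(5, 5, 5)), 4)
        dm = distance_matrix(collapse_haplotypes(ds.alignment))
        rep = nuclear_congruence(dm, None, self._groups(ds))
        assert all(s in ("congruent", "trivial") for s in rep.group_status.values())
        assert rep.shared_pool is None

    def test_shared_pool_pattern_detected(self):
        # five "species" drawn from one nuclear pool plus a distinct outgroup
        ds = simulate_dataset(SimConfig(sample_sizes=(25, 5), intra=0.01, inter=0.1), 6)
        relabel = ds.truth.copy()
        relabel.loc[relabel.species == "sp1", "species"] = [
            f"pool{i % 5 + 1}" for i in range((relabel.species == "sp1").sum())
        ]
        groups = {
            s: set(relabel[relabel.species == s].haplotype)
            for s in relabel.species.unique()
        }
        dm = distance_matrix(collapse_haplotypes(ds.alignment))
        rep = nuclear_congruence(dm, None, groups)
        assert rep.shared_pool is not None
        assert set(rep.shared_pool) == {f"pool{i}" for i in range(1, 6)}
        assert rep.group_status["sp2"] in ("congruent", "trivial")

    def test_missing_groups_skipped_and_reported(self):
        ds = simulate_dataset(SimConfig(sample_sizes=(5, 5, 5)), 4)
        dm = distance_matrix(collapse_haplotypes(ds.alignment))
        groups = self._groups(ds)
        groups["ghost"] = {"not-a-haplotype"}
        rep = nuclear_congruence(dm, None, groups)
        assert rep.group_status["ghost"] == "skipped"

    def test_single_group_cannot_flag_shared_pool(self):
        ds = simulate_dataset(SimConfig(sample_sizes=(5, 5)), 4)
        dm = distance_matrix(collapse_haplotypes(ds.alignment))
        groups = {"only": set(ds.truth[ds.truth.species == "sp1"].haplotype)}
        rep = nuclear_congruence(dm, None, groups)
        assert rep.shared_pool is None
        assert "single testable group" in rep.note
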