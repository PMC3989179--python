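"""Refinement of primary into secondary species hypotheses by congruence.

A primary species hypothesis (PSH) is a purely distance-based partition.  The
secondary species hypothesis (SSH) integrates it with monophyly and
morphological evidence ("integration by congruence"):

R1  accept: a monophyletic PSH becomes an SSH species unchanged;
R2  split: a non-monophyletic PSH whose subset analysis resolves it into
    children is split along child groups that are themselves monophyletic;
R3  merge: morphologically indistinguishable PSHs whose union is monophyletic
    are combined into one SSH species;
R4  keep: members of such a set whose union is *not* monophyletic stay
    separate SSH species.

"Monophyletic" for rule purposes means NJ bootstrap >= 75 in at least one
relevant analysis (whole-family or subset); Bayesian posteriors are
corroborating evidence carried along, not required.  PSHs represented by a
single haplotype are trivially monophyletic.

The module also compares an SSH set against a known faunal checklist and
detects mito/morphology and mito/nuclear conflicts, the signature of
interspecific hybridisation and one-way introgression.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .k2p import DistanceMatrix
from .nj_phylo import TreeNode, is_monophyletic, nj_tree

__all__ = [
    "RefinementError",
    "PSHRecord",
    "SplitGroup",
    "SplitPlan",
    "MergeCandidateSet",
    "SSHSpecies",
    "SSHSet",
    "FaunaComparison",
    "ConflictReport",
    "NuclearCongruenceReport",
    "refine",
    "compare_fauna",
    "conflict_table",
    "nuclear_congruence",
]

MORPH_STATES = ("yes", "no", "uncertain")


class RefinementError(ValueError):
    pass


@dataclass(frozen=True)
class SplitGroup:
    """One SSH-to-be within a split plan: child PSH ids plus the NJ bootstrap
    support of the clade they form together."""

    children: tuple[str, ...]
    nj_support: float | None


@dataclass(frozen=True)
class SplitPlan:
    """How a non-monophyletic PSH resolves into children in the subset
    analysis (e.g. PSH 1 -> 1A | 1B+1C)."""

    groups: tuple[SplitGroup, ...]

    def child_ids(self) -> tuple[str, ...]:
        return tuple(c for g in self.groups for c in g.children)


@dataclass(frozen=True)
class PSHRecord:
    """Evidence bundle for one putative species.

    NJ/BI supports are percentages (0-100) or None ("n/a", e.g. when the PSH
    has a single haplotype or was absent from a subset analysis).  Morphology
    flags take values in {"yes", "no", "uncertain"}.
    """

    psh_id: str
    n_haplotypes: int
    n_individuals: int
    nj_whole: float | None = None
    bi_whole: float | None = None
    nj_subset: float | None = None
    bi_subset: float | None = None
    morph_unique_external: str = "no"
    morph_unique_internal: str = "no"
    mean_intra: float | None = None
    min_inter: float | None = None
    split_plan: SplitPlan | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.n_individuals < self.n_haplotypes or self.n_haplotypes < 1:
            raise RefinementError(
                f"PSH {self.psh_id}: need n_individuals >= n_haplotypes >= 1"
            )
        for attr in ("morph_unique_external", "morph_unique_internal"):
            if getattr(self, attr) not in MORPH_STATES:
                raise RefinementError(
                    f"PSH {self.psh_id}: {attr} must be one of {MORPH_STATES}"
                )

    @property
    def morphologically_unique(self) -> bool:
        """External OR internal morphology marked unique ('uncertain' does not
        count as unique, but does not veto acceptance under strong monophyly)."""
        return "yes" in (self.morph_unique_external, self.morph_unique_internal)

    def nj_supports(self) -> list[float]:
        return [s for s in (self.nj_whole, self.nj_subset) if s is not None]


@dataclass(frozen=True)
class MergeCandidateSet:
    """PSHs declared morphologically indistinguishable from one another
    (external evidence), with the NJ support of their joint clade."""

    members: tuple[str, ...]
    joint_nj: float | None
    joint_bi: float | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise RefinementError("a merge-candidate set needs >= 2 members")
        if len(set(self.members)) != len(self.members):
            raise RefinementError(f"duplicate members in merge set: {self.members}")


@dataclass(frozen=True)
class SSHSpecies:
    ssh_id: str
    constituents: tuple[str, ...]
    action: str  # accept | split_child | merge | keep
    rule: str  # R1..R4
    applied_name: str | None = None


@dataclass
class RefinementDecision:
    psh_id: str
    rule: str
    action: str
    detail: str


@dataclass
class SSHSet:
    """The refined species set plus the per-PSH decision log."""

    species: list[SSHSpecies]
    log: list[RefinementDecision]
    support_threshold: float

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_accepted_unchanged(self) -> int:
        return sum(1 for s in self.species if s.action == "accept")

    def constituents(self) -> list[str]:
        return [c for s in self.species for c in s.constituents]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ssh_id": s.ssh_id,
                    "constituents": "+".join(s.constituents),
                    "action": s.action,
                    "rule": s.rule,
                }
                for s in self.species
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "support_threshold": self.support_threshold,
                "species": [
                    {
                        "ssh_id": s.ssh_id,
                        "constituents": list(s.constituents),
                        "action": s.action,
                        "rule": s.rule,
                    }
                    for s in self.species
                ],
                "log": [
                    {
                        "psh_id": d.psh_id,
                        "rule": d.rule,
                        "action": d.action,
                        "detail": d.detail,
                    }
                    for d in self.log
                ],
            },
            indent=2,
        )


def _is_monophyletic_record(rec: PSHRecord, threshold: float) -> bool:
    supports = rec.nj_supports()
    if supports:
        return max(supports) >= threshold
    if rec.n_haplotypes <= 1:
        return True  # single haplotype: trivially monophyletic
    raise RefinementError(
        f"PSH {rec.psh_id}: monophyly support required but all values are n/a"
    )


def refine(
    psh_table: Sequence[PSHRecord],
    merges: Sequence[MergeCandidateSet] = (),
    support_threshold: float = 75.0,
) -> SSHSet:
    """Apply rules R1-R4 to a PSH table, producing the SSH set.

    Every PSH (or split child) lands in exactly one SSH species; each decision
    is logged with its rule.  A PSH may not both carry a split plan and belong
    to a merge-candidate set; merge sets must be disjoint and reference known
    PSH ids.
    """
    by_id = {r.psh_id: r for r in psh_table}
    if len(by_id) != len(psh_table):
        raise RefinementError("duplicate psh_id in table")
    merge_of: dict[str, MergeCandidateSet] = {}
    for ms in merges:
        for m in ms.members:
            if m not in by_id:
                raise RefinementError(f"merge set references unknown PSH {m}")
            if m in merge_of:
                raise RefinementError(f"PSH {m} appears in more than one merge set")
            if by_id[m].split_plan is not None:
                raise RefinementError(
                    f"PSH {m} has both a split plan and merge-set membership"
                )
            merge_of[m] = ms

    species: list[SSHSpecies] = []
    log: list[RefinementDecision] = []
    handled_merge: set[str] = set()

    for rec in psh_table:
        if rec.psh_id in merge_of:
            ms = merge_of[rec.psh_id]
            if rec.psh_id in handled_merge:
                continue
            handled_merge.update(ms.members)
            if ms.joint_nj is None:
                raise RefinementError(
                    f"merge set {ms.members}: joint monophyly support missing"
                )
            ordered = tuple(m for m in by_id if m in ms.members)
            if ms.joint_nj >= support_threshold:
                ssh_id = "+".join(ordered)
                species.append(
                    SSHSpecies(ssh_id, ordered, action="merge", rule="R3")
                )
                for m in ordered:
                    log.append(
                        RefinementDecision(
                            m,
                            "R3",
                            "merge",
                            f"morphologically indistinguishable set {ordered} "
                            f"combined; joint NJ {ms.joint_nj:g} >= {support_threshold:g}",
                        )
                    )
            else:
                for m in ordered:
                    member = by_id[m]
                    if not _is_monophyletic_record(member, support_threshold):
                        raise RefinementError(
                            f"PSH {m}: kept separate (R4) but not itself monophyletic"
                        )
                    species.append(
                        SSHSpecies(m, (m,), action="keep", rule="R4")
                    )
                    log.append(
                        RefinementDecision(
                            m,
                            "R4",
                            "keep",
                            f"union {ordered} not monophyletic "
                            f"(joint NJ {ms.joint_nj:g} < {support_threshold:g}); "
                            "members maintained as separate species",
                        )
                    )
            continue

        if rec.split_plan is not None:
            if _is_monophyletic_record(rec, support_threshold):
                # whole PSH holds together after all: accept unchanged
                species.append(
                    SSHSpecies(rec.psh_id, (rec.psh_id,), action="accept", rule="R1")
                )
                log.append(
                    RefinementDecision(
                        rec.psh_id, "R1", "accept", "split plan unused: whole PSH monophyletic"
                    )
                )
                continue
            for grp in rec.split_plan.groups:
                if grp.nj_support is None:
                    raise RefinementError(
                        f"PSH {rec.psh_id}: split group {grp.children} lacks support"
                    )
                if grp.nj_support < support_threshold:
                    raise RefinementError(
                        f"PSH {rec.psh_id}: split group {grp.children} not "
                        f"monophyletic (NJ {grp.nj_support:g})"
                    )
                ssh_id = "+".join(grp.children)
                species.append(
                    SSHSpecies(ssh_id, grp.children, action="split_child", rule="R2")
                )
            log.append(
                RefinementDecision(
                    rec.psh_id,
                    "R2",
                    "split",
                    "non-monophyletic PSH split into "
                    + " | ".join("+".join(g.children) for g in rec.split_plan.groups),
                )
            )
            continue

        if not _is_monophyletic_record(rec, support_threshold):
            raise RefinementError(
                f"PSH {rec.psh_id}: not monophyletic and no split plan or "
                "merge evidence available"
            )
        species.append(SSHSpecies(rec.psh_id, (rec.psh_id,), action="accept", rule="R1"))
        log.append(
            RefinementDecision(
                rec.psh_id,
                "R1",
                "accept",
                "monophyletic putative species accepted unchanged",
            )
        )

    return SSHSet(species=species, log=log, support_threshold=support_threshold)


@dataclass
class FaunaComparison:
    """Accounting of an SSH set against a known faunal checklist."""

    total_ssh: int
    matched_known: int  # SSH species matched to >= 1 checklist name
    names_covered: int  # distinct checklist names claimed by some SSH
    known_lumped_pairs: int  # extra names absorbed by multi-name SSHs
    known_split: int  # checklist names shared by >= 2 SSHs
    additional: int  # SSH species matching no checklist name
    additional_ssh_ids: tuple[str, ...]
    percent_increase: int  # additional / checklist size, nearest integer %

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=list)


def compare_fauna(
    ssh: SSHSet | Sequence[SSHSpecies],
    checklist: Sequence[str],
    name_map: Mapping[str, Sequence[str]],
) -> FaunaComparison:
    """Compare SSH species to a checklist of known species names.

    ``name_map`` gives, per SSH id, the checklist names that SSH corresponds
    to (empty list or absent id: no known name — an additional species).  One
    SSH covering two names is a lumped pair; two SSHs sharing one name is a
    known species split.
    """
    if not checklist:
        raise RefinementError("checklist is empty")
    if len(set(checklist)) != len(checklist):
        dupes = sorted({n for n in checklist if list(checklist).count(n) > 1})
        raise RefinementError(f"duplicate checklist names: {dupes}")
    known = set(checklist)
    species = ssh.species if isinstance(ssh, SSHSet) else list(ssh)
    matched = 0
    lumped_pairs = 0
    additional_ids: list[str] = []
    claims: Counter[str] = Counter()
    for s in species:
        names = list(name_map.get(s.ssh_id, ()))
        unknown = [n for n in names if n not in known]
        if unknown:
            raise RefinementError(
                f"SSH {s.ssh_id} mapped to names not on the checklist: {unknown}"
            )
        if names:
            matched += 1
            lumped_pairs += len(set(names)) - 1
            claims.update(set(names))
        else:
            additional_ids.append(s.ssh_id)
    additional = len(additional_ids)
    if matched + additional != len(species):
        raise RefinementError("accounting error: matched + additional != total")
    return FaunaComparison(
        total_ssh=len(species),
        matched_known=matched,
        names_covered=len(claims),
        known_lumped_pairs=lumped_pairs,
        known_split=sum(1 for n, c in claims.items() if c >= 2),
        additional=additional,
        additional_ssh_ids=tuple(additional_ids),
        percent_increase=round(100.0 * additional / len(checklist)),
    )


@dataclass
class ConflictReport:
    """Mito/morphology conflict counts and their classification.

    ``pair_counts[(A, B)]`` is the number of specimens with morphology label A
    but an mtDNA assignment B != A.  Each unordered species pair is classified
    ``one_way`` (conflicts in a single direction) or ``two_way``; for one-way
    pairs ``directions[pair]`` records (recipient_morphospecies, mtdna_source)
    — the morphospecies whose individuals carry foreign mtDNA, i.e.
    introgressed hybrids descended from a mother of the donor species.
    """

    n_specimens: int
    n_concordant: int
    pair_counts: dict[tuple[str, str], int]
    classifications: dict[tuple[str, str], str]
    directions: dict[tuple[str, str], tuple[str, str]]

    @property
    def has_conflict(self) -> bool:
        return bool(self.pair_counts)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for pair, cls in sorted(self.classifications.items()):
            a, b = pair
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "n_morphA_mtB": self.pair_counts.get((a, b), 0),
                    "n_morphB_mtA": self.pair_counts.get((b, a), 0),
                    "classification": cls,
                    "recipient": self.directions.get(pair, (None, None))[0],
                    "mtdna_source": self.directions.get(pair, (None, None))[1],
                }
            )
        return pd.DataFrame(rows)


def conflict_table(specimens: Iterable[tuple[str, str]]) -> ConflictReport:
    """Classify mito/morphology conflicts from (morph label, mtDNA assignment)
    pairs.

    Specimens whose two labels agree are concordant.  For a species pair with
    conflicts in only one direction the report is ``one_way`` with the
    direction naming the recipient morphospecies (e.g. individuals with one
    species' anatomy carrying the other species' mtDNA); conflicts in both
    directions are ``two_way``.  No specimen is dropped or double-counted.
    """
    counts: Counter[tuple[str, str]] = Counter()
    n_total = 0
    n_same = 0
    for morph, mt in specimens:
        n_total += 1
        if morph == mt:
            n_same += 1
        else:
            counts[(morph, mt)] += 1
    classifications: dict[tuple[str, str], str] = {}
    directions: dict[tuple[str, str], tuple[str, str]] = {}
    for (a, b) in list(counts):
        pair = tuple(sorted((a, b)))
        if pair in classifications:
            continue
        ab = counts.get((pair[0], pair[1]), 0)
        ba = counts.get((pair[1], pair[0]), 0)
        if ab > 0 and ba > 0:
            classifications[pair] = "two_way"
        else:
            classifications[pair] = "one_way"
            if ab > 0:
                directions[pair] = (pair[0], pair[1])
            else:
                directions[pair] = (pair[1], pair[0])
    return ConflictReport(
        n_specimens=n_total,
        n_concordant=n_same,
        pair_counts=dict(counts),
        classifications=classifications,
        directions=directions,
    )


@dataclass
class NuclearCongruenceReport:
    """Per-SSH congruence with a nuclear (e.g. ITS-1) tree.

    ``group_status`` maps group id to ``congruent`` (monophyletic in the
    nuclear tree), ``not_monophyletic``, ``trivial`` (single nuclear leaf) or
    ``skipped`` (no nuclear data).  ``shared_pool`` names a set of groups none
    of which is individually monophyletic while their union is — the pattern
    of a shared nuclear gene pool across hybridising mitochondrial lineages,
    to the exclusion of the remaining taxa.
    """

    group_status: dict[str, str]
    shared_pool: tuple[str, ...] | None
    note: str = ""


def nuclear_congruence(
    nuclear_dm: DistanceMatrix | None,
    nuclear_tree: TreeNode | None,
    ssh_groups: Mapping[str, Iterable[str]],
) -> NuclearCongruenceReport:
    """Test each SSH group for monophyly on a nuclear tree.

    Either a tree or a distance matrix (from which an NJ tree is built) must
    be supplied.  Groups with no members among the nuclear leaves are skipped
    and reported.  With a single testable group no shared-pool flag is
    possible, noted as such.
    """
    if nuclear_tree is None:
        if nuclear_dm is None:
            raise RefinementError("need a nuclear tree or distance matrix")
        nuclear_tree = nj_tree(nuclear_dm)
    leaves = frozenset(n.name for n in nuclear_tree.tips())
    status: dict[str, str] = {}
    present: dict[str, frozenset[str]] = {}
    for gid, members in ssh_groups.items():
        here = frozenset(members) & leaves
        if not here:
            status[gid] = "skipped"
            continue
        present[gid] = here
        if len(here) == 1:
            status[gid] = "trivial"
        elif here == leaves:
            status[gid] = "trivial"  # whole tree: no sister group to test against
        elif is_monophyletic(nuclear_tree, here):
            status[gid] = "congruent"
        else:
            status[gid] = "not_monophyletic"
    non_mono = [g for g, s in status.items() if s == "not_monophyletic"]
    shared: tuple[str, ...] | None = None
    note = ""
    if len(present) <= 1:
        note = "single testable group: shared-pool detection not possible"
    elif len(non_mono) >= 2:
        union = frozenset().union(*(present[g] for g in non_mono))
        if union < leaves and is_monophyletic(nuclear_tree, union):
            shared = tuple(non_mono)
            note = (
                "groups form a single nuclear clade without internal "
                "group structure (shared nuclear pool)"
            )
    return NuclearCongruenceReport(group_status=status, shared_pool=shared, note=note)
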