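"""Packaged reference evidence: the British and Irish slug fauna survey.

These files transcribe the summary-level evidence of a DNA-barcoding
delimitation survey of the slugs of Britain and Ireland: one row per putative
species (PSH) with haplotype/individual counts, mean intra- and minimum mean
interspecific K2P distances, NJ bootstrap and Bayesian posterior monophyly
supports from whole-family and subset analyses, and morphology-uniqueness
flags; the merge-candidate sets of morphologically indistinguishable PSHs;
the split plan for the one PSH resolved into children by a subset analysis;
the 36-name checklist of the previously known fauna; and the checklist names
matched by each refined species.

Running :func:`gapdelim.ssh_integration.refine` on this bundle reproduces the
published refinement: 42 secondary species (44 with the two monotypic-family
additions), 36 putative species accepted unchanged, and 8 species additional
to the known fauna (a 22% increase).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from importlib import resources

from .ssh_integration import (
    MergeCandidateSet,
    PSHRecord,
    SplitGroup,
    SplitPlan,
    SSHSpecies,
)

__all__ = ["ReferenceBundle", "load_reference_bundle"]

_MORPH = {"yes": "yes", "no": "no", "uncertain": "uncertain", "": "no"}


@dataclass
class ReferenceBundle:
    """Everything needed to rerun the published refinement and comparison."""

    psh_table: list[PSHRecord]
    merges: list[MergeCandidateSet]
    checklist: list[str]
    name_map: dict[str, list[str]]
    published_ssh: dict[str, str]  # psh_id -> published SSH id
    applied_names: dict[str, str]  # psh_id -> name applied to its SSH
    extra_species: list[SSHSpecies]  # degenerate monotypic-family additions


def _read_text(name: str) -> str:
    return resources.files("gapdelim.data").joinpath(name).read_text()


def _opt_float(value: str) -> float | None:
    return float(value) if value not in ("", "n/a") else None


def load_reference_bundle() -> ReferenceBundle:
    rows = list(csv.DictReader(_read_text("slug_psh_table.csv").splitlines()))
    split_spec = json.loads(_read_text("slug_split_plan.json"))
    plans: dict[str, SplitPlan] = {}
    child_rows: dict[str, dict] = {r["psh_id"]: r for r in rows if r["parent"]}
    for plan in split_spec["plans"]:
        groups = []
        for g in plan["groups"]:
            for child in g["children"]:
                if child not in child_rows:
                    raise ValueError(f"split plan references unknown child {child}")
            groups.append(
                SplitGroup(children=tuple(g["children"]), nj_support=g["nj_support"])
            )
        plans[plan["parent"]] = SplitPlan(groups=tuple(groups))

    psh_table: list[PSHRecord] = []
    published_ssh: dict[str, str] = {}
    applied: dict[str, str] = {}
    for r in rows:
        if r["parent"]:
            continue  # child rows live inside their parent's split plan
        rec = PSHRecord(
            psh_id=r["psh_id"],
            n_haplotypes=int(r["n_haplotypes"]),
            n_individuals=int(r["n_individuals"]),
            nj_whole=_opt_float(r["nj_whole"]),
            bi_whole=_opt_float(r["bi_whole"]),
            nj_subset=_opt_float(r["nj_subset"]),
            bi_subset=_opt_float(r["bi_subset"]),
            morph_unique_external=_MORPH[r["morph_external"]],
            morph_unique_internal=_MORPH[r["morph_internal"]],
            mean_intra=_opt_float(r["mean_intra"]),
            min_inter=_opt_float(r["min_inter"]),
            split_plan=plans.get(r["psh_id"]),
        )
        psh_table.append(rec)
        published_ssh[r["psh_id"]] = r["published_ssh"]
        if r["applied_name"]:
            applied[r["psh_id"]] = r["applied_name"]
    for cid, r in child_rows.items():
        published_ssh[cid] = r["published_ssh"]
        if r["applied_name"]:
            applied[cid] = r["applied_name"]

    merge_spec = json.loads(_read_text("slug_merge_sets.json"))
    merges = [
        MergeCandidateSet(
            members=tuple(s["members"]),
            joint_nj=s["joint_nj"],
            note=s.get("note", ""),
        )
        for s in merge_spec["sets"]
    ]

    checklist = [
        line.strip()
        for line in _read_text("slug_checklist.txt").splitlines()
        if line.strip() and not line.startswith("#")
    ]

    names_spec = json.loads(_read_text("slug_ssh_names.json"))
    name_map = {k: list(v) for k, v in names_spec["name_map"].items()}
    extra = [
        SSHSpecies(
            ssh_id=e["ssh_id"],
            constituents=(e["ssh_id"],),
            action="accept",
            rule="degenerate",
            applied_name=e["applied_name"],
        )
        for e in names_spec["degenerate_family_species"]
    ]
    return ReferenceBundle(
        psh_table=psh_table,
        merges=merges,
        checklist=checklist,
        name_map=name_map,
        published_ssh=published_ssh,
        applied_names=applied,
        extra_species=extra,
    )
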