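"""Refine the packaged slug-survey evidence into a secondary species
hypothesis and compare it against the known 36-species checklist.

The bundle transcribes the summary evidence of a DNA-barcoding survey of the
slugs of Britain and Ireland: 45 putative species with monophyly supports,
morphology flags, one split plan and three merge-candidate sets.
"""

from gapdelim import compare_fauna, load_reference_bundle, refine

bundle = load_reference_bundle()
ssh = refine(bundle.psh_table, bundle.merges)

actions = ssh.to_dataframe().action.value_counts()
print(f"refined species: {ssh.n_species}  (from {len(bundle.psh_table)} PSHs)")
print(actions.to_string())

fauna = compare_fauna(
    list(ssh.species) + bundle.extra_species, bundle.checklist, bundle.name_map
)
print(
    f"\ntotal species incl. the two degenerate families: {fauna.total_ssh}"
    f"\nmatched to the {len(bundle.checklist)}-name checklist: {fauna.matched_known}"
    f"\nadditional (previously undetected) species: {fauna.additional} "
    f"= +{fauna.percent_increase}% on the known fauna"
    f"\nadditional species ids: {', '.join(fauna.additional_ssh_ids)}"
)
print(
    "\n'accept' species passed monophyly unchanged (rule R1); splits follow "
    "subset-analysis structure (R2); merges combine morphologically "
    "indistinguishable monophyletic unions (R3); 'keep' pairs stay separate "
    "because their union is not monophyletic (R4)."
)
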