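{
  "comment": "Merge-candidate sets: putative slug species that could not be distinguished morphologically from one another. joint_nj encodes whether their joint clade was supported as monophyletic in the published trees (>=75: yes; the {7,8} union was not monophyletic in any analysis).",
  "sets": [
    {"members": ["7", "8"], "joint_nj": 0, "note": "union not monophyletic in any analysis; maintained as separate species"},
    {"members": ["9", "10"], "joint_nj": 99, "note": "joint clade monophyletic; combined"},
    {"members": ["33", "34", "35", "36"], "joint_nj": 99, "note": "joint clade monophyletic; combined (multiple lineages, further study required)"}
  ]
}
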