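{
  "comment": "Split plan for the one putative species delimited whole in the family-level analysis but resolved into children in the subset analysis. Group supports are the NJ bootstrap values of the child clades (1A alone; 1B and 1C together form a supported clade).",
  "plans": [
    {
      "parent": "1",
      "groups": [
        {"children": ["1A"], "nj_support": 99},
        {"children": ["1B", "1C"], "nj_support": 93}
      ]
    }
  ]
}
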