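{
  "improved_online_subset": ["H1", "H4", "H6", "H8", "H9", "H11", "H12", "H13", "H14", "H15", "H16"],
  "bci_illiterate": ["H1", "H2", "H4", "H11", "H13", "H15"],
  "note": "The source report lists six BCI-illiterate subjects by ID but then refers to 'these five subjects'; the six-ID list is stored verbatim and the count inconsistency is surfaced rather than resolved."
}
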