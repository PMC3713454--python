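{
  "comment": "Ectodomain domain intervals (inclusive, mature author numbering). EGFR intervals are the reference; HER2/HER3/DEGFR defaults are alignment-offset estimates and should be overridden with alignment-derived maps when sequences are available.",
  "EGFR": {"I": [1, 165], "II": [166, 310], "III": [311, 480], "IV": [481, 620]},
  "HER2": {"I": [1, 171], "II": [172, 316], "III": [317, 488], "IV": [489, 630]},
  "HER3": {"I": [1, 165], "II": [166, 310], "III": [311, 480], "IV": [481, 620]},
  "DEGFR": {"I": [1, 160], "II": [161, 305], "III": [306, 475], "IV": [476, 615], "V": [616, 781]}
}
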