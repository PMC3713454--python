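{
  "comment": "Heavy-atom van der Waals radii (Angstrom), Bondi (1964) set; used for SASA and clash geometry. Override per atom via AtomRecord.radius.",
  "default": 1.7,
  "elements": {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.9
  }
}
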