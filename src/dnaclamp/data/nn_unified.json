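{
  "name": "unified-dna-nn",
  "description": "Unified DNA nearest-neighbor duplex parameters at 1 M NaCl: dH in kcal/mol, dS in cal/(mol K) per dinucleotide step (5'->3' top strand). Monovalent salt enters as dS + salt_ds_per_step * ln[Mon+] per step.",
  "salt_ds_per_step": 0.368,
  "steps": {
    "AA": {"dH": -7.9, "dS": -22.2},
    "AT": {"dH": -7.2, "dS": -20.4},
    "TA": {"dH": -7.2, "dS": -21.3},
    "CA": {"dH": -8.5, "dS": -22.7},
    "GT": {"dH": -8.4, "dS": -22.4},
    "CT": {"dH": -7.8, "dS": -21.0},
    "GA": {"dH": -8.2, "dS": -22.2},
    "CG": {"dH": -10.6, "dS": -27.2},
    "GC": {"dH": -9.8, "dS": -24.4},
    "GG": {"dH": -8.0, "dS": -19.9}
  }
}
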