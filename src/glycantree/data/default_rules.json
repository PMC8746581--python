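[
  {"_comment": "glycantree default rule table v1. Reconstructed cover of the common animal donor residues; replace wholesale with --rules for other residue spaces."},
  {"first_block": "dglc-HEX", "second_block": "n-acetyl", "first_carbon": 2, "second_carbon": 1, "composition": "HexNAc"},
  {"first_block": "dgal-HEX", "second_block": "n-acetyl", "first_carbon": 2, "second_carbon": 1, "composition": "HexNAc"},
  {"first_block": "dman-HEX", "second_block": "n-acetyl", "first_carbon": 2, "second_carbon": 1, "composition": "HexNAc"},
  {"first_block": "dglc-HEX", "second_block": "amino", "first_carbon": 2, "second_carbon": 1, "composition": "HexN"},
  {"first_block": "dgal-HEX", "second_block": "amino", "first_carbon": 2, "second_carbon": 1, "composition": "HexN"},
  {"first_block": "dgro-dgal-NON", "second_block": "n-acetyl", "first_carbon": 5, "second_carbon": 1, "composition": "Neu5Ac"},
  {"first_block": "dgro-dgal-NON", "second_block": "n-glycolyl", "first_carbon": 5, "second_carbon": 1, "composition": "Neu5Gc"},

  {"block": "dglc-HEX", "composition": "Hex"},
  {"block": "dgal-HEX", "composition": "Hex"},
  {"block": "dman-HEX", "composition": "Hex"},
  {"block": "lgal-HEX", "composition": "Hex"},
  {"block": "lgal-HEX|6:d", "composition": "dHex"},
  {"block": "lman-HEX|6:d", "composition": "dHex"},
  {"block": "dglc-HEX|6:a", "composition": "HexA"},
  {"block": "dgal-HEX|6:a", "composition": "HexA"},
  {"block": "lido-HEX|6:a", "composition": "HexA"},
  {"block": "dxyl-PEN", "composition": "Pent"},
  {"block": "lara-PEN", "composition": "Pent"},
  {"block": "drib-PEN", "composition": "Pent"},
  {"block": "dgro-dgal-NON", "composition": "Kdn"},

  {"block": "n-acetyl", "composition": "NAc"},
  {"block": "n-glycolyl", "composition": "NGc"},
  {"block": "amino", "composition": "N"},
  {"block": "acetyl", "composition": "Ac"},
  {"block": "methyl", "composition": "Me"},
  {"block": "sulfate", "composition": "S"},
  {"block": "phosphate", "composition": "P"}
]
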