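{
  "comment": "Van der Waals radii in Angstrom. 'element' are Bondi radii; 'sidechain_pseudo' are effective radii for the single side-chain centroid pseudo-atom of the reduced representation, scaled with side-chain heavy-atom count.",
  "element": {
    "H": 1.2,
    "C": 1.7,
    "N": 1.55,
    "O": 1.52,
    "S": 1.8,
    "P": 1.8,
    "SE": 1.9,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98
  },
  "sidechain_pseudo": {
    "GLY": 1.0,
    "ALA": 1.9,
    "SER": 2.0,
    "CYS": 2.1,
    "THR": 2.2,
    "VAL": 2.3,
    "PRO": 2.3,
    "ASP": 2.4,
    "ASN": 2.4,
    "ILE": 2.5,
    "LEU": 2.5,
    "MET": 2.6,
    "GLU": 2.6,
    "GLN": 2.6,
    "LYS": 2.7,
    "HIS": 2.7,
    "PHE": 2.8,
    "ARG": 2.9,
    "TYR": 2.9,
    "TRP": 3.1,
    "UNK": 2.4
  }
}
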