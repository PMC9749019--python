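{
  "*": {
    "N": "donor", "O": "acceptor", "OXT": "acceptor",
    "O5'": "acceptor", "O3'": "acceptor", "O4'": "acceptor", "O2'": "both",
    "OP1": "acceptor", "OP2": "acceptor"
  },
  "HOH": {"O": "both"},
  "SOL": {"OW": "both"},
  "SER": {"OG": "both"},
  "THR": {"OG1": "both"},
  "TYR": {"OH": "both"},
  "CYS": {"SG": "both"},
  "MET": {"SD": "acceptor"},
  "ASN": {"OD1": "acceptor", "ND2": "donor"},
  "GLN": {"OE1": "acceptor", "NE2": "donor"},
  "ASP": {"OD1": "acceptor", "OD2": "acceptor"},
  "GLU": {"OE1": "acceptor", "OE2": "acceptor"},
  "LYS": {"NZ": "donor"},
  "ARG": {"NE": "donor", "NH1": "donor", "NH2": "donor"},
  "HIS": {"ND1": "both", "NE2": "both"},
  "TRP": {"NE1": "donor"},
  "PRO": {"N": null},
  "A": {"N1": "acceptor", "N3": "acceptor", "N6": "donor", "N7": "acceptor"},
  "G": {"N1": "donor", "N2": "donor", "N3": "acceptor", "N7": "acceptor", "O6": "acceptor"},
  "C": {"N3": "acceptor", "N4": "donor", "O2": "acceptor"},
  "U": {"N3": "donor", "O2": "acceptor", "O4": "acceptor"},
  "T": {"N3": "donor", "O2": "acceptor", "O4": "acceptor"},
  "GLC": {"O1": "both", "O2": "both", "O3": "both", "O4": "both", "O6": "both"}
}
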