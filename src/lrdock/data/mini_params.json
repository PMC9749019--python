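{
  "combination_rule": "geometric",
  "provenance": "lrdock bundled mini table: synthetic generic parameters covering the fixture chemistry (water, a few amino-acid side chains, ions, generic ligand atoms). Not a redistribution of any published force field.",
  "entries": {
    "HOH": {
      "O":  {"charge": -0.82, "c6": 2617.0, "c12": 2634000.0, "vdw_radius": 1.52, "role": "both"},
      "H1": {"charge": 0.41, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2},
      "H2": {"charge": 0.41, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2}
    },
    "SOL": {
      "OW":  {"charge": -0.82, "c6": 2617.0, "c12": 2634000.0, "vdw_radius": 1.52, "role": "both"},
      "HW1": {"charge": 0.41, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2},
      "HW2": {"charge": 0.41, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2}
    },
    "NA": {"NA": {"charge": 1.0, "c6": 150.0, "c12": 80000.0, "vdw_radius": 1.16}},
    "CL": {"CL": {"charge": -1.0, "c6": 8000.0, "c12": 12000000.0, "vdw_radius": 1.9}},
    "ALA": {
      "N":  {"charge": -0.28, "c6": 2440.0, "c12": 1690000.0, "vdw_radius": 1.55, "role": "donor"},
      "H":  {"charge": 0.28, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2},
      "CA": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "CB": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "C":  {"charge": 0.38, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "O":  {"charge": -0.38, "c6": 2262.0, "c12": 1000000.0, "vdw_radius": 1.52, "role": "acceptor"}
    },
    "GLY": {
      "N":  {"charge": -0.28, "c6": 2440.0, "c12": 1690000.0, "vdw_radius": 1.55, "role": "donor"},
      "H":  {"charge": 0.28, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2},
      "CA": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "C":  {"charge": 0.38, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "O":  {"charge": -0.38, "c6": 2262.0, "c12": 1000000.0, "vdw_radius": 1.52, "role": "acceptor"}
    },
    "LYS": {
      "N":  {"charge": -0.28, "c6": 2440.0, "c12": 1690000.0, "vdw_radius": 1.55, "role": "donor"},
      "H":  {"charge": 0.28, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2},
      "CA": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "CB": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "CG": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "CD": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "CE": {"charge": 0.13, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "C":  {"charge": 0.38, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "O":  {"charge": -0.38, "c6": 2262.0, "c12": 1000000.0, "vdw_radius": 1.52, "role": "acceptor"},
      "NZ": {"charge": 0.33, "c6": 2440.0, "c12": 1690000.0, "vdw_radius": 1.55, "role": "donor"},
      "HZ1": {"charge": 0.18, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2},
      "HZ2": {"charge": 0.18, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2},
      "HZ3": {"charge": 0.18, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2}
    },
    "GLU": {
      "N":  {"charge": -0.28, "c6": 2440.0, "c12": 1690000.0, "vdw_radius": 1.55, "role": "donor"},
      "H":  {"charge": 0.28, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2},
      "CA": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "CB": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "CG": {"charge": -0.1, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "CD": {"charge": 0.3, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "C":  {"charge": 0.38, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "O":  {"charge": -0.38, "c6": 2262.0, "c12": 1000000.0, "vdw_radius": 1.52, "role": "acceptor"},
      "OE1": {"charge": -0.6, "c6": 2262.0, "c12": 1000000.0, "vdw_radius": 1.52, "role": "acceptor"},
      "OE2": {"charge": -0.6, "c6": 2262.0, "c12": 1000000.0, "vdw_radius": 1.52, "role": "acceptor"}
    },
    "LIG": {
      "C1": {"charge": 0.1, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "C2": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "C3": {"charge": 0.0, "c6": 2340.0, "c12": 3370000.0, "vdw_radius": 1.7},
      "N1": {"charge": -0.4, "c6": 2440.0, "c12": 1690000.0, "vdw_radius": 1.55, "role": "donor"},
      "O1": {"charge": -0.5, "c6": 2262.0, "c12": 1000000.0, "vdw_radius": 1.52, "role": "acceptor"},
      "H1": {"charge": 0.3, "c6": 0.0, "c12": 0.0, "vdw_radius": 1.2}
    }
  }
}
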