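{
  "version": 1,
  "description": "Default screening condition grids: the G4 targets, buffers, assays, ligand:G4 ratios, cell lines and exposure times most abundant in the modeling data. Sequences uniquely identify their oncogene/telomere target, so the target field is derived, not enumerated.",
  "targets": {
    "AGGGTTAGGGTTAGGGTTAGGG": "hTel",
    "GGGTTAGGGTTAGGGTTAGGG": "hTel",
    "TGAGGGTGGGTAGGGTGGGTAA": "cMYC",
    "GGGAGGGCGCTGGGAGGAGGG": "cKIT1",
    "GGGCGGGCGCGAGGGAGGGG": "cKIT2",
    "AGGGCGGTGTGGGAAGAGGGAAGAGGGGGAGG": "KRAS"
  },
  "models": {
    "selectivity": {
      "endpoint": "selectivity",
      "fields": ["sequence", "buffer", "assay"],
      "derived": {"oncogene": "sequence"},
      "grid": {
        "sequence": [
          "AGGGTTAGGGTTAGGGTTAGGG",
          "GGGTTAGGGTTAGGGTTAGGG",
          "TGAGGGTGGGTAGGGTGGGTAA",
          "GGGAGGGCGCTGGGAGGAGGG",
          "GGGCGGGCGCGAGGGAGGGG",
          "AGGGCGGTGTGGGAAGAGGGAAGAGGGGGAGG"
        ],
        "buffer": [
          "KCl 10 mM LiCl 90 mM Lithium Cacodylate (10 mM)",
          "NaCl 100 mM Lithium Cacodylate (10 mM)",
          "KCl 100 mM Lithium Cacodylate (10 mM)"
        ],
        "assay": ["FRET melting"]
      }
    },
    "interaction": {
      "endpoint": "Kd",
      "fields": ["sequence", "buffer"],
      "derived": {"oncogene": "sequence"},
      "grid": {
        "sequence": [
          "AGGGTTAGGGTTAGGGTTAGGG",
          "GGGTTAGGGTTAGGGTTAGGG",
          "TGAGGGTGGGTAGGGTGGGTAA",
          "GGGAGGGCGCTGGGAGGAGGG",
          "GGGCGGGCGCGAGGGAGGGG",
          "AGGGCGGTGTGGGAAGAGGGAAGAGGGGGAGG"
        ],
        "buffer": [
          "KCl 100 mM Lithium Cacodylate (10 mM)",
          "NaCl 35 mM KCl 50 mM Tween20 0.05% HEPES (10 mM)",
          "NaCl 100 mM Tris-HCl (50 mM)",
          "KCl 100 mM Tris-HCl (10 mM)"
        ]
      }
    },
    "stabilization": {
      "endpoint": "dTm",
      "fields": ["sequence", "buffer", "assay", "lgr"],
      "derived": {"oncogene": "sequence"},
      "grid": {
        "sequence": [
          "AGGGTTAGGGTTAGGGTTAGGG",
          "GGGTTAGGGTTAGGGTTAGGG",
          "TGAGGGTGGGTAGGGTGGGTAA",
          "GGGAGGGCGCTGGGAGGAGGG",
          "GGGCGGGCGCGAGGGAGGGG",
          "AGGGCGGTGTGGGAAGAGGGAAGAGGGGGAGG"
        ],
        "buffer": [
          "KCl 10 mM LiCl 90 mM Lithium Cacodylate (10 mM)",
          "NaCl 10 mM LiCl 90 mM Lithium Cacodylate (10 mM)"
        ],
        "assay": ["FRET melting"],
        "lgr": [5, 10]
      }
    },
    "cytotoxicity": {
      "endpoint": "IC50",
      "fields": ["cell_line", "exposure_time", "assay"],
      "derived": {},
      "grid": {
        "cell_line": ["HELA", "A549", "MCF7", "A375", "HCT116"],
        "exposure_time": [48, 72],
        "assay": ["MTT"]
      }
    }
  }
}
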