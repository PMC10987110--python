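{
  "note": "Approximate domain boundaries of the 860-residue LDL receptor (mature-protein numbering including the signal peptide). Ranges are an editable approximation assembled from UniProt P01130 feature annotation, not ground truth; edit to taste.",
  "protein_length": 860,
  "domains": [
    {"name": "signal peptide", "start": 1, "end": 21},
    {"name": "ligand binding", "start": 22, "end": 313},
    {"name": "EGF-A", "start": 314, "end": 353},
    {"name": "EGF-B", "start": 354, "end": 393},
    {"name": "beta-propeller", "start": 394, "end": 650},
    {"name": "EGF-C", "start": 651, "end": 693},
    {"name": "O-linked", "start": 694, "end": 767},
    {"name": "transmembrane", "start": 768, "end": 789},
    {"name": "cytosolic", "start": 790, "end": 860}
  ]
}
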