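[
  {"name": "Glycine", "smiles": "NCC(=O)O"},
  {"name": "Alanine", "smiles": "NC(C)C(=O)O"},
  {"name": "Valine", "smiles": "NC(C(C)C)C(=O)O"},
  {"name": "Leucine", "smiles": "NC(CC(C)C)C(=O)O"},
  {"name": "Isoleucine", "smiles": "NC(C(C)CC)C(=O)O"},
  {"name": "Proline", "smiles": "OC(=O)C1CCCN1"},
  {"name": "Phenylalanine", "smiles": "NC(Cc1ccccc1)C(=O)O"},
  {"name": "Tryptophan", "smiles": "NC(Cc1c[nH]c2ccccc12)C(=O)O"},
  {"name": "Methionine", "smiles": "NC(CCSC)C(=O)O"},
  {"name": "Serine", "smiles": "NC(CO)C(=O)O"},
  {"name": "Threonine", "smiles": "NC(C(O)C)C(=O)O"},
  {"name": "Cysteine", "smiles": "NC(CS)C(=O)O"},
  {"name": "Tyrosine", "smiles": "NC(Cc1ccc(O)cc1)C(=O)O"},
  {"name": "Asparagine", "smiles": "NC(CC(N)=O)C(=O)O"},
  {"name": "Glutamine", "smiles": "NC(CCC(N)=O)C(=O)O"},
  {"name": "Aspartate", "smiles": "NC(CC(O)=O)C(=O)O"},
  {"name": "Glutamate", "smiles": "NC(CCC(O)=O)C(=O)O"},
  {"name": "Lysine", "smiles": "NC(CCCCN)C(=O)O"},
  {"name": "Arginine", "smiles": "NC(CCCNC(N)=N)C(=O)O"},
  {"name": "Histidine", "smiles": "NC(Cc1c[nH]cn1)C(=O)O"}
]
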