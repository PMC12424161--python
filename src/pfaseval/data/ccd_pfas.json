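{
  "8PF": {"name": "perfluorooctanoic acid (PFOA)", "smiles": "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"},
  "4EI": {"name": "perfluoroheptanoic acid (PFHpA)", "smiles": "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"},
  "4I6": {"name": "perfluorononanoic acid (PFNA)", "smiles": "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"},
  "P8S": {"name": "perfluorooctanesulfonic acid (PFOS)", "smiles": "OS(=O)(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"},
  "TFA": {"name": "trifluoroacetic acid", "smiles": "OC(=O)C(F)(F)F"},
  "PFB": {"name": "perfluorobutanoic acid (PFBA)", "smiles": "OC(=O)C(F)(F)C(F)(F)C(F)(F)F"},
  "PFH": {"name": "perfluorohexanoic acid (PFHxA)", "smiles": "OC(=O)C(F)(F)C(F)(F)C(F)(F)C(F)(F)C(F)(F)F"}
}
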