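[
  {
    "name": "peptide bond from NH2",
    "pattern": "[NX3;H2,H1;!$([NX3][CX3]=[OX1]):1][H:2]",
    "delete": [2],
    "attach": 1,
    "standalone": true,
    "priority": 10
  },
  {
    "name": "peptide bond from C(=O)OH",
    "pattern": "[CX3:1](=[OX1:2])[OX2:3][H:4]",
    "delete": [3, 4],
    "attach": 1,
    "standalone": true,
    "priority": 10
  },
  {
    "name": "SH bond",
    "pattern": "[SX2:1][H:2]",
    "delete": [2],
    "attach": 1,
    "standalone": false,
    "priority": 1
  }
]
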