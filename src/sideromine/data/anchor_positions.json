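{
  "comment": "1-based positions in the reference numbering of the synthetic anchor; Stachelhaus = canonical pocket positions + invariant Lys517; extended (8 A) set is a superset of the Stachelhaus set",
  "stachelhaus_positions": [
    235,
    236,
    239,
    278,
    299,
    301,
    322,
    330,
    331,
    517
  ],
  "extended_positions": [
    217,
    218,
    228,
    235,
    236,
    239,
    240,
    243,
    244,
    250,
    259,
    262,
    278,
    299,
    301,
    311,
    322,
    330,
    331,
    345,
    356,
    365,
    375,
    391,
    392,
    415,
    449,
    463,
    465,
    466,
    474,
    481,
    508,
    517
  ]
}
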