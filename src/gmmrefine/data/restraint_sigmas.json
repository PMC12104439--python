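{
 "version": 1,
 "bond_sigma": {
  "C-C": 0.021,
  "C-N": 0.016,
  "C-O": 0.015,
  "C-S": 0.025,
  "O-P": 0.015,
  "N-P": 0.02,
  "O-S": 0.02,
  "default": 0.02
 },
 "bond_overrides": {
  "peptide_C-N": [
   1.329,
   0.014
  ],
  "phosphodiester_O3'-P": [
   1.607,
   0.015
  ]
 },
 "angle_sigma": {
  "default": 1.9
 },
 "angle_overrides": {
  "N-CA-C": 2.7,
  "inter_CA-C-N": [
   116.2,
   2.0
  ],
  "inter_O-C-N": [
   123.0,
   1.6
  ],
  "inter_C-N-CA": [
   121.7,
   1.8
  ],
  "inter_C-N-CD": [
   128.4,
   2.1
  ],
  "inter_C3'-O3'-P": [
   119.7,
   1.2
  ],
  "inter_O3'-P-O5'": [
   104.0,
   1.9
  ],
  "inter_O3'-P-OP1": [
   108.0,
   3.0
  ],
  "inter_O3'-P-OP2": [
   108.0,
   3.0
  ]
 }
}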