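{
 "version": 1,
 "radii": {
  "C": 1.7,
  "N": 1.55,
  "O": 1.4,
  "S": 1.8,
  "P": 1.8,
  "SE": 1.9,
  "H": 1.17,
  "H_POLAR": 1.0,
  "default": 1.7
 }
}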