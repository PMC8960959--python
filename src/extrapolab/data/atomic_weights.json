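{
  "H": 1.0080,
  "Li": 6.9400,
  "B": 10.8110,
  "C": 12.0110,
  "N": 14.0070,
  "O": 15.9990,
  "F": 18.9984,
  "Na": 22.9898,
  "Mg": 24.3050,
  "Al": 26.9815,
  "Si": 28.0850,
  "P": 30.9738,
  "S": 32.0600,
  "Cl": 35.4500,
  "K": 39.0983,
  "Ca": 40.0780,
  "Fe": 55.8450,
  "Zn": 65.3800,
  "As": 74.9216,
  "Se": 78.9710,
  "Br": 79.9040,
  "I": 126.9045
}
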