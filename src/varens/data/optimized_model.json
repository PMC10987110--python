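{
  "schema_version": 1,
  "weights": {
    "SIFT": 0.76,
    "PolyPhen-2": 1.38,
    "MLb-LDLr": 0.67,
    "MutationTaster": 0.91,
    "REVEL": 0.51,
    "VARITY": 1.82
  },
  "intercept": -3.43,
  "display_max": 7.0
}
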