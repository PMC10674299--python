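{
  "name": "PM_B",
  "target": "alpha2-ADR",
  "features": {
    "F1": "AroHyd",
    "F2": "AroHyd",
    "F3": "Don",
    "F4": "Acc"
  },
  "constraints": [
    {"pair": ["F1", "F2"], "distance": 4.48},
    {"pair": ["F3", "F4"], "distance": 2.19},
    {"pair": ["F3", "F1"], "distance": 5.72}
  ]
}
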