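{
  "name": "PM_A",
  "target": "hTAAR1",
  "features": {
    "F1": "Aro",
    "F2": "Hyd",
    "F3": "Hyd",
    "F4": "Hyd",
    "F5": "AroHyd",
    "F7": "Don",
    "F8": "Acc"
  },
  "constraints": [
    {"pair": ["F1", "F5"], "distance": 4.27},
    {"pair": ["F7", "F8"], "distance": 2.22},
    {"pair": ["F7", "F5"], "distance": 5.27},
    {"pair": ["F3", "F1"], "distance": 4.83},
    {"pair": ["F4", "F1"], "distance": 5.58},
    {"pair": ["F3", "F5"], "distance": 4.70},
    {"pair": ["F4", "F5"], "distance": 4.92}
  ],
  "note": "F2 is a flexible hydrophobic spacer with no published distance; it is a class-only slot."
}
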