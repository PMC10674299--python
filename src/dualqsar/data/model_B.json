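{
  "name": "model_B",
  "response": "pKi_alpha2ADR",
  "intercept": 7.00986,
  "coefficients": {
    "GCUT_SMR_1": 0.56459,
    "balabanJ": -1.49103,
    "E_tor": -0.02896,
    "Q_VSA_FHYD": 0.04376,
    "Q_VSA_PNEG": -0.08643,
    "Q_VSA_POL": 0.06695,
    "vsa_other": 0.02122,
    "SlogP_VSA3": 0.03314,
    "vsurf_ID1": 0.32188,
    "vsurf_ID7": 1.0442,
    "vsurf_IW4": 0.29374
  },
  "relative_importance": {
    "Q_VSA_PNEG": 1.0,
    "Q_VSA_POL": 0.795835,
    "SlogP_VSA3": 0.195358,
    "vsurf_ID7": 0.156047,
    "vsa_other": 0.102077,
    "vsurf_IW4": 0.1005,
    "E_tor": 0.098422,
    "balabanJ": 0.085904,
    "vsurf_ID1": 0.022599,
    "GCUT_SMR_1": 0.005108,
    "Q_VSA_FHYD": 0.001779
  },
  "negatively_related": ["Q_VSA_PNEG", "E_tor", "balabanJ"],
  "provenance": "published alpha2-adrenoreceptor binding-affinity equation (11 ISE-selected descriptors, PLS on 31 training compounds)"
}
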