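{
  "name": "model_A",
  "response": "pKi_hTAAR1",
  "intercept": 5.88651,
  "coefficients": {
    "GCUT_SMR_0": -0.78177,
    "E": -0.02455,
    "DipoleY": 2.02712,
    "DipoleZ": 0.80749,
    "DCASA": -0.00279,
    "Q_RPC-": -0.96171,
    "Q_VSA_FHYD": -1.76365,
    "SlogP_VSA4": 0.13838,
    "vsurf_EDmin1": -0.69487,
    "vsurf_IW5": 0.30105
  },
  "relative_importance": {
    "DipoleY": 1.0,
    "SlogP_VSA4": 0.810513,
    "DCASA": 0.582248,
    "E": 0.435867,
    "vsurf_IW5": 0.344589,
    "DipoleZ": 0.325382,
    "Q_VSA_FHYD": 0.31853,
    "vsurf_EDmin1": 0.29631,
    "Q_RPC-": 0.061043,
    "GCUT_SMR_0": 0.027644
  },
  "negatively_related": ["DCASA", "E", "Q_VSA_FHYD", "vsurf_EDmin1", "Q_RPC-", "GCUT_SMR_0"],
  "provenance": "published hTAAR1 binding-affinity equation (10 ISE-selected descriptors, PLS on 31 training compounds)"
}
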