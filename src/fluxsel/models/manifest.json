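{
  "family": "tca",
  "models": [
    "m1",
    "m2",
    "m3",
    "m4",
    "m5",
    "m6",
    "m7"
  ],
  "true_model": "m4",
  "true_fluxes_m4": {
    "PYRT": 1.0,
    "GLNT": 0.85,
    "PDH": 0.8,
    "CS": 0.7,
    "ACONT1m": 0.65,
    "ACONT2m_IDH": 0.6,
    "GLS": 0.85,
    "GDH": 0.85,
    "OGDH": 1.15,
    "FUMm": 1.1,
    "MDH": 0.9,
    "GOT": 0.2,
    "ASCm": 0.1,
    "GDH_rev": 0.2,
    "GLNS": 0.1,
    "ME": 0.15,
    "PYR_ef": 0.35,
    "CIT_ef": 0.05,
    "ACON_ef": 0.05,
    "AKG_ef": 0.1,
    "GLU_ef": 0.1,
    "GLN_ef": 0.1,
    "FUM_ef": 0.05,
    "MAL_ef": 0.05,
    "ASP_ef": 0.2,
    "AC_ef": 0.1
  },
  "normalized_flux": "PYRT",
  "additions": {
    "m2": [
      "GDH_rev"
    ],
    "m3": [
      "GLNS"
    ],
    "m4": [
      "ME"
    ],
    "m5": [
      "ME_rev"
    ],
    "m6": [
      "PC"
    ],
    "m7": [
      "ACE"
    ]
  },
  "estimation_tracers": [
    "U-13C-glutamine",
    "3-13C-pyruvate",
    "1,2-13C-glutamine"
  ],
  "validation_tracer": "U-13C-pyruvate",
  "true_polynomial_coefficients": [
    -0.3,
    -5.6,
    0.8,
    44.8,
    0.0,
    -89.6,
    0.0,
    51.2
  ],
  "true_linear_parameters": [
    10.0,
    5.0,
    2.0
  ]
}
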