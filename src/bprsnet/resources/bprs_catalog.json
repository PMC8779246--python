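{
  "scale": "Brief Psychiatric Rating Scale (18 items)",
  "K": 7,
  "items": [
    {"code": "SOM", "name": "Somatic concern", "group": "non-DSM"},
    {"code": "ANX", "name": "Anxiety", "group": "non-DSM"},
    {"code": "EMO", "name": "Emotional withdrawal", "group": "DSM"},
    {"code": "CON", "name": "Conceptual disorganization", "group": "DSM"},
    {"code": "GUI", "name": "Guilt feelings", "group": "non-DSM"},
    {"code": "TEN", "name": "Tension", "group": "non-DSM"},
    {"code": "MAN", "name": "Mannerism and posturing", "group": "DSM"},
    {"code": "GRA", "name": "Grandiosity", "group": "non-DSM"},
    {"code": "DEP", "name": "Depressive mood", "group": "non-DSM"},
    {"code": "HOS", "name": "Hostility", "group": "non-DSM"},
    {"code": "SUS", "name": "Suspiciousness", "group": "DSM"},
    {"code": "HAL", "name": "Hallucinatory behavior", "group": "DSM"},
    {"code": "MOT", "name": "Motor retardation", "group": "DSM"},
    {"code": "UNC", "name": "Uncooperativeness", "group": "non-DSM"},
    {"code": "THO", "name": "Unusual thought content", "group": "DSM"},
    {"code": "BLU", "name": "Blunted affect", "group": "DSM"},
    {"code": "EXC", "name": "Excitement", "group": "non-DSM"},
    {"code": "DIS", "name": "Disorientation", "group": "non-DSM"}
  ]
}
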