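{
  "description": "Published categorical counts describing the REAP-AP schizophrenia cohort (n = 1438); used to recompute the descriptive percentages of the cohort table.",
  "n": 1438,
  "counts": {
    "male": 830,
    "female": 608,
    "country_india": 400,
    "country_indonesia": 261,
    "country_japan": 98,
    "country_malaysia": 299,
    "country_taiwan": 380,
    "inpatient": 664,
    "unemployed": 237,
    "antipsychotic_polypharmacy": 536,
    "adjunctive_mood_stabilizer": 142,
    "adjunctive_antidepressant": 129,
    "adjunctive_antiparkinsonian": 560,
    "high_dose_antipsychotic": 161,
    "long_acting_injectable": 305,
    "clozapine": 293,
    "electroconvulsive_therapy": 42,
    "cannabis_use_lifetime": 119
  }
}
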