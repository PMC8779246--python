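{
  "description": "Published per-category response counts of the 18 BPRS items in the REAP-AP schizophrenia cohort (n = 1438). Categories run 1 ('not present') to 7 ('very severe').",
  "n": 1438,
  "K": 7,
  "counts": {
    "SOM": [840, 258, 199, 87, 37, 13, 4],
    "ANX": [596, 348, 290, 143, 44, 16, 1],
    "EMO": [511, 274, 294, 221, 85, 42, 11],
    "CON": [599, 251, 265, 176, 102, 32, 13],
    "GUI": [1016, 237, 140, 32, 7, 4, 2],
    "TEN": [656, 336, 286, 121, 31, 8, 0],
    "MAN": [1090, 148, 117, 56, 18, 9, 0],
    "GRA": [1107, 140, 97, 63, 14, 12, 5],
    "DEP": [804, 301, 233, 74, 14, 9, 3],
    "HOS": [807, 256, 169, 136, 47, 15, 8],
    "SUS": [587, 248, 269, 201, 81, 41, 11],
    "HAL": [530, 234, 259, 196, 118, 80, 21],
    "MOT": [898, 244, 158, 82, 37, 15, 4],
    "UNC": [814, 273, 182, 103, 38, 22, 6],
    "THO": [578, 239, 251, 181, 118, 54, 17],
    "BLU": [572, 285, 285, 162, 84, 43, 7],
    "EXC": [1001, 184, 113, 77, 49, 13, 1],
    "DIS": [1144, 162, 87, 30, 7, 3, 5]
  }
}
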