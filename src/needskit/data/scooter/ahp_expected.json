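{
  "description": "Published AHP results for the mobility-scooter case study: local weight columns, the comprehensive weight ranking, and the consistency-check table (values attached to matrices by dimension). Local weights for the 6x6 functional matrix were evidently computed by normalized-column arithmetic means.",
  "criterion_weights": {"O": 0.57143, "A": 0.14286, "M": 0.28571},
  "local_weights": {
    "A": {"A1": 0.42857, "A2": 0.14286, "A3": 0.42857},
    "M": {"M1": 0.5, "M2": 0.25, "M3": 0.125, "M4": 0.125},
    "O": {"O1": 0.04205, "O2": 0.19738, "O3": 0.07881, "O4": 0.3676, "O5": 0.28554, "O6": 0.02862}
  },
  "comprehensive": {
    "A1": {"weight": 0.0614, "rank": 7},
    "A2": {"weight": 0.0204, "rank": 12},
    "A3": {"weight": 0.0614, "rank": 6},
    "M1": {"weight": 0.1429, "rank": 3},
    "M2": {"weight": 0.0714, "rank": 5},
    "M3": {"weight": 0.0357, "rank": 9},
    "M4": {"weight": 0.0357, "rank": 10},
    "O1": {"weight": 0.024, "rank": 11},
    "O2": {"weight": 0.1131, "rank": 4},
    "O3": {"weight": 0.045, "rank": 8},
    "O4": {"weight": 0.2098, "rank": 1},
    "O5": {"weight": 0.1637, "rank": 2},
    "O6": {"weight": 0.0164, "rank": 13}
  },
  "consistency": {
    "criteria": {"n": 3, "CI": 0.0, "RI": 0.52, "CR": 0.0},
    "A": {"n": 3, "CI": 0.0, "RI": 0.52, "CR": 0.0},
    "M": {"n": 4, "CI": 0.0, "RI": 0.89, "CR": 0.0},
    "O": {"n": 6, "CI": 0.022, "RI": 1.26, "CR": 0.018}
  }
}
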