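{
  "description": "Older-adults mobility-scooter case study: per-requirement Kano category counts reconstructed exactly from the published percentage summary (denominator 32 respondents, or 17 for reverse-dominated requirements). The reported_si / reported_dsi columns reproduce the source report verbatim; note those two printed columns are transposed relative to the standard Better-Worse definitions SI=(A+O)/(A+O+M+I), DSI=-(O+M)/(A+O+M+I).",
  "requirements": {
    "A1": {"counts": {"A": 0, "O": 10, "M": 18, "I": 4, "R": 0, "Q": 0}, "reported_category": "M", "reported_si": 87.5, "reported_dsi": -31.25},
    "A2": {"counts": {"A": 0, "O": 14, "M": 15, "I": 3, "R": 0, "Q": 0}, "reported_category": "M", "reported_si": 90.63, "reported_dsi": -43.75},
    "A3": {"counts": {"A": 8, "O": 18, "M": 2, "I": 4, "R": 0, "Q": 0}, "reported_category": "O", "reported_si": 62.5, "reported_dsi": -81.25},
    "A4": {"counts": {"A": 0, "O": 1, "M": 1, "I": 6, "R": 9, "Q": 0}, "reported_category": "R", "reported_si": 25.0, "reported_dsi": -12.5},
    "M1": {"counts": {"A": 14, "O": 15, "M": 0, "I": 3, "R": 0, "Q": 0}, "reported_category": "O", "reported_si": 46.88, "reported_dsi": -90.63},
    "M2": {"counts": {"A": 20, "O": 11, "M": 0, "I": 1, "R": 0, "Q": 0}, "reported_category": "A", "reported_si": 34.3, "reported_dsi": -96.88},
    "M3": {"counts": {"A": 14, "O": 13, "M": 4, "I": 1, "R": 0, "Q": 0}, "reported_category": "A", "reported_si": 53.1, "reported_dsi": -84.38},
    "M4": {"counts": {"A": 11, "O": 14, "M": 5, "I": 2, "R": 0, "Q": 0}, "reported_category": "O", "reported_si": 59.3, "reported_dsi": -78.13},
    "M5": {"counts": {"A": 0, "O": 0, "M": 1, "I": 6, "R": 10, "Q": 0}, "reported_category": "R", "reported_si": 14.29, "reported_dsi": 0.0},
    "O1": {"counts": {"A": 3, "O": 7, "M": 18, "I": 4, "R": 0, "Q": 0}, "reported_category": "M", "reported_si": 78.1, "reported_dsi": -31.25},
    "O2": {"counts": {"A": 5, "O": 16, "M": 9, "I": 2, "R": 0, "Q": 0}, "reported_category": "O", "reported_si": 78.1, "reported_dsi": -65.63},
    "O3": {"counts": {"A": 5, "O": 12, "M": 9, "I": 6, "R": 0, "Q": 0}, "reported_category": "M", "reported_si": 65.6, "reported_dsi": -53.13},
    "O4": {"counts": {"A": 8, "O": 16, "M": 5, "I": 3, "R": 0, "Q": 0}, "reported_category": "O", "reported_si": 65.63, "reported_dsi": -75.0},
    "O5": {"counts": {"A": 4, "O": 17, "M": 8, "I": 3, "R": 0, "Q": 0}, "reported_category": "O", "reported_si": 78.13, "reported_dsi": -65.63},
    "O6": {"counts": {"A": 3, "O": 8, "M": 13, "I": 8, "R": 0, "Q": 0}, "reported_category": "M", "reported_si": 65.63, "reported_dsi": -34.38},
    "O7": {"counts": {"A": 0, "O": 1, "M": 1, "I": 1, "R": 14, "Q": 0}, "reported_category": "R", "reported_si": 66.67, "reported_dsi": -33.33}
  }
}
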