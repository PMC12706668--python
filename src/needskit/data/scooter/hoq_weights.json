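{
  "description": "Published house-of-quality base row for the mobility-scooter case study: the 13 technical features with their absolute weights (authoritative Develop-stage input; the published symbol grid is internally inconsistent with these totals and is kept as documentation only) and the published relative-weight percentages.",
  "features": [
    "Streamlined Design",
    "Modular Component Design",
    "Lightweight Vehicle Body",
    "Multi-Directional Steering Wheels",
    "Adjustable Safety Railings",
    "Flexible Skin-Friendly Materials",
    "Retractable Chassis",
    "Anti-Slip Surface Texture Design",
    "Warning Reflective Strip Design",
    "Emergency Braking Device",
    "Progressive Braking System",
    "Foldable Walking Cane",
    "Ergonomic Elastic Grip Design"
  ],
  "absolute_weights": [1.8098, 4.0797, 3.0141, 2.2805, 1.7331, 0.2603, 2.1747, 0.5969, 0.4182, 0.4998, 0.4998, 2.5757, 1.4786],
  "reported_percent": [8.45, 19.05, 14.07, 10.65, 8.09, 1.22, 10.15, 2.79, 1.95, 2.33, 2.33, 12.02, 6.9]
}
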