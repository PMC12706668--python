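# Need -> technical-feature expansion for the mobility-scooter case study.
# Consolidating in order of first occurrence yields the 13 HOQ feature columns.
A1:
  - Streamlined Design
  - Modular Component Design
  - Lightweight Vehicle Body
  - Multi-Directional Steering Wheels
A2:
  - Adjustable Safety Railings
  - Flexible Skin-Friendly Materials
A3:
  - Adjustable Safety Railings
  - Flexible Skin-Friendly Materials
  - Retractable Chassis
M1:
  - Multi-Directional Steering Wheels
  - Anti-Slip Surface Texture Design
  - Adjustable Safety Railings
  - Retractable Chassis
M2:
  - Warning Reflective Strip Design
  - Emergency Braking Device
M3:
  - Anti-Slip Surface Texture Design
  - Flexible Skin-Friendly Materials
M4:
  - Progressive Braking System
  - Anti-Slip Surface Texture Design
O1:
  - Retractable Chassis
  - Foldable Walking Cane
O2:
  - Multi-Directional Steering Wheels
  - Retractable Chassis
  - Foldable Walking Cane
  - Lightweight Vehicle Body
O3:
  - Retractable Chassis
  - Adjustable Safety Railings
  - Foldable Walking Cane
O4:
  - Ergonomic Elastic Grip Design
  - Adjustable Safety Railings
  - Lightweight Vehicle Body
  - Foldable Walking Cane
O5:
  - Lightweight Vehicle Body
  - Multi-Directional Steering Wheels
O6:
  - Lightweight Vehicle Body
  - Retractable Chassis
  - Foldable Walking Cane
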