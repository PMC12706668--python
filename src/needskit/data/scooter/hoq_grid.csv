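need,Streamlined Design,Modular Component Design,Lightweight Vehicle Body,Multi-Directional Steering Wheels,Adjustable Safety Railings,Flexible Skin-Friendly Materials,Retractable Chassis,Anti-Slip Surface Texture Design,Warning Reflective Strip Design,Emergency Braking Device,Progressive Braking System,Foldable Walking Cane,Ergonomic Elastic Grip Design
A1,●,△,,◎,,◎,△,◎,,,,,◎
A2,◎,,◎,△,,◎,,,△,,,●,△
A3,△,,,,△,,△,,,,,,●
M1,,,,●,◎,,,,,,,,
M2,,,,,●,,,●,●,△,△,,
M3,,,,●,,●,,●,,△,△,,
M4,,,,△,,,,,,●,●,,
O1,,△,△,,,,△,,,,,,
O2,◎,●,△,△,,,△,,,,,,
O3,◎,◎,◎,,,,,,,,,△,
O4,,,,,●,,,,,,,,●
O5,,◎,,●,,,△,,,,,,
O6,△,,●,,,,,,,,,●,
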