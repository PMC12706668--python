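# Older-adults mobility-scooter case study: three-level AHP hierarchy.
# Criterion layer: functional (O), emotional (A) and safety (M) needs,
# compared against the goal; one indicator matrix per criterion.
goal: "Older adults walking aid product"
criteria:
  labels: [O, A, M]
  matrix:
    - [1, 4, 2]
    - [0.25, 1, 0.5]
    - [0.5, 2, 1]
indicators:
  A:
    labels: [A1, A2, A3]
    matrix:
      - [1, 3, 1]
      - [0.333, 1, 0.333]
      - [1, 3, 1]
  M:
    labels: [M1, M2, M3, M4]
    matrix:
      - [1, 2, 4, 4]
      - [0.5, 1, 2, 2]
      - [0.25, 0.5, 1, 1]
      - [0.25, 0.5, 1, 1]
  O:
    labels: [O1, O2, O3, O4, O5, O6]
    matrix:
      - [1, 0.2, 0.5, 0.111, 0.125, 2]
      - [5, 1, 3, 0.5, 0.5, 8]
      - [2, 0.333, 1, 0.25, 0.25, 3]
      - [9, 2, 4, 1, 2, 9]
      - [8, 2, 4, 0.5, 1, 9]
      - [0.5, 0.125, 0.333, 0.111, 0.111, 1]
names:
  O: Functional needs
  A: Emotional needs
  M: Safety needs
  A1: Attractive and friendly form
  A2: Humanistic care
  A3: Comfortable human-machine dimensions
  M1: Structural stability
  M2: Safety protection
  M3: Anti-slip features
  M4: Brake mechanism
  O1: Foldability
  O2: Ease of use
  O3: Adjustable size
  O4: Adjustable safety guardrail
  O5: Flexible movement
  O6: Compact and lightweight
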