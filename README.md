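# needskit

Requirement prioritization for product design teams: a tested Python
implementation of the classic **Kano → AHP → QFD** chain that turns raw
questionnaire answers into a ranked list of technical features.

It is written for design researchers and engineers who run user-needs
studies — the bundled case study prioritizes design requirements for an
older-adults mobility scooter — but every stage is generic and works on any
requirement set.

## The methods

**Kano model.** Each respondent answers a functional ("feature present?")
and a dysfunctional ("feature absent?") question per requirement on a
5-point scale (Like … Dislike). The answer pair maps through a 5×5
evaluation table to one of six categories — Attractive (A), One-dimensional
(O), Must-be (M), Indifferent (I), Reverse (R), Questionable (Q). Each
requirement gets its modal category and the Better–Worse coefficients

```
SI  =  (A + O) / (A + O + M + I)        satisfaction index  ∈ [0, 1]
DSI = −(O + M) / (A + O + M + I)        dissatisfaction index ∈ [−1, 0]
```

Reverse-classified requirements are filtered out before weighting.

**AHP.** Retained requirements form a goal → criteria → indicators
hierarchy. Each node carries a reciprocal pairwise-comparison matrix on the
Saaty 1–9 scale; local weights are the normalized principal right
eigenvector **w** of the matrix (row geometric means and normalized-column
means are available as alternative estimators). Judgment consistency is
checked with CI = (λ_max − n)/(n − 1) and CR = CI/RI < 0.1. An indicator's
comprehensive weight is its criterion weight × local weight.

**QFD.** The house of quality relates need weights W_i to technical
features through symbol-coded relationship strengths P_ij
(● = 5, ◎ = 3, △ = 1, blank = 0):

```
W_j = Σ_i W_i · P_ij        absolute technical weight
W_k = W_j / Σ_j W_j         relative technical weight
```

Features are ranked by W_k.

## Worked example

```python
from needskit import ahp, datasets, kano, qfd

# 1. Kano screening of the 16 candidate requirements
summary = kano.summarize(datasets.load_kano_responses())
print("retained:", len(summary.retained), "excluded:", summary.excluded)
# retained: 13 excluded: ['A4', 'M5', 'O7']

# 2. AHP weighting of the retained requirements
result = ahp.synthesize(datasets.load_hierarchy())
print(result.table.sort_values("rank").head(3)[
    ["indicator", "indicator_name", "global_weight", "rank"]].round(4))
# indicator              indicator_name  global_weight  rank
#        O4 Adjustable safety guardrail         0.2122     1
#        O5           Flexible movement         0.1641     2
#        M1        Structural stability         0.1429     3

# 3. QFD translation to technical features
hoq = datasets.load_hoq_weights()
report = qfd.technical_weight_report(hoq["features"], hoq["absolute_weights"])
print(report.sort_values("rank").head(3)[["feature", "percent", "rank"]])
#                  feature  percent  rank
# Modular Component Design    19.05     1
# Lightweight Vehicle Body    14.07     2
#    Foldable Walking Cane    12.02     3
```

Reading: safety-guardrail adjustability carries a fifth of all requirement
weight, and translating the weighted needs through the house of quality
makes modular component design the top engineering priority (19.05 % of the
total technical weight).

A CLI mirrors the library (`needskit kano`, `ahp`, `qfd`, `pipeline`,
`simulate`, `case-study`); `needskit case-study` prints a full
computed-vs-published diff table for the bundled study.

Synthetic inputs for every stage — category-mixture questionnaires, noisy
reciprocal matrices around known weights, sparse random houses of quality —
come from `needskit.simulate`, all seeded and deterministic.

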