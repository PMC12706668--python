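# Methods

This note documents the models, the numerical choices, and the places where
the bundled case-study tables forced a decision.

## Kano stage

The evaluation table is the canonical 5×5 grid (functional answer × 
dysfunctional answer): a functional "Like" with dysfunctional "Dislike" is
One-dimensional; "Like"/"Like" and "Dislike"/"Dislike" are Questionable;
the first row below "Like" maps to Must-be against "Dislike", Indifferent
against the middle answers, Reverse against "Like". The table is
overridable (JSON/YAML) for non-standard instruments.

Per requirement we report category counts, fractions, the modal category,
and the Better–Worse coefficients SI = (A+O)/(A+O+M+I),
DSI = −(O+M)/(A+O+M+I). Reverse and Questionable answers are excluded from
the SI/DSI denominator — they express rejection or contradiction, not a
position on the satisfaction axis — but their fractions are still reported.
A requirement whose answers are all R/Q has undefined indices and raises a
degenerate-requirement error. If the Q rate exceeds 10 % a data-quality
warning is emitted (a common screening heuristic; the instrument itself is
probably misread).

Ties for the modal category are broken by the configurable priority
M > O > A > I > R > Q: when in doubt, treat a requirement as more basic
(safety-first). The retained-requirement filter drops modal-R requirements
by default; `exclude=("R", "I")` also drops indifferent ones.

Respondents missing either half of an answer pair contribute nothing for
that requirement (dropped at the I/O layer with a logged warning).

Useful algebraic identity, used as a property test:
SI − |DSI| = (A − M)/(A+O+M+I).

### Questionnaire QC

Cronbach's α uses sample (n−1) variances: α = k/(k−1)·(1 − Σs²ᵢ/s²_total);
zero total variance raises an undefined-α error. Bartlett's sphericity test
is χ² = −(n−1−(2k+5)/6)·ln|R| with df = k(k−1)/2; KMO is Σr²/(Σr²+Σp²)
over off-diagonals, with anti-image partial correlations taken from the
inverse correlation matrix (p_ij = −s_ij/√(s_ii s_jj), S = R⁻¹). A singular
correlation matrix yields a QC report without KMO. The case-study's raw
respondent-level answers were never published, so its α/KMO values are not
reproducible; these operations are provided as reusable QC tools and are
validated against independent oracles (pingouin for α, a residual-regression
partial-correlation computation for KMO).

## AHP stage

Three weight estimators are implemented:

- `eigenvector` (default): power iteration, uniform start, tolerance 1e-12
  on successive normalized iterates, max 10 000 iterations; λ_max from the
  converged Rayleigh quotient. On a perfectly consistent matrix
  (a_ij = w_i/w_j) it recovers w to machine precision in one step.
- `geometric_mean`: normalized row geometric means (log least squares).
- `column_normalization`: row means of the column-sum-normalized matrix —
  the traditional hand calculation, and the estimator whose output matches
  the case study's published 6×6 weight column to all printed decimals
  (the eigenvector differs from that column in the third decimal, so the
  published regression checks use `column_normalization`; all three
  estimators coincide to ≤1e-10 on consistent matrices).

Consistency: CI = (λ_max − n)/(n − 1), CR = CI/RI, pass iff CR < 0.1. The
default random-index table is {3: 0.52, 4: 0.89, 5: 1.12, 6: 1.26, 7: 1.36,
8: 1.41, 9: 1.46, 10: 1.49} with RI = 0 (hence CR ≡ 0) for n ≤ 2; it is
fully configurable. Synthesis multiplies criterion weight by local weight;
comprehensive weights therefore sum to 1 whenever each layer's weights do.
Ranks are descending by weight with ties broken by ascending indicator
label — for exactly tied weights any order is equally defensible, so tests
compare tied groups as sets.

### Parsing judgments

Printed matrices carry display-rounded reciprocals (0.333 for 1/3, 0.111
for 1/9). The parser accepts |a_ij·a_ji − 1| ≤ 0.05 and, by default,
canonicalizes each pair to exact reciprocity taking the entry ≥ 1 — the
recorded integer judgment — as authoritative. `repair=False` keeps entries
verbatim (validation only). `snap_to_saaty` rounds judgments to the nearest
admissible scale value in log space.

The case-study fixture stores the matrices verbatim as published.
`load_hierarchy(exact=True)` (default) snaps them to exact Saaty fractions,
which reproduces every published weight column; `exact=False` keeps the
rounded decimals, which is the only way the published CI of the 6×6 matrix
(0.022) reproduces — on the exact-fraction matrix λ_max is 6.1126 and CI is
0.0225. Evidently the source computed weights on exact fractions but
consistency on the rounded display values; the regression suite therefore
checks each against the matrix variant that generated it.

## QFD stage

The default symbol scale is ● = 5, ◎ = 3, △ = 1, blank = 0 (a 1–3–9
dialect is provided; any mapping is accepted). ASCII aliases S/M/W are read
alongside the unicode symbols. Absolute weights are W_j = Σ_i W_i·P_ij,
relative weights W_k = W_j/ΣW_j; percentages are half-up rounded to two
decimals at the report layer only — internal values stay full precision.
The feature list is the deduplicated (first-occurrence order) expansion of
the need→feature map; ranking is descending by W_k with label-order
tie-breaks.

The published symbol grid of the case study cannot regenerate the published
absolute weights (recomputing the first feature column from the printed
symbols and weights gives 0.92 against a printed 1.81; the grid appears
column-shifted in transcription). The fixture therefore treats the
published absolute-weight vector as the authoritative Develop-stage input —
it reproduces the published relative-percent row and ranking exactly — and
keeps the symbol grid for documentation and structural tests. The Eq. W_j
summation path is validated against a naive double-loop oracle on seeded
random houses instead. The HOQ roof (feature–feature correlations) is out
of scope: no correlation data exist for this study and the roof plays no
part in the weight translation.

## Synthetic data

Generators emulate the statistical structure of each stage's input, with a
single seeded `numpy.random.Generator` per call and no global state:

- **Kano**: per requirement a category mixture over {A,O,M,I,R,Q}; per
  respondent a category is drawn, then an answer pair uniformly from the
  evaluation-table cells of that category (many-to-one for I, A, M, R —
  uniformity documented so tests can reason about answer marginals).
- **Pairwise matrices**: a_ij = (w_i/w_j)·exp(ε), ε ~ N(0, σ²) on the upper
  triangle, exact reciprocals below; σ = 0 gives a perfectly consistent
  matrix; optional log-space snapping to the Saaty scale preserves
  reciprocity by construction.
- **HOQ**: Dirichlet-like (normalized gamma) need weights and a sparse
  strength matrix at a requested density with at least one nonzero cell per
  need row.

What the generators do *not* model: respondent demographics, item
non-response patterns, acquiescence bias, or correlated judgments across
experts. Passing recovery tests therefore shows the estimators invert the
assumed generative models, not that real panels satisfy those models.

## Problem sizes and determinism

All bundled-study computations are desk scale (16 requirements × ≤32
respondents, matrices up to 6×6, 13×13 HOQ) and run in well under a second.
Property tests use 100–1000 seeded repetitions for oracle and range checks
and n = 10 000 respondents for the law-of-large-numbers recovery check;
hypothesis tests are seeded/derandomized. Every pipeline run with a fixed
config and seed is bit-reproducible in its numeric fields.

## Known limitations

- Single-matrix AHP only: no aggregation of multiple expert judgments
  (the case study publishes consensus matrices), no fuzzy AHP, no ANP.
- The Kano engine is the discrete-category variant; no continuous/fuzzy
  Kano scoring.
- Three case-study cells are internally inconsistent with their own inputs
  and are left as failing regression checks rather than special-cased: one
  published classification (O3) disagrees with the modal category of its
  own fractions, one comprehensive weight (O5) disagrees with the product
  of its published factors under every estimator, and the two exactly tied
  indicator pairs have no defined mutual rank order.
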