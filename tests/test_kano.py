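"""Kano classification, tabulation and Better–Worse statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from needskit import kano
from needskit.kano import (
    AnswerScale,
    Category,
    DegenerateRequirementError,
    EvaluationTable,
    KanoResponse,
    assign_category,
    better_worse,
    classify_pair,
    parse_answer,
    stats_from_counts,
    summarize,
    tabulate_requirement,
)

# raw evaluation grid used as an independent lookup in oracle checks,
# row = functional 1..5, column = dysfunctional 1..5
RAW_GRID = ["QRRRR", "MIIIR", "MIIIR", "MIIIR", "OAAAQ"]


@pytest.mark.parametrize(
    "functional, dysfunctional, expected",
    [
        (AnswerScale.LIKE, AnswerScale.DISLIKE, Category.ONE_DIMENSIONAL),
        (AnswerScale.MUST_BE, AnswerScale.DISLIKE, Category.MUST_BE),
        (AnswerScale.LIKE, AnswerScale.LIKE, Category.QUESTIONABLE),
        (AnswerScale.NEUTRAL, AnswerScale.NEUTRAL, Category.INDIFFERENT),
        ("like", "live with", Category.ATTRACTIVE),
        (1, 2, Category.REVERSE),
    ],
)
def test_classify_pair(functional, dysfunctional, expected):
    assert classify_pair(functional, dysfunctional) is expected


def test_classify_pair_total_over_all_cells(eval_table):
    """Every one of the 25 answer pairs maps to a category, matching the raw grid."""
    for f in range(1, 6):
        for d in range(1, 6):
            assert eval_table.classify(f, d).value == RAW_GRID[f - 1][d - 1]


@pytest.mark.parametrize("bad", [0, 6, "meh", None])
def test_answer_scale_rejects_out_of_range(bad):
    with pytest.raises((ValueError, TypeError)):
        parse_answer(bad)


def test_evaluation_table_requires_all_cells():
    cells = {(f, d): "I" for f in range(1, 6) for d in range(1, 6)}
    del cells[(3, 3)]
    with pytest.raises(ValueError, match="incomplete"):
        EvaluationTable(cells)


def _make_responses(rid, spec):
    """spec: list of (count, functional, dysfunctional)."""
    out = []
    k = 0
    for count, f, d in spec:
        for _ in range(count):
            out.append(KanoResponse(f"r{k}", rid, f, d))
            k += 1
    return out


def test_tabulate_requirement_fractions():
    responses = _make_responses("A1", [(10, 5, 1), (18, 2, 1), (4, 3, 3)])
    stats = tabulate_requirement(responses)
    frac = stats.fractions
    assert stats.n == 32
    assert frac[Category.ONE_DIMENSIONAL] == pytest.approx(0.3125)
    assert frac[Category.MUST_BE] == pytest.approx(0.5625)
    assert frac[Category.INDIFFERENT] == pytest.approx(0.125)
    assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)


def test_tabulate_requirement_errors():
    with pytest.raises(ValueError, match="no responses"):
        tabulate_requirement([])
    mixed = [KanoResponse("r0", "A1", 5, 1), KanoResponse("r1", "A2", 5, 1)]
    with pytest.raises(ValueError, match="mix"):
        tabulate_requirement(mixed)


def test_single_response_is_its_own_category():
    stats = tabulate_requirement([KanoResponse("r0", "X", 5, 1)])
    assert stats.fractions[Category.ONE_DIMENSIONAL] == 1.0
    assert assign_category(stats) is Category.ONE_DIMENSIONAL


def test_assign_category_modal_and_tie_break():
    stats = stats_from_counts("A1", {"O": 10, "M": 18, "I": 4})
    assert stats.category is Category.MUST_BE
    # M2-like profile: attractive majority
    stats = stats_from_counts("M2", {"A": 20, "O": 11, "I": 1})
    assert stats.category is Category.ATTRACTIVE
    # exact tie resolved by the safety-first priority M > O > A > I > R > Q
    tie = stats_from_counts("T", {"A": 16, "M": 16})
    assert tie.category is Category.MUST_BE
    # custom ordering flips the tie
    alt = kano.RequirementStats("T", {Category.ATTRACTIVE: 16, Category.MUST_BE: 16})
    assert assign_category(alt, tie_break=("A", "O", "M", "I", "R", "Q")) is Category.ATTRACTIVE


def test_better_worse_values():
    stats = stats_from_counts("A3", {"A": 8, "O": 18, "M": 2, "I": 4})
    assert stats.si == pytest.approx(0.8125)
    assert stats.dsi == pytest.approx(-0.625)
    all_i = stats_from_counts("X", {"I": 7})
    assert (all_i.si, all_i.dsi) == (0.0, 0.0)
    all_o = stats_from_counts("Y", {"O": 5})
    assert (all_o.si, all_o.dsi) == (1.0, -1.0)


def test_better_worse_degenerate():
    stats = kano.RequirementStats("Z", {Category.REVERSE: 3, Category.QUESTIONABLE: 1})
    with pytest.raises(DegenerateRequirementError):
        better_worse(stats)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    counts=st.fixed_dictionaries(
        {c.value: st.integers(min_value=0, max_value=50) for c in Category}
    )
)
def test_better_worse_ranges_and_identity(counts):
    """SI in [0,1], DSI in [-1,0], and SI - |DSI| = (A - M)/(A+O+M+I)."""
    if sum(counts.values()) == 0:
        counts["I"] = 1
    stats = kano.RequirementStats("P", {Category(k): v for k, v in counts.items()})
    a, o, m, i = (counts["A"], counts["O"], counts["M"], counts["I"])
    if a + o + m + i == 0:
        with pytest.raises(DegenerateRequirementError):
            better_worse(stats)
        return
    si, dsi = better_worse(stats)
    assert 0.0 <= si <= 1.0
    assert -1.0 <= dsi <= 0.0
    assert si - abs(dsi) == pytest.approx((a - m) / (a + o + m + i), abs=1e-12)
    assert sum(stats.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_summary_matches_brute_force_oracle(rng):
    """Category counts equal a naive per-response loop over the raw grid."""
    rows = []
    for r in range(40):
        for rid in ["a", "b", "c"]:
            f, d = rng.integers(1, 6), rng.integers(1, 6)
            rows.append((f"r{r}", rid, int(f), int(d)))
    df = pd.DataFrame(rows, columns=["respondent_id", "requirement_id", "functional", "dysfunctional"])
    import warnings as _warnings

    with _warnings.catch_warnings():
        # uniform random answers can trip the Q-rate guard; irrelevant here
        _warnings.simplefilter("ignore", kano.DataQualityWarning)
        summary = summarize(df)
    for rid, group in df.groupby("requirement_id"):
        naive = {c.value: 0 for c in Category}
        for _, row in group.iterrows():
            naive[RAW_GRID[row.functional - 1][row.dysfunctional - 1]] += 1
        n = len(group)
        for cat, cnt in naive.items():
            assert summary.table.loc[rid, cat] == pytest.approx(cnt / n)


def test_summary_permutation_invariant(kano_responses):
    base = summarize(kano_responses)
    shuffled = kano_responses.sample(frac=1.0, random_state=7).reset_index(drop=True)
    pd.testing.assert_frame_equal(
        base.table.sort_index(), summarize(shuffled).table.sort_index()
    )


def test_case_study_retention(kano_responses):
    """Three reverse-classified requirements are dropped, 13 of 16 retained."""
    summary = summarize(kano_responses)
    assert sorted(summary.excluded) == ["A4", "M5", "O7"]
    assert len(summary.retained) == 13


def test_exclusion_set_configurable(kano_responses):
    summary = summarize(kano_responses, exclude=("R", "I"))
    assert len(summary.retained) == 13  # the case study has no modal-I requirement
    single = summarize([KanoResponse("r0", "solo", 5, 1)])
    assert single.retained == ["solo"]


def test_scatter_coordinates(kano_responses):
    summary = summarize(kano_responses)
    merged = summary.scatter.set_index("requirement_id").join(summary.table)
    assert np.allclose(merged["x"], merged["DSI"].abs())
    assert np.allclose(merged["y"], merged["SI"])


def test_q_rate_guard_warns():
    responses = _make_responses("q", [(3, 5, 5), (7, 5, 1)])
    with pytest.warns(kano.DataQualityWarning, match="Questionable"):
        tabulate_requirement(responses)
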