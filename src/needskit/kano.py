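"""Kano-model classification of product requirements.

The Kano model sorts product requirements by how their presence or absence
drives user satisfaction.  Each respondent answers a *functional* question
("how do you feel if the feature is present?") and a *dysfunctional* question
("... if it is absent?") on a five-level scale.  The answer pair is looked up
in a 5x5 evaluation table yielding one of six categories:

- ``A`` attractive — delighters; absence does not hurt, presence pleases
- ``O`` one-dimensional — satisfaction scales with performance
- ``M`` must-be — expected basics; absence actively dissatisfies
- ``I`` indifferent — no effect either way
- ``R`` reverse — users prefer the feature absent
- ``Q`` questionable — contradictory answer pair

Per-requirement category counts are summarized by the modal category and the
Better–Worse coefficients

    SI  =  (A + O) / (A + O + M + I)          satisfaction index, in [0, 1]
    DSI = -(O + M) / (A + O + M + I)          dissatisfaction index, in [-1, 0]

where the letters denote category counts (R and Q are excluded from the
denominator).
"""

from __future__ import annotations

import enum
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AnswerScale",
    "Category",
    "EvaluationTable",
    "KanoResponse",
    "RequirementStats",
    "KanoSummary",
    "DegenerateRequirementError",
    "DataQualityWarning",
    "DEFAULT_TIE_BREAK",
    "classify_pair",
    "tabulate_requirement",
    "assign_category",
    "better_worse",
    "stats_from_counts",
    "summarize",
    "parse_answer",
]


class AnswerScale(enum.IntEnum):
    """Five-level Kano answer scale."""

    DISLIKE = 1
    LIVE_WITH = 2
    NEUTRAL = 3
    MUST_BE = 4
    LIKE = 5


_ANSWER_ALIASES: dict[str, AnswerScale] = {
    "dislike": AnswerScale.DISLIKE,
    "live with": AnswerScale.LIVE_WITH,
    "live-with": AnswerScale.LIVE_WITH,
    "live_with": AnswerScale.LIVE_WITH,
    "neutral": AnswerScale.NEUTRAL,
    "must be": AnswerScale.MUST_BE,
    "must-be": AnswerScale.MUST_BE,
    "must_be": AnswerScale.MUST_BE,
    "like": AnswerScale.LIKE,
}


def parse_answer(value: int | str | AnswerScale) -> AnswerScale:
    """Coerce an integer code 1–5 or a canonical label to :class:`AnswerScale`."""
    if isinstance(value, AnswerScale):
        return value
    if isinstance(value, str):
        key = value.strip().lower()
        if key in _ANSWER_ALIASES:
            return _ANSWER_ALIASES[key]
        try:
            value = int(key)
        except ValueError:
            raise ValueError(f"unrecognized answer label: {value!r}") from None
    try:
        return AnswerScale(int(value))
    except ValueError:
        raise ValueError(f"answer must be on the 1–5 scale, got {value!r}") from None


class Category(str, enum.Enum):
    """Six exhaustive, mutually exclusive Kano categories."""

    ATTRACTIVE = "A"
    ONE_DIMENSIONAL = "O"
    MUST_BE = "M"
    INDIFFERENT = "I"
    REVERSE = "R"
    QUESTIONABLE = "Q"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CATEGORIES: tuple[Category, ...] = tuple(Category)

#: Modal-category tie-break priority: safety-critical categories first.
DEFAULT_TIE_BREAK: tuple[Category, ...] = (
    Category.MUST_BE,
    Category.ONE_DIMENSIONAL,
    Category.ATTRACTIVE,
    Category.INDIFFERENT,
    Category.REVERSE,
    Category.QUESTIONABLE,
)

# Canonical evaluation grid, row = functional answer, column = dysfunctional
# answer, both ordered Dislike..Like (1..5).
_DEFAULT_GRID = {
    1: "QRRRR",
    2: "MIIIR",
    3: "MIIIR",
    4: "MIIIR",
    5: "OAAAQ",
}


class EvaluationTable:
    """The 25-cell (functional x dysfunctional) -> category lookup table."""

    def __init__(self, cells: Mapping[tuple[int, int], Category | str]):
        parsed: dict[tuple[AnswerScale, AnswerScale], Category] = {}
        for (f, d), cat in cells.items():
            parsed[(parse_answer(f), parse_answer(d))] = Category(cat)
        missing = [
            (f, d)
            for f in AnswerScale
            for d in AnswerScale
            if (f, d) not in parsed
        ]
        if missing:
            raise ValueError(f"evaluation table incomplete: {len(missing)} cells missing")
        self._cells = parsed

    @classmethod
    def default(cls) -> "EvaluationTable":
        cells = {
            (f, d): Category(_DEFAULT_GRID[f][d - 1])
            for f in range(1, 6)
            for d in range(1, 6)
        }
        return cls(cells)

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "EvaluationTable":
        """Build from a nested ``{functional: {dysfunctional: code}}`` mapping."""
        cells = {}
        for f, row in mapping.items():
            for d, cat in row.items():
                cells[(int(f), int(d))] = Category(cat)
        return cls(cells)

    def classify(self, functional, dysfunctional) -> Category:
        f = parse_answer(functional)
        d = parse_answer(dysfunctional)
        return self._cells[(f, d)]

    def cells_for(self, category: Category | str) -> list[tuple[AnswerScale, AnswerScale]]:
        """All (functional, dysfunctional) pairs mapping to *category*."""
        cat = Category(category)
        return sorted((fd for fd, c in self._cells.items() if c is cat))

    def to_dict(self) -> dict[int, dict[int, str]]:
        out: dict[int, dict[int, str]] = {}
        for (f, d), cat in sorted(self._cells.items()):
            out.setdefault(int(f), {})[int(d)] = cat.value
        return out


def classify_pair(functional, dysfunctional, table: EvaluationTable | None = None) -> Category:
    """Classify one functional/dysfunctional answer pair."""
    table = table or EvaluationTable.default()
    return table.classify(functional, dysfunctional)


@dataclass(frozen=True)
class KanoResponse:
    """One respondent's paired answers for one requirement."""

    respondent_id: str
    requirement_id: str
    functional: AnswerScale
    dysfunctional: AnswerScale

    def __post_init__(self):
        if not str(self.requirement_id):
            raise ValueError("requirement_id must be non-empty")
        object.__setattr__(self, "functional", parse_answer(self.functional))
        object.__setattr__(self, "dysfunctional", parse_answer(self.dysfunctional))


class DegenerateRequirementError(ValueError):
    """Raised when every answer is Reverse/Questionable and SI/DSI are undefined."""


class DataQualityWarning(UserWarning):
    """Emitted when a requirement's responses look unreliable (high Q rate)."""


#: Q-rate above which a data-quality warning is emitted.
Q_RATE_GUARD = 0.1


@dataclass
class RequirementStats:
    """Per-requirement category counts, fractions, modal category and SI/DSI."""

    requirement_id: str
    counts: dict[Category, int]
    category: Category | None = None
    si: float | None = None
    dsi: float | None = None

    def __post_init__(self):
        self.counts = {c: int(self.counts.get(c, 0)) for c in CATEGORIES}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError(f"requirement {self.requirement_id!r} has no responses")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[Category, float]:
        n = self.n
        return {c: v / n for c, v in self.counts.items()}


def tabulate_requirement(
    responses: Sequence[KanoResponse], table: EvaluationTable | None = None
) -> RequirementStats:
    """Count categories over all responses to a single requirement.

    Raises on an empty response list or mixed requirement ids; warns when the
    Questionable rate exceeds the guard threshold.
    """
    if not responses:
        raise ValueError("no responses supplied")
    rid = responses[0].requirement_id
    if any(r.requirement_id != rid for r in responses):
        raise ValueError("responses mix multiple requirement_ids")
    table = table or EvaluationTable.default()
    counts = Counter(table.classify(r.functional, r.dysfunctional) for r in responses)
    stats = RequirementStats(rid, dict(counts))
    if stats.fractions[Category.QUESTIONABLE] > Q_RATE_GUARD:
        warnings.warn(
            f"requirement {rid!r}: Questionable rate "
            f"{stats.fractions[Category.QUESTIONABLE]:.0%} exceeds {Q_RATE_GUARD:.0%}",
            DataQualityWarning,
            stacklevel=2,
        )
    return stats


def assign_category(
    stats: RequirementStats, tie_break: Sequence[Category | str] = DEFAULT_TIE_BREAK
) -> Category:
    """Modal category of the counts; ties resolved by *tie_break* priority."""
    order = [Category(c) for c in tie_break]
    if set(order) != set(CATEGORIES):
        raise ValueError("tie_break must order all six categories")
    best = max(stats.counts.values())
    return next(c for c in order if stats.counts[c] == best)


def better_worse(stats: RequirementStats) -> tuple[float, float]:
    """Better–Worse coefficients (SI, DSI) from category counts.

    R and Q responses are excluded from the denominator; if nothing else
    remains the indices are undefined and a
    :class:`DegenerateRequirementError` is raised.
    """
    c = stats.counts
    a, o, m, i = (
        c[Category.ATTRACTIVE],
        c[Category.ONE_DIMENSIONAL],
        c[Category.MUST_BE],
        c[Category.INDIFFERENT],
    )
    denom = a + o + m + i
    if denom == 0:
        raise DegenerateRequirementError(
            f"requirement {stats.requirement_id!r}: all answers Reverse/Questionable"
        )
    return (a + o) / denom, -(o + m) / denom


def stats_from_counts(
    requirement_id: str,
    counts: Mapping[Category | str, int],
    tie_break: Sequence[Category | str] = DEFAULT_TIE_BREAK,
) -> RequirementStats:
    """Build fully-populated stats straight from category counts."""
    stats = RequirementStats(requirement_id, {Category(k): v for k, v in counts.items()})
    stats.category = assign_category(stats, tie_break)
    try:
        stats.si, stats.dsi = better_worse(stats)
    except DegenerateRequirementError:
        stats.si = stats.dsi = None
    return stats


@dataclass
class KanoSummary:
    """Result of a whole-questionnaire Kano analysis."""

    table: pd.DataFrame
    retained: list[str]
    excluded: list[str]
    scatter: pd.DataFrame = field(repr=False, default=None)


def _iter_responses(responses) -> list[KanoResponse]:
    if isinstance(responses, pd.DataFrame):
        return [
            KanoResponse(
                str(row.respondent_id),
                str(row.requirement_id),
                row.functional,
                row.dysfunctional,
            )
            for row in responses.itertuples(index=False)
        ]
    return list(responses)


def summarize(
    responses: pd.DataFrame | Iterable[KanoResponse],
    table: EvaluationTable | None = None,
    exclude: Iterable[Category | str] = (Category.REVERSE,),
    tie_break: Sequence[Category | str] = DEFAULT_TIE_BREAK,
) -> KanoSummary:
    """Per-requirement Kano statistics plus the retained-requirement filter.

    Parameters
    ----------
    responses
        Long-format response table (columns ``respondent_id``,
        ``requirement_id``, ``functional``, ``dysfunctional``) or an iterable
        of :class:`KanoResponse`.
    exclude
        Categories whose requirements are dropped from the retained list
        (default: Reverse only; pass ``("R", "I")`` to also drop indifferent
        requirements).

    Returns
    -------
    KanoSummary
        ``table`` has one row per requirement with category fractions,
        respondent count, modal category, SI and DSI; ``scatter`` holds the
        Better–Worse coordinates (x = |DSI|, y = SI) for plotting.
    """
    table = table or EvaluationTable.default()
    exclude_set = {Category(c) for c in exclude}
    groups: dict[str, list[KanoResponse]] = {}
    for r in _iter_responses(responses):
        groups.setdefault(r.requirement_id, []).append(r)
    if not groups:
        raise ValueError("no responses supplied")

    rows, scatter_rows, retained, dropped = [], [], [], []
    for rid, group in groups.items():
        stats = tabulate_requirement(group, table)
        stats.category = assign_category(stats, tie_break)
        try:
            stats.si, stats.dsi = better_worse(stats)
        except DegenerateRequirementError:
            stats.si = stats.dsi = None
        frac = stats.fractions
        rows.append(
            {
                "requirement_id": rid,
                **{c.value: frac[c] for c in CATEGORIES},
                "n": stats.n,
                "category": stats.category.value,
                "SI": stats.si,
                "DSI": stats.dsi,
            }
        )
        if stats.si is not None:
            scatter_rows.append(
                {"requirement_id": rid, "x": abs(stats.dsi), "y": stats.si}
            )
        (dropped if stats.category in exclude_set else retained).append(rid)

    summary = pd.DataFrame(rows).set_index("requirement_id")
    scatter = pd.DataFrame(scatter_rows, columns=["requirement_id", "x", "y"])
    return KanoSummary(table=summary, retained=retained, excluded=dropped, scatter=scatter)
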