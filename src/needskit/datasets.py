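"""Bundled case-study dataset: older-adults mobility-scooter requirements.

The package ships the complete desk-scale dataset of a published-style design
study — Kano questionnaire category counts for 16 candidate requirements, a
three-level AHP hierarchy with expert pairwise matrices, and a house-of-quality
feature set — so the whole pipeline runs and can be regression-checked without
any external data.

Caveats carried by the source tables (documented in the fixture files
themselves): the reported SI/DSI columns are transposed relative to the
standard Better–Worse definitions, one reported classification (O3) does not
match the modal category of its own fractions, and the published HOQ symbol
grid does not regenerate the published absolute weights — the absolute-weight
vector is therefore the authoritative Develop-stage input.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd
import yaml

from .ahp import Hierarchy, PairwiseMatrix, snap_to_saaty
from .kano import CATEGORIES, Category, EvaluationTable, stats_from_counts

__all__ = [
    "load_kano_counts",
    "load_kano_responses",
    "load_hierarchy",
    "load_ahp_expected",
    "load_hoq_weights",
    "load_hoq_grid",
    "load_feature_map",
]

_PKG = "needskit.data.scooter"


def _read_text(name: str) -> str:
    return resources.files(_PKG).joinpath(name).read_text(encoding="utf-8")


def load_kano_counts() -> pd.DataFrame:
    """Per-requirement Kano category counts plus the reported summary columns.

    Columns: counts ``A O M I R Q``, ``n``, and the source report's
    ``reported_category`` / ``reported_si`` / ``reported_dsi`` (percent scale;
    see the module docstring for the SI/DSI transposition caveat).
    """
    raw = json.loads(_read_text("kano_counts.json"))["requirements"]
    rows = []
    for rid, rec in raw.items():
        rows.append(
            {
                "requirement_id": rid,
                **rec["counts"],
                "n": sum(rec["counts"].values()),
                "reported_category": rec["reported_category"],
                "reported_si": rec["reported_si"],
                "reported_dsi": rec["reported_dsi"],
            }
        )
    return pd.DataFrame(rows).set_index("requirement_id")


#: Canonical answer pair used when expanding counts to respondent level.
_CANONICAL_CELL = {
    Category.ONE_DIMENSIONAL: (5, 1),
    Category.ATTRACTIVE: (5, 2),
    Category.MUST_BE: (2, 1),
    Category.INDIFFERENT: (3, 3),
    Category.REVERSE: (1, 2),
    Category.QUESTIONABLE: (1, 1),
}


def load_kano_responses() -> pd.DataFrame:
    """Deterministic respondent-level expansion of the category counts.

    Each classified response is materialized as a canonical answer pair of
    its category, so re-tabulating through the evaluation table reproduces
    the stored counts exactly.
    """
    counts = load_kano_counts()
    table = EvaluationTable.default()
    rows = []
    for rid, row in counts.iterrows():
        k = 0
        for cat in CATEGORIES:
            f, d = _CANONICAL_CELL[cat]
            assert table.classify(f, d) is cat
            for _ in range(int(row[cat.value])):
                rows.append((f"resp{k:03d}", rid, f, d))
                k += 1
    return pd.DataFrame(
        rows, columns=["respondent_id", "requirement_id", "functional", "dysfunctional"]
    )


def load_kano_stats() -> dict:
    """Fully-populated per-requirement stats keyed by requirement id."""
    counts = load_kano_counts()
    return {
        rid: stats_from_counts(rid, {c: int(row[c.value]) for c in CATEGORIES})
        for rid, row in counts.iterrows()
    }


def load_hierarchy(exact: bool = True) -> Hierarchy:
    """The three-level needs hierarchy with its expert pairwise matrices.

    The fixture stores the matrices as published, with reciprocals rounded
    to 3 decimals for display (0.333 for 1/3).  With ``exact=True`` (default)
    every judgment is snapped back to the nearest Saaty scale value, which
    restores exact reciprocity and reproduces the published weight columns;
    ``exact=False`` keeps the entries verbatim (the published consistency
    indices were evidently computed on those).
    """
    import numpy as np

    cfg = yaml.safe_load(_read_text("hierarchy.yaml"))

    def build(labels, matrix):
        a = np.asarray(matrix, dtype=float)
        if exact:
            off = ~np.eye(a.shape[0], dtype=bool)
            a = a.copy()
            a[off] = snap_to_saaty(a[off])
            return PairwiseMatrix(tuple(labels), a)
        return PairwiseMatrix(tuple(labels), a, repair=False)

    crit = build(cfg["criteria"]["labels"], cfg["criteria"]["matrix"])
    indicators = {
        name: build(block["labels"], block["matrix"])
        for name, block in cfg["indicators"].items()
    }
    return Hierarchy(
        goal=cfg["goal"],
        criteria=crit,
        indicators=indicators,
        names=dict(cfg.get("names", {})),
    )


def load_ahp_expected() -> dict:
    """Published AHP result tables (local/comprehensive weights, ranks, CI/CR)."""
    return json.loads(_read_text("ahp_expected.json"))


def load_hoq_weights() -> dict:
    """Published HOQ base row: feature labels, absolute weights, relative %."""
    return json.loads(_read_text("hoq_weights.json"))


def load_hoq_grid() -> pd.DataFrame:
    """Published relationship symbol grid (documentation-grade; see caveats)."""
    import io as _io

    df = pd.read_csv(_io.StringIO(_read_text("hoq_grid.csv")), keep_default_na=False)
    return df.set_index("need")


def load_feature_map() -> dict[str, list[str]]:
    """Need -> technical-features expansion used to build the HOQ ceiling."""
    return yaml.safe_load(_read_text("feature_map.yaml"))
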