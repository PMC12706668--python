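"""Quality function deployment: the house-of-quality weight translation.

The house of quality (HOQ) relates weighted user needs (left wall) to
technical features (ceiling) through a relationship matrix (body) whose cells
are symbol-coded strengths (default ● = 5 strong, ◎ = 3 moderate, △ = 1 weak,
blank = 0).  The base of the house carries the translated feature weights:

    W_j = sum_i W_i * P_ij          absolute technical weight
    W_k = W_j / sum_j W_j           relative technical weight

where W_i is need i's (comprehensive) weight and P_ij the relationship
strength between need i and feature j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SymbolScale",
    "HouseOfQuality",
    "DegenerateHOQError",
    "SymbolParseError",
    "parse_relationship_matrix",
    "absolute_weights",
    "relative_weights",
    "rank_features",
    "technical_weight_report",
    "consolidate_features",
    "build_hoq_report",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (report formatting only)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class SymbolParseError(ValueError):
    """A relationship-grid cell holds an unrecognized symbol."""


class DegenerateHOQError(ValueError):
    """All absolute weights are zero; relative weights are undefined."""


@dataclass(frozen=True)
class SymbolScale:
    """Symbol -> relationship strength mapping.

    The default is the 1–3–5 dialect; :meth:`strong_1_3_9` gives the common
    1–3–9 alternative.  ASCII aliases S/M/W are always accepted alongside the
    unicode symbols, and blank cells map to 0.
    """

    mapping: Mapping[str, float] = field(
        default_factory=lambda: {"●": 5.0, "◎": 3.0, "△": 1.0, "": 0.0}
    )
    ascii_aliases: Mapping[str, str] = field(
        default_factory=lambda: {"S": "●", "M": "◎", "W": "△"}
    )

    def __post_init__(self):
        if any(v < 0 for v in self.mapping.values()):
            raise ValueError("strengths must be non-negative")
        if self.mapping.get("", 0) != 0:
            raise ValueError("blank must map to 0")

    @classmethod
    def strong_1_3_9(cls) -> "SymbolScale":
        return cls(mapping={"●": 9.0, "◎": 3.0, "△": 1.0, "": 0.0})

    def strength(self, cell) -> float:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return 0.0
        key = str(cell).strip()
        key = self.ascii_aliases.get(key.upper() if len(key) == 1 else key, key)
        if key not in self.mapping:
            raise SymbolParseError(f"unrecognized relationship symbol {cell!r}")
        return float(self.mapping[key])


@dataclass(frozen=True)
class HouseOfQuality:
    """Left wall (needs + weights), ceiling (features) and body (P matrix)."""

    needs: tuple[str, ...]
    need_weights: np.ndarray = field(repr=False)
    features: tuple[str, ...]
    relationships: np.ndarray = field(repr=False)

    def __post_init__(self):
        w = np.asarray(self.need_weights, dtype=float)
        p = np.asarray(self.relationships, dtype=float)
        if w.shape != (len(self.needs),):
            raise ValueError("need_weights length mismatch")
        if p.shape != (len(self.needs), len(self.features)):
            raise ValueError(
                f"relationship matrix shape {p.shape} does not match "
                f"{len(self.needs)} needs x {len(self.features)} features"
            )
        if (w < 0).any():
            raise ValueError("need weights must be non-negative")
        if (p < 0).any():
            raise ValueError("relationship strengths must be non-negative")
        object.__setattr__(self, "needs", tuple(map(str, self.needs)))
        object.__setattr__(self, "features", tuple(map(str, self.features)))
        object.__setattr__(self, "need_weights", w)
        object.__setattr__(self, "relationships", p)
        w.setflags(write=False)
        p.setflags(write=False)


def parse_relationship_matrix(
    grid: pd.DataFrame, scale: SymbolScale | None = None
) -> np.ndarray:
    """Symbol grid (needs as rows, features as columns) -> numeric P matrix."""
    scale = scale or SymbolScale()
    p = np.zeros(grid.shape)
    for i, (rid, row) in enumerate(grid.iterrows()):
        for j, col in enumerate(grid.columns):
            try:
                p[i, j] = scale.strength(row[col])
            except SymbolParseError as exc:
                raise SymbolParseError(f"{exc} at row {rid!r}, column {col!r}") from None
    return p


def absolute_weights(hoq: HouseOfQuality) -> np.ndarray:
    """Absolute technical weights W_j = sum_i W_i * P_ij."""
    return hoq.need_weights @ hoq.relationships


def relative_weights(absolute: Sequence[float] | np.ndarray) -> np.ndarray:
    """Normalize absolute weights to fractions summing to 1."""
    w = np.asarray(absolute, dtype=float)
    if (w < 0).any():
        raise ValueError("absolute weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise DegenerateHOQError("all absolute weights are zero")
    return w / total


def rank_features(features: Sequence[str], relative: Sequence[float]) -> pd.Series:
    """Descending ranks (1 = heaviest); ties broken by feature label."""
    df = pd.DataFrame({"feature": list(features), "relative": list(relative)})
    order = df.sort_values(
        ["relative", "feature"], ascending=[False, True], kind="mergesort"
    ).index
    rank = pd.Series(np.arange(1, len(order) + 1), index=order)
    return rank.reindex(df.index).rename("rank")


def technical_weight_report(
    features: Sequence[str], absolute: Sequence[float] | np.ndarray
) -> pd.DataFrame:
    """Base-of-house report: absolute, relative, percent (2-dec half-up), rank."""
    absolute = np.asarray(absolute, dtype=float)
    rel = relative_weights(absolute)
    return pd.DataFrame(
        {
            "feature": list(features),
            "absolute_weight": absolute,
            "relative_weight": rel,
            "percent": [round_half_up(100 * v, 2) for v in rel],
            "rank": rank_features(features, rel).to_numpy(),
        }
    )


def consolidate_features(feature_map: Mapping[str, Iterable[str]]) -> list[str]:
    """Deduplicate the need -> features expansion, preserving first occurrence."""
    if not feature_map:
        raise ValueError("feature map is empty")
    seen: list[str] = []
    for feats in feature_map.values():
        for f in feats:
            if f not in seen:
                seen.append(f)
    if not seen:
        raise ValueError("feature map lists no features")
    return seen


@dataclass
class HOQReport:
    """End-to-end house-of-quality artifact."""

    hoq: HouseOfQuality
    weights: pd.DataFrame
    provenance: pd.DataFrame


def build_hoq_report(
    need_weights: Mapping[str, float],
    feature_map: Mapping[str, Iterable[str]],
    grid: pd.DataFrame,
    scale: SymbolScale | None = None,
) -> HOQReport:
    """Assemble the full HOQ from AHP need weights, the need->feature
    expansion and the symbol grid, then compute the base weights.

    The feature list is the consolidated (deduplicated) expansion of
    *feature_map*; the grid must be indexed by need id with the consolidated
    features as columns.  Needs present in the grid but absent from
    *need_weights* raise a linkage error.
    """
    features = consolidate_features(feature_map)
    missing = [n for n in grid.index if n not in need_weights]
    if missing:
        raise KeyError(f"needs absent from the weight table: {missing}")
    unknown_cols = [c for c in grid.columns if c not in features]
    if unknown_cols:
        raise KeyError(f"grid columns not in the consolidated feature list: {unknown_cols}")
    grid = grid.reindex(columns=features, fill_value="")
    needs = [str(n) for n in grid.index]
    w = np.array([float(need_weights[n]) for n in needs])
    p = parse_relationship_matrix(grid, scale)
    hoq = HouseOfQuality(tuple(needs), w, tuple(features), p)
    report = technical_weight_report(features, absolute_weights(hoq))
    prov = pd.DataFrame(
        [(need, feat) for need, feats in feature_map.items() for feat in feats],
        columns=["need", "feature"],
    )
    return HOQReport(hoq=hoq, weights=report, provenance=prov)
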