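"""File I/O for questionnaires, hierarchies and HOQ grids.

All files are UTF-8 text.  Questionnaires are long-format CSV; hierarchies
are YAML/JSON (matrices either full or upper-triangle); HOQ grids are CSV
with need ids in the first column and feature labels as remaining headers.
Numeric outputs always store fractions — percent strings appear only in
human-readable reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .ahp import Hierarchy, PairwiseMatrix
from .kano import parse_answer

logger = logging.getLogger("needskit")

__all__ = [
    "read_kano_csv",
    "read_hierarchy",
    "read_hoq_grid",
    "write_kano_summary",
    "write_weight_table",
    "write_json_report",
]

_KANO_COLUMNS = ["respondent_id", "requirement_id", "functional", "dysfunctional"]


def read_kano_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format Kano questionnaire CSV.

    Answers may be integer codes 1–5 or canonical labels.  Rows missing
    either half of the answer pair are dropped with a logged warning, so an
    incomplete respondent contributes nothing for that requirement.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty questionnaire file") from None
    missing_cols = [c for c in _KANO_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    df = df[_KANO_COLUMNS]
    incomplete = df[["functional", "dysfunctional"]].isna().any(axis=1) | df[
        "requirement_id"
    ].isna()
    if incomplete.any():
        for line in (df.index[incomplete] + 2).tolist():
            logger.warning("%s: line %d incomplete answer pair, dropped", path, line)
        df = df[~incomplete]
    if df.empty:
        raise ValueError(f"{path}: no complete responses")

    def _parse(col: pd.Series) -> pd.Series:
        out = []
        for line, v in zip(col.index + 2, col):
            try:
                out.append(int(parse_answer(v)))
            except ValueError as exc:
                raise ValueError(f"{path}: line {line}: {exc}") from None
        return pd.Series(out, index=col.index)

    df = df.copy()
    df["functional"] = _parse(df["functional"])
    df["dysfunctional"] = _parse(df["dysfunctional"])
    return df.reset_index(drop=True)


def _matrix_from_config(labels, block, where: str) -> PairwiseMatrix:
    if "matrix" in block:
        return PairwiseMatrix(tuple(labels), block["matrix"])
    if "upper" in block:
        upper = {}
        for key, v in block["upper"].items():
            li, _, lj = key.partition(":")
            if not lj:
                raise ValueError(f"{where}: upper-triangle key {key!r} must be 'i:j'")
            upper[(li.strip(), lj.strip())] = float(v)
        return PairwiseMatrix.from_upper_triangle(labels, upper)
    raise ValueError(f"{where}: needs either 'matrix' or 'upper'")


def read_hierarchy(path: str | Path) -> Hierarchy:
    """Read a hierarchy config (YAML or JSON).

    Structure: ``goal``, ``criteria: {labels, matrix|upper}``,
    ``indicators: {<criterion>: {labels, matrix|upper}}``, optional ``names``.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ValueError(f"{path}: empty hierarchy file")
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict) or "criteria" not in cfg or "indicators" not in cfg:
        raise ValueError(f"{path}: hierarchy config must define 'criteria' and 'indicators'")
    crit = _matrix_from_config(cfg["criteria"]["labels"], cfg["criteria"], f"{path}:criteria")
    indicators = {}
    for name, block in cfg["indicators"].items():
        indicators[name] = _matrix_from_config(block["labels"], block, f"{path}:{name}")
    return Hierarchy(
        goal=cfg.get("goal", "goal"),
        criteria=crit,
        indicators=indicators,
        names=dict(cfg.get("names", {})),
    )


def read_hoq_grid(path: str | Path) -> pd.DataFrame:
    """Read a relationship symbol grid CSV (first column = need id)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, keep_default_na=False, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty HOQ grid") from None
    if df.shape[1] < 2:
        raise ValueError(f"{path}: grid needs a need column plus feature columns")
    return df.set_index(df.columns[0])


def write_kano_summary(summary, out_dir: str | Path, prefix: str = "kano") -> dict[str, Path]:
    """Write the per-requirement summary and Better–Worse scatter CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": out_dir / f"{prefix}_summary.csv",
        "scatter": out_dir / f"{prefix}_scatter.csv",
    }
    summary.table.to_csv(paths["summary"])
    summary.scatter.to_csv(paths["scatter"], index=False)
    return paths


def write_weight_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def write_json_report(report: Mapping, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2, default=_json_default), encoding="utf-8")
    return path


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        from dataclasses import asdict

        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
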