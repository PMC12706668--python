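"""Questionnaire reliability and validity statistics.

Standard pre-analysis quality checks for Likert-type item batteries:
Cronbach's alpha (internal consistency), the Kaiser–Meyer–Olkin measure of
sampling adequacy, and Bartlett's test of sphericity on the item correlation
matrix.  The input is always a respondents x items score table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "QCReport",
    "UndefinedAlphaError",
    "SingularCorrelationError",
    "cronbach_alpha",
    "kmo",
    "bartlett_sphericity",
    "qc_report",
]


class UndefinedAlphaError(ValueError):
    """Total-score variance is zero, so alpha is undefined."""


class SingularCorrelationError(ValueError):
    """Item correlation matrix is singular; KMO cannot be computed."""


def _as_table(table, min_items: int, min_resp: int = 2) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("score table must be 2-D (respondents x items)")
    n, k = x.shape
    if k < min_items:
        raise ValueError(f"need at least {min_items} items, got {k}")
    if n < min_resp:
        raise ValueError(f"need at least {min_resp} respondents, got {n}")
    if not np.isfinite(x).all():
        raise ValueError("score table contains non-finite values")
    return x


def cronbach_alpha(table) -> float:
    """Cronbach's alpha with sample (n-1) variances.

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total score))
    """
    x = _as_table(table, min_items=2)
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedAlphaError("total-score variance is zero")
    return k / (k - 1) * (1 - item_var.sum() / total_var)


def bartlett_sphericity(table) -> tuple[float, int, float]:
    """Bartlett's test that the item correlation matrix is the identity.

    Returns ``(chi2, df, p)`` with
    chi2 = -(n - 1 - (2k + 5)/6) * ln|R| and df = k(k-1)/2.
    """
    x = _as_table(table, min_items=2)
    n, k = x.shape
    r = np.corrcoef(x, rowvar=False)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise SingularCorrelationError("correlation matrix is not positive definite")
    chi2 = -(n - 1 - (2 * k + 5) / 6) * logdet
    chi2 = max(chi2, 0.0)
    df = k * (k - 1) // 2
    p = float(sps.chi2.sf(chi2, df))
    return float(chi2), df, p


def kmo(table) -> float:
    """Overall Kaiser–Meyer–Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum p_ij^2) over off-diagonal cells,
    where p_ij are the anti-image partial correlations obtained from the
    inverse correlation matrix.
    """
    x = _as_table(table, min_items=3)
    r = np.corrcoef(x, rowvar=False)
    try:
        s = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise SingularCorrelationError("correlation matrix is singular") from exc
    d = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    partial = -s / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[off] ** 2).sum()
    p2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + p2))


@dataclass(frozen=True)
class QCReport:
    """Bundle of questionnaire QC statistics for one score table."""

    n_respondents: int
    n_items: int
    cronbach_alpha: float | None
    alpha_undefined: bool
    kmo: float | None
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def qc_report(table) -> QCReport:
    """Compute all QC statistics; KMO is omitted (None) when not computable."""
    x = _as_table(table, min_items=3)
    try:
        alpha, undefined = cronbach_alpha(x), False
    except UndefinedAlphaError:
        alpha, undefined = None, True
    chi2, df, p = bartlett_sphericity(x)
    try:
        kmo_val = kmo(x)
    except SingularCorrelationError:
        kmo_val = None
    return QCReport(
        n_respondents=x.shape[0],
        n_items=x.shape[1],
        cronbach_alpha=alpha,
        alpha_undefined=undefined,
        kmo=kmo_val,
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=p,
    )
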