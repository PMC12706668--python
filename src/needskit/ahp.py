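"""Analytic hierarchy process: pairwise-comparison weighting with consistency checks.

A decision hierarchy has a goal, a criterion layer and an indicator layer.
Each node carries a reciprocal pairwise-comparison matrix on the Saaty 1–9
scale (a_ij = judged importance of i over j, a_ji = 1/a_ij).  Local priority
weights are the normalized principal right eigenvector of the matrix (two
alternative estimators — row geometric means and normalized-column arithmetic
means — are provided; all three coincide on perfectly consistent matrices).

Judgment consistency is measured by

    CI = (lambda_max - n) / (n - 1)        consistency index
    CR = CI / RI                            consistency ratio

where RI is the tabulated random index for matrix size n; CR < 0.1 is
conventionally acceptable.  Global (comprehensive) indicator weights are the
product of the criterion weight and the indicator's local weight.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairwiseMatrix",
    "WeightVector",
    "ConsistencyReport",
    "Hierarchy",
    "SynthesisResult",
    "ReciprocityError",
    "ConvergenceError",
    "ConsistencyGateError",
    "DEFAULT_RI_TABLE",
    "SAATY_SCALE_VALUES",
    "snap_to_saaty",
    "WEIGHT_METHODS",
    "eigenvector_weights",
    "geometric_mean_weights",
    "column_normalization_weights",
    "weights",
    "lambda_max",
    "consistency",
    "synthesize",
]

#: The admissible Saaty judgments: 1/9 ... 1/2, 1, 2 ... 9.
SAATY_SCALE_VALUES: np.ndarray = np.array(
    [1.0 / k for k in range(9, 1, -1)] + [float(k) for k in range(1, 10)]
)


def snap_to_saaty(values):
    """Round judgments to the nearest admissible Saaty value in log-space.

    Restores exact fractions from display-rounded reciprocals (0.333 -> 1/3,
    0.111 -> 1/9) and preserves reciprocity by construction.
    """
    v = np.asarray(values, dtype=float)
    logs = np.log(SAATY_SCALE_VALUES)
    idx = np.argmin(np.abs(np.log(v)[..., None] - logs), axis=-1)
    return SAATY_SCALE_VALUES[idx]


#: Random-index table by matrix size (Saaty-type simulation values).
DEFAULT_RI_TABLE: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.52,
    4: 0.89,
    5: 1.12,
    6: 1.26,
    7: 1.36,
    8: 1.41,
    9: 1.46,
    10: 1.49,
}

#: Default CR acceptance threshold.
CR_THRESHOLD = 0.1

#: Tolerance on |a_ij * a_ji - 1| for raw input (printed matrices carry
#: 3-decimal reciprocals like 0.333); the lower triangle is canonicalized to
#: exact reciprocals afterwards.
RECIPROCITY_TOLERANCE = 0.05


class ReciprocityError(ValueError):
    """A pair of entries violates a_ji = 1/a_ij beyond tolerance."""


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge."""


class ConsistencyGateError(ValueError):
    """A matrix fails the CR threshold and force was not set."""


@dataclass(frozen=True)
class PairwiseMatrix:
    """Validated reciprocal pairwise-comparison matrix with labelled rows.

    With ``repair=True`` (default) each reciprocal pair is canonicalized to
    exact reciprocity; ``repair=False`` keeps entries verbatim (useful for
    regression against published matrices that carry rounded decimals), still
    validating reciprocity within tolerance.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    repair: InitVar[bool] = True

    def __post_init__(self, repair: bool = True):
        a = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if a.shape != (n, n):
            raise ValueError(f"matrix shape {a.shape} does not match {n} labels")
        if n < 2:
            raise ValueError("pairwise matrix needs at least 2 elements")
        if not (a > 0).all():
            raise ValueError("all entries must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=1e-9):
            raise ValueError("diagonal entries must equal 1")
        prod = a * a.T
        bad = np.abs(prod - 1.0) > RECIPROCITY_TOLERANCE
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ReciprocityError(
                f"entries ({self.labels[i]},{self.labels[j]}): "
                f"{a[i, j]:g} * {a[j, i]:g} = {prod[i, j]:g} != 1"
            )
        # canonicalize to exact reciprocity: in each pair the entry >= 1 (the
        # recorded Saaty judgment) is authoritative, its partner is usually a
        # rounded decimal reciprocal (e.g. 0.111 for 1/9)
        canon = a.copy()
        if repair:
            for i in range(n):
                for j in range(i + 1, n):
                    if a[i, j] >= 1.0:
                        canon[j, i] = 1.0 / a[i, j]
                    elif a[j, i] >= 1.0:
                        canon[i, j] = 1.0 / a[j, i]
                    else:
                        canon[j, i] = 1.0 / a[i, j]
            np.fill_diagonal(canon, 1.0)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "values", canon)
        self.values.setflags(write=False)

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_upper_triangle(
        cls, labels: Sequence[str], upper: Mapping[tuple[str, str], float]
    ) -> "PairwiseMatrix":
        """Complete a matrix from upper-triangle judgments {(i_label, j_label): a_ij}."""
        labels = [str(l) for l in labels]
        idx = {l: k for k, l in enumerate(labels)}
        n = len(labels)
        a = np.eye(n)
        seen = set()
        for (li, lj), v in upper.items():
            if li not in idx or lj not in idx:
                raise KeyError(f"unknown label in pair ({li}, {lj})")
            i, j = idx[li], idx[lj]
            if i == j:
                raise ValueError("diagonal judgments are fixed at 1")
            a[i, j] = float(v)
            a[j, i] = 1.0 / float(v)
            seen.add(frozenset((i, j)))
        expected = {frozenset((i, j)) for i in range(n) for j in range(i + 1, n)}
        if seen != expected:
            raise ValueError("upper triangle incomplete: missing judgments")
        return cls(tuple(labels), a)

    def permuted(self, order: Sequence[int]) -> "PairwiseMatrix":
        order = list(order)
        return PairwiseMatrix(
            tuple(self.labels[i] for i in order),
            self.values[np.ix_(order, order)],
        )


@dataclass(frozen=True)
class WeightVector:
    """Positive priority weights summing to one, with labels."""

    labels: tuple[str, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.labels),):
            raise ValueError("weights/labels length mismatch")
        if not (w > 0).all():
            raise ValueError("weights must be strictly positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "weights", w)
        w.setflags(write=False)

    def __getitem__(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.labels), name="weight")


def _power_iteration(
    a: np.ndarray, tol: float = 1e-12, max_iter: int = 10_000
) -> tuple[np.ndarray, float]:
    n = a.shape[0]
    w = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        w_new = a @ w
        w_new /= w_new.sum()
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    else:
        raise ConvergenceError(f"power iteration did not converge in {max_iter} steps")
    lam = float(np.mean((a @ w) / w))
    return w, lam


def eigenvector_weights(matrix: PairwiseMatrix) -> tuple[WeightVector, float]:
    """Normalized principal right eigenvector and lambda_max (power iteration)."""
    w, lam = _power_iteration(matrix.values)
    return WeightVector(matrix.labels, w), lam


def geometric_mean_weights(matrix: PairwiseMatrix) -> WeightVector:
    """Normalized row geometric means (log least squares estimator)."""
    g = np.exp(np.log(matrix.values).mean(axis=1))
    return WeightVector(matrix.labels, g / g.sum())


def column_normalization_weights(matrix: PairwiseMatrix) -> WeightVector:
    """Row means of the column-sum-normalized matrix (common hand calculation)."""
    a = matrix.values
    return WeightVector(matrix.labels, (a / a.sum(axis=0)).mean(axis=1))


WEIGHT_METHODS = {
    "eigenvector": lambda m: eigenvector_weights(m)[0],
    "geometric_mean": geometric_mean_weights,
    "column_normalization": column_normalization_weights,
}


def weights(matrix: PairwiseMatrix, method: str = "eigenvector") -> WeightVector:
    """Local priority weights by the chosen estimator."""
    try:
        return WEIGHT_METHODS[method](matrix)
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(WEIGHT_METHODS)}"
        ) from None


def lambda_max(matrix: PairwiseMatrix) -> float:
    """Principal eigenvalue of the comparison matrix."""
    return _power_iteration(matrix.values)[1]


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency check for one pairwise matrix."""

    n: int
    lambda_max: float
    ci: float
    ri: float
    cr: float
    passed: bool


def consistency(
    matrix_or_lambda: PairwiseMatrix | float,
    n: int | None = None,
    ri_table: Mapping[int, float] = DEFAULT_RI_TABLE,
    threshold: float = CR_THRESHOLD,
) -> ConsistencyReport:
    """CI/CR consistency check.

    Accepts either a :class:`PairwiseMatrix` or a precomputed
    ``(lambda_max, n)`` pair.  CR is defined as 0 when RI is 0 (n <= 2).
    """
    if isinstance(matrix_or_lambda, PairwiseMatrix):
        lam = lambda_max(matrix_or_lambda)
        n = matrix_or_lambda.n
    else:
        lam = float(matrix_or_lambda)
        if n is None:
            raise ValueError("n is required when passing lambda_max directly")
    if n < 2:
        raise ValueError("consistency requires n >= 2")
    # verbatim (unrepaired) matrices with rounded reciprocals can undershoot
    # n marginally; anything further below signals a bad input
    if lam < n - 1e-2 * n:
        raise ValueError(f"lambda_max {lam} below matrix size {n}")
    ci = max((lam - n) / (n - 1), 0.0)
    if n not in ri_table:
        raise KeyError(f"no random index configured for n={n}")
    ri = ri_table[n]
    cr = ci / ri if ri > 0 else 0.0
    return ConsistencyReport(n=n, lambda_max=lam, ci=ci, ri=ri, cr=cr, passed=cr < threshold)


@dataclass(frozen=True)
class Hierarchy:
    """Three-level decision hierarchy: goal, criteria, indicators.

    ``criteria`` compares the criterion-layer nodes against the goal;
    ``indicators`` maps each criterion label to the pairwise matrix of its
    child indicators.  Optional ``names`` gives display names per node id.
    """

    goal: str
    criteria: PairwiseMatrix
    indicators: dict[str, PairwiseMatrix]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.indicators) != set(self.criteria.labels):
            raise ValueError(
                "indicator matrices must cover exactly the criterion labels; "
                f"got {sorted(self.indicators)} vs {sorted(self.criteria.labels)}"
            )
        seen: set[str] = set()
        for crit, m in self.indicators.items():
            dup = seen & set(m.labels)
            if dup:
                raise ValueError(f"indicator(s) {sorted(dup)} appear under multiple criteria")
            seen |= set(m.labels)

    @property
    def indicator_labels(self) -> list[str]:
        return [l for c in self.criteria.labels for l in self.indicators[c].labels]


@dataclass
class SynthesisResult:
    """Global weight table plus per-matrix consistency reports."""

    table: pd.DataFrame
    consistency: dict[str, ConsistencyReport]
    method: str

    def global_weights(self) -> pd.Series:
        return self.table.set_index("indicator")["global_weight"]


def synthesize(
    hierarchy: Hierarchy,
    method: str = "eigenvector",
    ri_table: Mapping[int, float] = DEFAULT_RI_TABLE,
    cr_threshold: float = CR_THRESHOLD,
    force: bool = False,
) -> SynthesisResult:
    """Comprehensive (global) indicator weights and ranks.

    Every matrix must pass CR < *cr_threshold* unless *force* is set.  The
    global weight of an indicator is its criterion's weight times its local
    weight; ranks are descending by global weight with ties broken by
    indicator label (ascending).
    """
    reports = {"criteria": consistency(hierarchy.criteria, ri_table=ri_table, threshold=cr_threshold)}
    for crit, m in hierarchy.indicators.items():
        reports[crit] = consistency(m, ri_table=ri_table, threshold=cr_threshold)
    failing = [name for name, rep in reports.items() if not rep.passed]
    if failing and not force:
        raise ConsistencyGateError(
            f"matrices fail CR < {cr_threshold}: {', '.join(failing)} (use force to override)"
        )

    crit_w = weights(hierarchy.criteria, method)
    rows = []
    for crit in hierarchy.criteria.labels:
        local = weights(hierarchy.indicators[crit], method)
        for lab, lw in zip(local.labels, local.weights):
            rows.append(
                {
                    "criterion": crit,
                    "criterion_weight": crit_w[crit],
                    "indicator": lab,
                    "indicator_name": hierarchy.names.get(lab, lab),
                    "local_weight": float(lw),
                    "global_weight": crit_w[crit] * float(lw),
                }
            )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["global_weight", "indicator"], ascending=[False, True], kind="mergesort"
    ).index
    rank = pd.Series(np.arange(1, len(order) + 1), index=order)
    table["rank"] = rank
    return SynthesisResult(table=table, consistency=reports, method=method)
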