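"""Seeded synthetic inputs for every pipeline stage.

Generators mirror the statistical structure each engine assumes: Kano
questionnaires drawn from per-requirement category mixtures, reciprocal
pairwise matrices perturbed around a known weight vector, and sparse
symbol-strength HOQ bodies.  All randomness flows through a single
``numpy.random.Generator`` seeded per spec; identical spec + seed reproduces
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ahp import SAATY_SCALE_VALUES, PairwiseMatrix, snap_to_saaty
from .kano import CATEGORIES, Category, EvaluationTable
from .qfd import HouseOfQuality

__all__ = [
    "KanoGeneratorSpec",
    "AHPGeneratorSpec",
    "HOQGeneratorSpec",
    "SAATY_SCALE_VALUES",
    "simulate_kano_responses",
    "simulate_pairwise_matrix",
    "simulate_hoq",
]



@dataclass(frozen=True)
class KanoGeneratorSpec:
    """Category-mixture model of a Kano questionnaire.

    ``requirements`` maps each requirement id to a probability vector over
    the six categories (missing categories get probability 0).
    """

    requirements: Mapping[str, Mapping[Category | str, float]]
    n_respondents: int
    seed: int

    def __post_init__(self):
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if not self.requirements:
            raise ValueError("at least one requirement is required")
        norm = {}
        for rid, probs in self.requirements.items():
            p = {Category(k): float(v) for k, v in probs.items()}
            if any(v < 0 for v in p.values()):
                raise ValueError(f"negative probability for requirement {rid!r}")
            if abs(sum(p.values()) - 1.0) > 1e-9:
                raise ValueError(f"probabilities for {rid!r} must sum to 1")
            norm[str(rid)] = p
        object.__setattr__(self, "requirements", norm)


def simulate_kano_responses(
    spec: KanoGeneratorSpec, table: EvaluationTable | None = None
) -> pd.DataFrame:
    """Draw a long-format response table from the category mixtures.

    For every respondent x requirement a category is drawn from the mixture,
    then an answer pair is drawn uniformly from the evaluation-table cells
    mapping to that category (many-to-one for I, A, M, R).
    """
    table = table or EvaluationTable.default()
    rng = np.random.default_rng(spec.seed)
    cells = {c: table.cells_for(c) for c in CATEGORIES}
    for rid, probs in spec.requirements.items():
        for cat, p in probs.items():
            if p > 0 and not cells[cat]:
                raise ValueError(
                    f"requirement {rid!r}: category {cat.value} has no cell in the "
                    "evaluation table"
                )
    rows = []
    req_ids = list(spec.requirements)
    for resp in range(spec.n_respondents):
        for rid in req_ids:
            probs = spec.requirements[rid]
            cats = list(probs)
            cat = cats[rng.choice(len(cats), p=[probs[c] for c in cats])]
            f, d = cells[cat][rng.integers(len(cells[cat]))]
            rows.append((f"r{resp:04d}", rid, int(f), int(d)))
    return pd.DataFrame(
        rows, columns=["respondent_id", "requirement_id", "functional", "dysfunctional"]
    )


@dataclass(frozen=True)
class AHPGeneratorSpec:
    """Multiplicatively perturbed pairwise matrix around true weights.

    Off-diagonal upper-triangle entries are a_ij = (w_i/w_j) * exp(eps) with
    eps ~ Normal(0, noise_sigma^2); the lower triangle holds the exact
    reciprocals.  With ``snap_to_saaty`` each judgment is rounded in
    log-space to the nearest admissible scale value.
    """

    true_weights: Sequence[float]
    noise_sigma: float = 0.0
    snap_to_saaty: bool = False
    seed: int = 0
    labels: tuple[str, ...] | None = None

    def __post_init__(self):
        w = np.asarray(self.true_weights, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("true_weights must be a vector of length >= 2")
        if not (w > 0).all():
            raise ValueError("true_weights must be positive")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("true_weights must sum to 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        labels = self.labels or tuple(f"c{i + 1}" for i in range(w.size))
        if len(labels) != w.size:
            raise ValueError("labels length mismatch")
        object.__setattr__(self, "true_weights", w)
        object.__setattr__(self, "labels", tuple(labels))


def simulate_pairwise_matrix(spec: AHPGeneratorSpec) -> PairwiseMatrix:
    """Generate a reciprocal matrix; exact consistency at noise_sigma = 0."""
    rng = np.random.default_rng(spec.seed)
    w = spec.true_weights
    n = w.size
    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = w[i] / w[j] * np.exp(rng.normal(0.0, spec.noise_sigma))
            if spec.snap_to_saaty:
                v = float(snap_to_saaty(v))
            a[i, j] = v
            a[j, i] = 1.0 / v
    return PairwiseMatrix(spec.labels, a)


@dataclass(frozen=True)
class HOQGeneratorSpec:
    """Sparse random house-of-quality body.

    ``density`` is the target fraction of nonzero relationship cells; every
    need row is guaranteed at least one nonzero cell, so the density must
    admit that (n_needs forced cells <= density * n_needs * n_features).
    """

    n_needs: int
    n_features: int
    density: float = 0.3
    strengths: tuple[float, ...] = (1.0, 3.0, 5.0)
    strength_probs: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_needs < 1 or self.n_features < 1:
            raise ValueError("n_needs and n_features must be >= 1")
        if not (0 < self.density <= 1):
            raise ValueError("density must be in (0, 1]")
        if self.strength_probs is not None:
            p = np.asarray(self.strength_probs, dtype=float)
            if p.size != len(self.strengths) or abs(p.sum() - 1) > 1e-9 or (p < 0).any():
                raise ValueError("strength_probs must be a distribution over strengths")
        n_cells = self.n_needs * self.n_features
        if round(self.density * n_cells) < self.n_needs:
            raise ValueError(
                "density too low to give every need a nonzero relationship"
            )


def simulate_hoq(spec: HOQGeneratorSpec) -> HouseOfQuality:
    """Random HOQ with normalized positive need weights and sparse body."""
    rng = np.random.default_rng(spec.seed)
    q, t = spec.n_needs, spec.n_features
    w = rng.gamma(shape=2.0, scale=1.0, size=q)
    w /= w.sum()

    n_nonzero = int(round(spec.density * q * t))
    p = np.zeros((q, t))
    strengths = np.asarray(spec.strengths, dtype=float)
    probs = spec.strength_probs
    # one guaranteed nonzero cell per need row
    forced_cols = rng.integers(0, t, size=q)
    for i, j in enumerate(forced_cols):
        p[i, j] = rng.choice(strengths, p=probs)
    remaining = n_nonzero - q
    if remaining > 0:
        flat_empty = np.flatnonzero(p.ravel() == 0)
        chosen = rng.choice(flat_empty, size=min(remaining, flat_empty.size), replace=False)
        p.ravel()[chosen] = rng.choice(strengths, p=probs, size=chosen.size)
    needs = tuple(f"n{i + 1}" for i in range(q))
    features = tuple(f"f{j + 1}" for j in range(t))
    return HouseOfQuality(needs, w, features, p)
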