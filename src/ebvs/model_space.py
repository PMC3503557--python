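"""Sparsity-restricted model space and interaction-expanded design matrices.

A *model* is an inclusion indicator vector gamma over the p predictors.  The
restricted space contains every model with at most ``d_max`` included
predictors, so its cardinality is sum_{k<=d_max} C(p, k) — polynomial in p —
which is what makes exact enumeration, and hence exact posterior inclusion
probabilities, feasible.

The design matrix for a model optionally contains one column per *non-empty
subset* of the included predictors (the element-wise product of that subset's
columns), capturing interactions of every order among included predictors.
All columns are standardised to zero mean and unit variance on training data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "InclusionVector",
    "ModelSpace",
    "ExpandedDesign",
    "enumerate_models",
    "expansion_terms",
    "build_design",
]

# Relative tolerance below which an expanded column is treated as constant.
_ZERO_SD_TOL = 1e-12


@dataclass(frozen=True)
class InclusionVector:
    """Binary inclusion indicator over p predictors; doubles as the model."""

    bits: Tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise InvalidArgumentError("inclusion vector entries must be 0 or 1")

    @classmethod
    def from_indices(cls, p: int, indices: Sequence[int]) -> "InclusionVector":
        idx = set(indices)
        if idx and (min(idx) < 0 or max(idx) >= p):
            raise InvalidArgumentError(f"indices out of range for p={p}")
        return cls(tuple(1 if j in idx else 0 for j in range(p)))

    @property
    def p(self) -> int:
        return len(self.bits)

    @property
    def size(self) -> int:
        return sum(self.bits)

    @property
    def indices(self) -> Tuple[int, ...]:
        return tuple(j for j, b in enumerate(self.bits) if b)

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class ModelSpace:
    """The restricted space {gamma : |gamma| <= d_max} over p predictors.

    Iteration is lazy and deterministic: models are yielded by size, then
    lexicographically on their included index tuple.  The space is never
    materialised by this class itself (its size grows as p^d_max), but callers
    working at small p may freely ``list()`` it.
    """

    p: int
    d_max: int

    def __post_init__(self) -> None:
        if self.p < 1:
            raise InvalidArgumentError("p must be >= 1")
        if not (0 <= self.d_max <= self.p):
            raise InvalidArgumentError("require 0 <= d_max <= p")

    def __len__(self) -> int:
        return sum(math.comb(self.p, k) for k in range(self.d_max + 1))

    def __iter__(self) -> Iterator[InclusionVector]:
        for idx in self.iter_indices():
            yield InclusionVector.from_indices(self.p, idx)

    def iter_indices(self) -> Iterator[Tuple[int, ...]]:
        """Yield the included-index tuple of each model, in canonical order."""
        for k in range(self.d_max + 1):
            yield from itertools.combinations(range(self.p), k)


def enumerate_models(p: int, d_max: int) -> ModelSpace:
    """Return the restricted model space with at most ``d_max`` inclusions."""
    return ModelSpace(p=p, d_max=d_max)


def expansion_terms(
    indices: Sequence[int], interactions: bool = True
) -> Tuple[Tuple[int, ...], ...]:
    """Column terms of the expanded design for a set of included predictors.

    With interactions, every non-empty subset of ``indices`` (ordered by
    subset size, then lexicographically); without, the singletons only.
    """
    idx = tuple(sorted(indices))
    if not interactions:
        return tuple((j,) for j in idx)
    terms = []
    for k in range(1, len(idx) + 1):
        terms.extend(itertools.combinations(idx, k))
    return tuple(terms)


@dataclass
class ExpandedDesign:
    """Standardised, interaction-expanded design matrix for one model."""

    columns: np.ndarray  # n x q
    column_terms: Tuple[Tuple[int, ...], ...]
    train_means: np.ndarray
    train_sds: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # bool mask over columns

    @property
    def q(self) -> int:
        return len(self.column_terms)


def _raw_product_columns(
    X: np.ndarray, terms: Sequence[Tuple[int, ...]]
) -> np.ndarray:
    n = X.shape[0]
    out = np.empty((n, len(terms)))
    for c, term in enumerate(terms):
        col = X[:, term[0]].copy()
        for j in term[1:]:
            col *= X[:, j]
        out[:, c] = col
    return out


def build_design(
    gamma: InclusionVector,
    X: np.ndarray,
    interactions: bool = True,
    standardizer: Optional[ExpandedDesign] = None,
) -> ExpandedDesign:
    """Interaction-expanded, standardised design matrix for model ``gamma``.

    Standardisation uses the unbiased (n-1) sample standard deviation.  When a
    ``standardizer`` (a training-time ExpandedDesign) is supplied, its means
    and sds are applied instead of recomputing — so test data never leaks into
    the standardisation.  Columns that are constant on training data are
    retained (keeping q well defined) but set identically to zero.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidArgumentError("X must be a 2-D matrix")
    n = X.shape[0]
    if n < 2:
        raise InvalidArgumentError("need at least 2 samples")
    if gamma.p != X.shape[1]:
        raise InvalidArgumentError("gamma length does not match number of predictors")
    terms = expansion_terms(gamma.indices, interactions)
    raw = _raw_product_columns(X, terms)
    if not np.all(np.isfinite(raw)):
        raise InvalidArgumentError("non-finite values in included predictor columns")

    if standardizer is not None:
        if standardizer.column_terms != terms:
            raise InvalidArgumentError("standardizer terms do not match this model")
        means, sds = standardizer.train_means, standardizer.train_sds
        zero = standardizer.zero_variance
    else:
        if raw.shape[1]:
            means = raw.mean(axis=0)
            sds = raw.std(axis=0, ddof=1)
        else:
            means = np.empty(0)
            sds = np.empty(0)
        scale = np.maximum(np.abs(means), 1.0)
        zero = sds <= _ZERO_SD_TOL * scale

    cols = raw - means
    safe_sds = np.where(zero, 1.0, sds)
    cols /= safe_sds
    cols[:, zero] = 0.0
    return ExpandedDesign(
        columns=cols,
        column_terms=terms,
        train_means=np.asarray(means, dtype=float),
        train_sds=np.asarray(sds, dtype=float),
        zero_variance=np.asarray(zero, dtype=bool),
    )
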