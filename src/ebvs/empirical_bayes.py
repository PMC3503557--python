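"""Empirical-Bayes selection of the prior source m and strength lambda.

The hyperparameter marginal likelihood

    p(Y | X, m, lambda) = sum_gamma p(Y | gamma, X_gamma) P(gamma | m, lambda)

is computed exactly over the restricted model space for every grid point, and
the (m, lambda) pair with the largest score is used for variable selection.
Model evidences do not depend on (m, lambda), so they are computed once and
reused across the whole grid; each grid point costs only a prior pass and one
log-sum-exp.

The default grid lambda in [-5, 5] with step 0.5 always contains lambda = 0,
at which every source reduces to the flat prior — so empirical Bayes can
always fall back to no prior information.  Ties are broken toward the weakest
prior (smallest |lambda|), then toward the smaller source index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import InvalidArgumentError
from .likelihood import ResponseVector, SpaceEvidence
from .model_space import ModelSpace
from .priors import PriorSource, PriorSpec, log_prior_vector, make_prior

__all__ = [
    "default_lambda_grid",
    "EBGrid",
    "EBSelection",
    "eb_score",
    "select_hyperparameters",
]


def default_lambda_grid(
    lo: float = -5.0, hi: float = 5.0, step: float = 0.5
) -> np.ndarray:
    """Evenly spaced lambda grid; must bracket and contain 0."""
    n = int(round((hi - lo) / step))
    grid = lo + step * np.arange(n + 1)
    grid[np.isclose(grid, 0.0)] = 0.0
    if not np.any(grid == 0.0):
        raise InvalidArgumentError("lambda grid must contain 0")
    return grid


@dataclass
class EBGrid:
    """Exact log p(Y | X, m, lambda) on a (source x lambda) grid."""

    sources: Tuple[PriorSource, ...]
    lambda_values: np.ndarray
    scores: np.ndarray  # shape (n_sources, n_lambda)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, src in enumerate(self.sources):
            for j, lam in enumerate(self.lambda_values):
                rows.append(
                    {
                        "m": src.m,
                        "source": src.name,
                        "lambda": float(lam),
                        "log_marginal": float(self.scores[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class EBSelection:
    """The empirical-Bayes optimum and the full diagnostic grid."""

    source: PriorSource
    lam: float
    spec: PriorSpec
    score: float
    grid: EBGrid

    @property
    def m(self) -> int:
        return self.source.m


def _score_from_parts(log_ml: np.ndarray, log_prior: np.ndarray) -> float:
    return float(logsumexp(log_ml + log_prior))


def eb_score(
    X: np.ndarray,
    Y: Union[np.ndarray, ResponseVector],
    spec: PriorSpec,
    space: ModelSpace,
    interactions: bool = True,
    evidence: Optional[SpaceEvidence] = None,
) -> float:
    """Exact log sum_gamma p(Y|gamma) P(gamma|m,lambda), up to the constant
    shared by all models on the same data."""
    ev = evidence if evidence is not None else SpaceEvidence(X, Y, space, interactions)
    return _score_from_parts(ev.log_ml, log_prior_vector(spec, space))


def select_hyperparameters(
    X: Optional[np.ndarray],
    Y: Optional[Union[np.ndarray, ResponseVector]],
    sources: Sequence[PriorSource],
    lambda_grid: Sequence[float],
    space: ModelSpace,
    interactions: bool = True,
    evidence: Optional[SpaceEvidence] = None,
) -> EBSelection:
    """Maximise the hyperparameter marginal likelihood over the grid.

    Evidence may be passed in to share one computation across many calls.
    """
    lam_values = np.asarray(lambda_grid, dtype=float)
    if lam_values.size == 0:
        raise InvalidArgumentError("lambda grid must be non-empty")
    if not np.any(lam_values == 0.0):
        raise InvalidArgumentError("lambda grid must contain 0")
    if not sources:
        raise InvalidArgumentError("need at least one prior source")
    ev = evidence if evidence is not None else SpaceEvidence(X, Y, space, interactions)
    log_ml = ev.log_ml

    scores = np.empty((len(sources), lam_values.size))
    for i, src in enumerate(sources):
        f = src.feature_vector(space)
        for j, lam in enumerate(lam_values):
            scores[i, j] = _score_from_parts(log_ml, lam * f - logsumexp(lam * f))

    best = scores.max()
    # break ties (within float noise) toward the weakest prior, then smaller m
    tied = np.argwhere(scores >= best - 1e-9)
    order = sorted(
        (abs(lam_values[j]), sources[i].m, lam_values[j], i, j) for i, j in tied
    )
    _, _, _, i_star, j_star = order[0]
    src, lam = sources[i_star], float(lam_values[j_star])
    return EBSelection(
        source=src,
        lam=lam,
        spec=make_prior(src, lam, space),
        score=float(scores[i_star, j_star]),
        grid=EBGrid(tuple(sources), lam_values, scores),
    )
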