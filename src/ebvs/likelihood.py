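"""Closed-form model evidence under the hierarchical g-prior (g = n).

Model: Y = Xbar_gamma beta + eps, eps ~ N(0, sigma^2 I), with
beta | sigma^2 ~ N(0, n sigma^2 (Xbar^T Xbar)^{-1}) and p(sigma^2) ∝ 1/sigma^2.
Integrating out (beta, sigma^2) gives, up to a constant shared by all models
on the same data,

    p(Y | gamma) ∝ (1+n)^{-q/2} [Y^T Y - n/(n+1) Y^T H Y]^{-n/2}

where H projects onto the column space of the standardised expanded design and
q is the number of expanded columns (2^|gamma| - 1 with interactions).  The
q-dependent first factor is the automatic complexity penalty; the prior has no
free hyperparameters and model posteriors are invariant under rescaling of Y.

The response is centred by its training mean (the design columns are mean
zero, so the intercept is handled outside the model and added back at
prediction time).

``SpaceEvidence`` computes the evidence for every model in a restricted space
at once, caching the standardised product columns that models share — the
expanded column for a subset S is the same in every model containing S.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.linalg

from .errors import InvalidArgumentError
from .model_space import (
    ExpandedDesign,
    InclusionVector,
    ModelSpace,
    build_design,
    expansion_terms,
)

__all__ = [
    "ResponseVector",
    "ModelEvidence",
    "log_marginal_likelihood",
    "posterior_mean_coefficients",
    "SpaceEvidence",
]

logger = logging.getLogger("ebvs")

# Relative singular-value / eigenvalue tolerance for pseudo-inverse fallback.
PINV_RTOL = 1e-10
# Residual floor, relative to Y^T Y, applied before taking logs.
RESIDUAL_FLOOR = 1e-12


@dataclass(frozen=True)
class ResponseVector:
    """Response values together with the training mean used for centring."""

    values: np.ndarray
    center: float

    @classmethod
    def of(cls, Y: Union[np.ndarray, "ResponseVector"]) -> "ResponseVector":
        if isinstance(Y, ResponseVector):
            return Y
        arr = np.asarray(Y, dtype=float).ravel()
        if arr.size < 2:
            raise InvalidArgumentError("response must have at least 2 values")
        if not np.all(np.isfinite(arr)):
            raise InvalidArgumentError("response contains non-finite values")
        return cls(values=arr, center=float(arr.mean()))

    @property
    def centered(self) -> np.ndarray:
        return self.values - self.center

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ModelEvidence:
    """Log marginal likelihood of one model, up to a shared constant."""

    gamma: InclusionVector
    log_ml: float
    q: int


def _projection_fit(G: np.ndarray, c: np.ndarray) -> Tuple[float, np.ndarray]:
    """Return (c^T G^+ c, G^+ c) with Cholesky fast path, pinv fallback."""
    try:
        cf = scipy.linalg.cho_factor(G, lower=True, check_finite=False)
        x = scipy.linalg.cho_solve(cf, c, check_finite=False)
    except scipy.linalg.LinAlgError:
        logger.warning(
            "singular expanded Gram matrix (q=%d); using pseudo-inverse", len(c)
        )
        x = scipy.linalg.pinvh(G, rtol=PINV_RTOL) @ c
    return float(c @ x), x


def _log_ml_from_parts(n: int, q: int, yty: float, fit: float) -> float:
    if yty <= 0.0:
        # constant response: only the complexity penalty differentiates
        # models, so the empty model is MAP and predicts the constant exactly
        return -0.5 * q * math.log1p(n)
    residual = yty - n / (n + 1.0) * fit
    residual = max(residual, RESIDUAL_FLOOR * yty)
    return -0.5 * q * math.log1p(n) - 0.5 * n * math.log(residual)


def log_marginal_likelihood(
    gamma: InclusionVector,
    X: np.ndarray,
    Y: Union[np.ndarray, ResponseVector],
    interactions: bool = True,
) -> ModelEvidence:
    """Closed-form log evidence of ``gamma``, up to a constant shared by all
    models on the same (X, Y)."""
    resp = ResponseVector.of(Y)
    yc = resp.centered
    n = resp.n
    design = build_design(gamma, X, interactions=interactions)
    yty = float(yc @ yc)
    if design.q == 0:
        fit = 0.0
    else:
        Z = design.columns
        fit, _ = _projection_fit(Z.T @ Z, Z.T @ yc)
    return ModelEvidence(
        gamma=gamma, log_ml=_log_ml_from_parts(n, design.q, yty, fit), q=design.q
    )


def posterior_mean_coefficients(
    gamma: InclusionVector,
    X: np.ndarray,
    Y: Union[np.ndarray, ResponseVector],
    interactions: bool = True,
) -> np.ndarray:
    """Shrunken least-squares coefficients n/(n+1) (Z^T Z)^+ Z^T Yc over the
    expanded (standardised) columns of ``gamma``; used for prediction."""
    resp = ResponseVector.of(Y)
    design = build_design(gamma, X, interactions=interactions)
    if design.q == 0:
        return np.empty(0)
    Z = design.columns
    _, x = _projection_fit(Z.T @ Z, Z.T @ resp.centered)
    return resp.n / (resp.n + 1.0) * x


# Above this many distinct expanded columns the full Gram matrix is not
# precomputed and per-model Grams are assembled instead.
_GRAM_LIMIT = 4000


class SpaceEvidence:
    """Evidence for every model of a restricted space on fixed training data.

    Builds each distinct subset-product column once, standardises it with
    training statistics, and solves a small q x q system per model.  Also
    exposes the training standardisation needed to expand and predict new
    data, so prediction never leaks test statistics.
    """

    def __init__(
        self,
        X: np.ndarray,
        Y: Union[np.ndarray, ResponseVector],
        space: ModelSpace,
        interactions: bool = True,
    ) -> None:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != space.p:
            raise InvalidArgumentError("X shape does not match model space")
        if not np.all(np.isfinite(X)):
            raise InvalidArgumentError("X contains non-finite values")
        self.space = space
        self.interactions = interactions
        self.response = ResponseVector.of(Y)
        if self.response.n != X.shape[0]:
            raise InvalidArgumentError("X and Y sample counts differ")
        self.n = X.shape[0]
        self.X = X

        # All subset terms that can appear as a column of some model.
        max_order = space.d_max if interactions else 1
        terms = []
        for k in range(1, max_order + 1):
            terms.extend(itertools.combinations(range(space.p), k))
        self.terms: Tuple[Tuple[int, ...], ...] = tuple(terms)
        self._term_index: Dict[Tuple[int, ...], int] = {
            t: i for i, t in enumerate(self.terms)
        }

        Z = np.empty((self.n, len(terms)))
        for i, term in enumerate(terms):
            col = X[:, term[0]].copy()
            for j in term[1:]:
                col *= X[:, j]
            Z[:, i] = col
        self.train_means = Z.mean(axis=0)
        self.train_sds = Z.std(axis=0, ddof=1)
        scale = np.maximum(np.abs(self.train_means), 1.0)
        self.zero_variance = self.train_sds <= 1e-12 * scale
        Z -= self.train_means
        Z /= np.where(self.zero_variance, 1.0, self.train_sds)
        Z[:, self.zero_variance] = 0.0
        self.Z = Z

        yc = self.response.centered
        self.yty = float(yc @ yc)
        self._c = Z.T @ yc
        self._G = Z.T @ Z if Z.shape[1] <= _GRAM_LIMIT else None

        self._log_ml: Optional[np.ndarray] = None
        self._model_terms: Optional[list] = None

    # -- per-model plumbing -------------------------------------------------

    def model_term_ids(self, indices: Sequence[int]) -> np.ndarray:
        terms = expansion_terms(indices, self.interactions)
        return np.array([self._term_index[t] for t in terms], dtype=np.intp)

    def _iter_model_terms(self):
        if self._model_terms is None:
            self._model_terms = [
                self.model_term_ids(idx) for idx in self.space.iter_indices()
            ]
        return self._model_terms

    def _gram(self, ids: np.ndarray) -> np.ndarray:
        if self._G is not None:
            return self._G[np.ix_(ids, ids)]
        Zs = self.Z[:, ids]
        return Zs.T @ Zs

    # -- evidence -----------------------------------------------------------

    @property
    def log_ml(self) -> np.ndarray:
        """Log evidence of every model, in the space's canonical order."""
        if self._log_ml is None:
            n, yty = self.n, self.yty
            out = np.empty(len(self.space))
            for i, ids in enumerate(self._iter_model_terms()):
                q = ids.size
                if q == 0:
                    fit = 0.0
                else:
                    fit, _ = _projection_fit(self._gram(ids), self._c[ids])
                out[i] = _log_ml_from_parts(n, q, yty, fit)
            self._log_ml = out
        return self._log_ml

    def coefficients(self, indices: Sequence[int]) -> np.ndarray:
        """Posterior-mean coefficients of one model on its expanded columns."""
        ids = self.model_term_ids(indices)
        if ids.size == 0:
            return np.empty(0)
        _, x = _projection_fit(self._gram(ids), self._c[ids])
        return self.n / (self.n + 1.0) * x

    # -- prediction support -------------------------------------------------

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Expand new data to all cached columns using training statistics."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != self.space.p:
            raise InvalidArgumentError("X_new shape does not match model space")
        Z = np.empty((X_new.shape[0], len(self.terms)))
        for i, term in enumerate(self.terms):
            col = X_new[:, term[0]].copy()
            for j in term[1:]:
                col *= X_new[:, j]
            Z[:, i] = col
        Z -= self.train_means
        Z /= np.where(self.zero_variance, 1.0, self.train_sds)
        Z[:, self.zero_variance] = 0.0
        return Z

    def design_for(self, gamma: InclusionVector) -> ExpandedDesign:
        """Training ExpandedDesign of one model, sliced from the cache."""
        ids = self.model_term_ids(gamma.indices)
        terms = tuple(self.terms[i] for i in ids)
        return ExpandedDesign(
            columns=self.Z[:, ids],
            column_terms=terms,
            train_means=self.train_means[ids],
            train_sds=self.train_sds[ids],
            zero_variance=self.zero_variance[ids],
        )
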