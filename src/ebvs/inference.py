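"""Exact posterior over the restricted model space and quantities derived
from it: posterior inclusion probabilities, the MAP model, and model-averaged
prediction.

All posterior arithmetic is carried out in log space with a single
log-sum-exp normalisation pass.  Because the restricted space is enumerated
exhaustively, inclusion probabilities P(gamma_j = 1 | Y, X) are exact sums of
posterior model probabilities, not Monte Carlo estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.special import logsumexp

from .errors import InvalidArgumentError
from .likelihood import ResponseVector, SpaceEvidence
from .model_space import InclusionVector, ModelSpace
from .priors import PriorSpec, log_prior_vector

__all__ = [
    "PosteriorSummary",
    "model_posterior",
    "inclusion_probabilities",
    "map_model",
    "predict",
]

# Posterior weights below this are dropped in model-averaged prediction; the
# induced error is at the level of float round-off.
_PREDICT_WEIGHT_FLOOR = 1e-15


@dataclass
class PosteriorSummary:
    """Normalised posterior over all models of a restricted space."""

    space: ModelSpace
    spec: PriorSpec
    log_posterior: np.ndarray  # in the space's canonical order
    interactions: bool = True
    _pips: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def inclusion_probs(self) -> np.ndarray:
        if self._pips is None:
            w = np.exp(self.log_posterior)
            pips = np.zeros(self.space.p)
            for wi, idx in zip(w, self.space.iter_indices()):
                for j in idx:
                    pips[j] += wi
            self._pips = np.clip(pips, 0.0, 1.0)
        return self._pips

    @property
    def map_model(self) -> InclusionVector:
        # argmax returns the first maximiser: the deterministic enumeration
        # order (by size, then lexicographic) is the tie-break
        i = int(np.argmax(self.log_posterior))
        for k, idx in enumerate(self.space.iter_indices()):
            if k == i:
                return InclusionVector.from_indices(self.space.p, idx)
        raise AssertionError("unreachable")


def model_posterior(
    evidence: Union[SpaceEvidence, np.ndarray],
    spec: PriorSpec,
    space: Optional[ModelSpace] = None,
    interactions: bool = True,
) -> PosteriorSummary:
    """log P(gamma | Y, X) = log_ml + log_prior - logsumexp over the space."""
    if isinstance(evidence, SpaceEvidence):
        space = evidence.space
        interactions = evidence.interactions
        log_ml = evidence.log_ml
    else:
        if space is None:
            raise InvalidArgumentError("space required with a raw evidence array")
        log_ml = np.asarray(evidence, dtype=float)
    unnorm = log_ml + log_prior_vector(spec, space)
    return PosteriorSummary(
        space=space,
        spec=spec,
        log_posterior=unnorm - logsumexp(unnorm),
        interactions=interactions,
    )


def inclusion_probabilities(post: PosteriorSummary) -> np.ndarray:
    """Exact P(gamma_j = 1 | Y, X) for every predictor j."""
    return post.inclusion_probs


def map_model(post: PosteriorSummary) -> InclusionVector:
    """Maximum a posteriori model (first in enumeration order on ties).

    Note the MAP model need not contain the predictors with the highest
    inclusion probabilities.
    """
    return post.map_model


def predict(
    X_new: np.ndarray,
    X: Optional[np.ndarray],
    Y: Optional[Union[np.ndarray, ResponseVector]],
    post: PosteriorSummary,
    mode: str = "model_average",
    evidence: Optional[SpaceEvidence] = None,
) -> np.ndarray:
    """Predict new responses by exact model averaging (or from the MAP model).

    Per-model predictions are n/(n+1) Zbar' (Zbar^T Zbar)^+ Zbar^T Yc with the
    new design expanded and standardised by *training* statistics, plus the
    training response mean.  ``model_average`` weights them by the posterior;
    ``map`` uses the MAP model alone.
    """
    if mode not in ("model_average", "map"):
        raise InvalidArgumentError(f"unknown prediction mode {mode!r}")
    ev = evidence
    if ev is None:
        ev = SpaceEvidence(X, Y, post.space, interactions=post.interactions)
    X_new = np.asarray(X_new, dtype=float)
    Zt = ev.transform(X_new)
    out = np.full(X_new.shape[0], ev.response.center)

    if mode == "map":
        idx = post.map_model.indices
        if idx:
            ids = ev.model_term_ids(idx)
            out = out + Zt[:, ids] @ ev.coefficients(idx)
        return out

    w = np.exp(post.log_posterior)
    for wi, idx in zip(w, post.space.iter_indices()):
        if wi <= _PREDICT_WEIGHT_FLOOR or not idx:
            continue
        ids = ev.model_term_ids(idx)
        out += wi * (Zt[:, ids] @ ev.coefficients(idx))
    return out
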