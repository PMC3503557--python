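"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the evidence oracle
integrates the likelihood-times-prior numerically instead of using the
closed form; the set-cover oracle enumerates every pathway subset; the
prediction oracle re-assembles model averaging from per-model pieces.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate
from scipy.stats import multivariate_normal

from ebvs.model_space import InclusionVector, build_design


def quad_log_evidence(X, Y, indices, interactions=True):
    """Log marginal likelihood by numerical integration.

    Marginalising the coefficients under their Normal prior gives
    Y | sigma^2 ~ N(0, sigma^2 (I + n H)) with H the projection onto the
    column space of the standardised design; the remaining one-dimensional
    integral over sigma^2 (improper prior 1/sigma^2) is computed by adaptive
    quadrature on the log scale.  The Gaussian density and the projection are
    evaluated numerically (SVD + scipy), not through the closed form.
    """
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean()
    n = Y.size
    p = X.shape[1]
    gamma = InclusionVector.from_indices(p, indices)
    design = build_design(gamma, X, interactions=interactions)
    if design.q:
        U, s, _ = np.linalg.svd(design.columns, full_matrices=False)
        rank = s > (s[0] * 1e-12 if s.size else 0)
        H = U[:, rank] @ U[:, rank].T
    else:
        H = np.zeros((n, n))
    cov = np.eye(n) + n * H

    def log_f(u):
        return multivariate_normal.logpdf(Yc, mean=np.zeros(n), cov=math.exp(u) * cov)

    # locate the peak on a coarse grid, then integrate the shifted integrand
    grid = np.linspace(-25.0, 25.0, 401)
    vals = np.array([log_f(u) for u in grid])
    shift = vals.max()
    val, _ = integrate.quad(
        lambda u: math.exp(log_f(u) - shift), -30.0, 30.0, limit=400,
        points=[float(grid[np.argmax(vals)])],
    )
    return shift + math.log(val)


def nquad_log_evidence_1col(Z, Y):
    """Full 2-D quadrature over (beta, log sigma^2) for a one-column design."""
    Y = np.asarray(Y, dtype=float)
    Yc = Y - Y.mean()
    n = Y.size
    z = Z.ravel()
    ztz = float(z @ z)

    def log_f(beta, u):
        s2 = math.exp(u)
        resid = Yc - beta * z
        log_lik = -0.5 * n * math.log(2 * math.pi * s2) - resid @ resid / (2 * s2)
        prior_var = n * s2 / ztz
        log_pri = -0.5 * math.log(2 * math.pi * prior_var) - beta**2 / (2 * prior_var)
        return log_lik + log_pri

    shift = log_f(0.0, float(np.log(Yc @ Yc / n)))
    val, _ = integrate.nquad(
        lambda b, u: math.exp(log_f(b, u) - shift),
        [[-60, 60], [-25, 25]],
        opts={"limit": 200},
    )
    return shift + math.log(val)


def min_cover_oracle(sets):
    """Minimum set cover by enumerating every subset of the collection."""
    sets = [frozenset(s) for s in sets if s]
    if not sets:
        return 0
    target = frozenset().union(*sets)
    best = len(sets)
    for r in range(1, len(sets) + 1):
        for comb in itertools.combinations(sets, r):
            if frozenset().union(*comb) == target:
                return r
    return best


def model_average_prediction_oracle(X_new, X, Y, space, log_posterior,
                                    interactions=True):
    """Model-averaged prediction assembled per model with explicit OLS-style
    shrinkage, standardising new data by training statistics."""
    Y = np.asarray(Y, dtype=float)
    center = Y.mean()
    Yc = Y - center
    n = Y.size
    w = np.exp(np.asarray(log_posterior))
    out = np.full(np.asarray(X_new).shape[0], center)
    for wi, gamma in zip(w, space):
        if not gamma.indices:
            continue
        tr = build_design(gamma, X, interactions=interactions)
        te = build_design(gamma, X_new, interactions=interactions, standardizer=tr)
        beta = n / (n + 1.0) * (np.linalg.pinv(tr.columns.T @ tr.columns)
                                @ tr.columns.T @ Yc)
        out = out + wi * (te.columns @ beta)
    return out
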