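"""Evaluation protocol: thresholded ROC/AUC for variable selection accuracy,
subsampled train/test predictive error, and leave-one-out cross-validation.

A ROC curve is built by thresholding posterior inclusion probabilities at
every level tau and plotting true positives |truth ∩ gamma_tau| against false
positives |gamma_tau \\ truth|; the AUC is normalised to [0, 1] and equals the
Mann-Whitney rank statistic with ties averaged.  Replicate curves are
averaged by taking the mean TP at each integer FP count; AUC is computed per
replicate and then averaged.

The subsample experiment mirrors the small-sample protocol: per seeded
replicate a small training set is drawn without replacement, the *entire*
pipeline (empirical Bayes included) is run on training data only, and
selection accuracy plus held-out mean absolute predictive error are recorded.
LOOCV likewise re-runs empirical Bayes inside every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .empirical_bayes import default_lambda_grid, select_hyperparameters
from .errors import InvalidArgumentError
from .likelihood import SpaceEvidence
from .inference import model_posterior, predict
from .model_space import InclusionVector, enumerate_models
from .priors import (
    FlatPrior,
    IntraPathwayDistancePrior,
    MRFPrior,
    Network,
    PathwayAnnotation,
    PathwayCountPrior,
    PriorSource,
    make_prior,
)
from .synthetic import SyntheticWorld

__all__ = [
    "ROCResult",
    "roc_from_scores",
    "tp_at_integer_fp",
    "Regime",
    "EvalConfig",
    "ExperimentReport",
    "world_prior_sources",
    "incorrect_regime_for",
    "run_subsample_experiment",
    "loocv",
]


@dataclass
class ROCResult:
    """TP/FP counts over all thresholds, plus normalised AUC."""

    thresholds: np.ndarray
    tp_counts: np.ndarray
    fp_counts: np.ndarray
    auc: float


def roc_from_scores(
    scores: np.ndarray, truth: InclusionVector
) -> ROCResult:
    """ROC of per-predictor scores against a known truth model.

    AUC is the tie-averaged rank statistic; all-equal scores give 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(truth.bits, dtype=bool)
    if scores.shape != pos.shape:
        raise InvalidArgumentError("scores length does not match truth")
    n_pos = int(pos.sum())
    n_neg = pos.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError("truth must be non-empty and non-full")
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    tp = np.empty(thresholds.size, dtype=int)
    fp = np.empty(thresholds.size, dtype=int)
    for i, t in enumerate(thresholds):
        sel = scores >= t
        tp[i] = int((sel & pos).sum())
        fp[i] = int((sel & ~pos).sum())
    return ROCResult(thresholds=thresholds, tp_counts=tp, fp_counts=fp, auc=float(auc))


def tp_at_integer_fp(roc: ROCResult, n_neg: int) -> np.ndarray:
    """Best TP achievable at each integer FP budget 0..n_neg (staircase)."""
    out = np.zeros(n_neg + 1)
    for f in range(n_neg + 1):
        mask = roc.fp_counts <= f
        out[f] = roc.tp_counts[mask].max() if mask.any() else 0
    return out


# ---------------------------------------------------------------------------
# Prior regimes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Regime:
    """How the model prior is chosen within one experimental arm."""

    name: str
    mode: str = "eb"  # "eb" | "fixed" | "flat"
    source: Optional[str] = None  # for "fixed": a source name
    lam: float = 0.0
    sources: Optional[Tuple[str, ...]] = None  # for "eb": restrict candidates
    lambda_grid: Optional[Tuple[float, ...]] = None


DEFAULT_REGIMES: Tuple[Regime, ...] = (Regime("eb"), Regime("flat", mode="flat"))


def incorrect_regime_for(scenario: int) -> Regime:
    """The deliberately mis-specified prior used as a comparison arm: the
    distance prior pushed in the direction opposite to the truth placement."""
    lam = -5.0 if scenario == 1 else 5.0
    return Regime("incorrect", mode="fixed", source="intra_pathway_distance", lam=lam)


def world_prior_sources(
    world: SyntheticWorld, include_mrf: bool = False
) -> Dict[str, PriorSource]:
    """Candidate prior sources for a world's network and pathways."""
    return prior_sources(
        world.pathways, world.network, world.names, include_mrf=include_mrf
    )


def prior_sources(
    ann: PathwayAnnotation,
    net: Network,
    names: Sequence[str],
    include_mrf: bool = False,
) -> Dict[str, PriorSource]:
    sources: Dict[str, PriorSource] = {
        "pathway_count": PathwayCountPrior(ann, names),
        "intra_pathway_distance": IntraPathwayDistancePrior(ann, net, names),
        "flat": FlatPrior(),
    }
    if include_mrf:
        sources["mrf"] = MRFPrior(net.adjacency(names))
    return sources


@dataclass
class EvalConfig:
    """Desk-scale experiment configuration."""

    n_train: int = 35
    replicates: int = 200
    d_max: int = 4
    interactions: Optional[bool] = None  # None: follow the scenario
    lambda_grid: Tuple[float, ...] = tuple(default_lambda_grid())
    eb_sources: Tuple[str, ...] = ("pathway_count", "intra_pathway_distance")
    include_mrf: bool = False
    seed: int = 0


@dataclass
class ExperimentReport:
    """Per-replicate metrics plus averaged ROC curves and summaries."""

    config: dict
    replicates: pd.DataFrame
    avg_roc: Dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def summary(self) -> pd.DataFrame:
        num = self.replicates.drop(columns=["regime"]).select_dtypes("number")
        g = num.join(self.replicates["regime"]).groupby("regime")
        mean = g.mean()
        se = g.sem()
        se.columns = [c + "_se" for c in se.columns]
        return mean.join(se)


def _topology_key(world: SyntheticWorld):
    return (
        world.names,
        tuple(sorted(tuple(sorted(e)) for e in world.network.edges)),
        tuple((k, tuple(sorted(v))) for k, v in world.pathways.pathways.items()),
    )


def _regime_spec(regime, sources, space, default_grid, evidence):
    """Resolve a regime to a normalised PriorSpec (running EB if asked)."""
    if regime.mode == "flat":
        return make_prior(sources["flat"], 0.0, space), {}
    if regime.mode == "fixed":
        return make_prior(sources[regime.source], regime.lam, space), {}
    cand = [sources[s] for s in (regime.sources or default_grid[1])]
    grid = np.asarray(regime.lambda_grid or default_grid[0], dtype=float)
    sel = select_hyperparameters(None, None, cand, grid, space, evidence=evidence)
    return sel.spec, {"m": sel.m, "source_name": sel.source.name, "lambda": sel.lam}


def run_subsample_experiment(
    world: Union[SyntheticWorld, Callable[[int], SyntheticWorld]],
    config: EvalConfig,
    regimes: Sequence[Regime] = DEFAULT_REGIMES,
) -> ExperimentReport:
    """Run the seeded subsample protocol.

    ``world`` is either a fixed SyntheticWorld (rows are subsampled from it,
    as when predictors are a fixed dataset) or a factory mapping a replicate
    seed to a fresh world.  Replicate r uses seed ``config.seed + r``.  Model
    evidences are computed once per replicate and shared by all regimes.
    """
    factory = world if callable(world) else (lambda s, w=world: w)
    rows: List[dict] = []
    tp_curves: Dict[str, List[np.ndarray]] = {r.name: [] for r in regimes}
    sources = None
    topo_key = None
    n_neg = None

    for r in range(config.replicates):
        rep_seed = config.seed + r
        w = factory(rep_seed)
        key = _topology_key(w)
        if sources is None or key != topo_key:
            sources = world_prior_sources(w, include_mrf=config.include_mrf)
            topo_key = key
        interactions = (
            config.interactions
            if config.interactions is not None
            else w.scenario.interactions
        )
        space = enumerate_models(w.p, config.d_max)
        rng = np.random.default_rng(rep_seed)
        if w.n_total > config.n_train:
            train = np.sort(
                rng.choice(w.n_total, size=config.n_train, replace=False)
            )
            test = np.setdiff1d(np.arange(w.n_total), train)
        else:
            train = np.arange(w.n_total)
            test = np.empty(0, dtype=int)
        Xtr, Ytr = w.X[train], w.Y[train]
        ev = SpaceEvidence(Xtr, Ytr, space, interactions=interactions)
        n_neg = w.p - w.truth.size

        if test.size:
            ones = np.column_stack([np.ones(len(train)), Xtr])
            beta, *_ = np.linalg.lstsq(ones, Ytr, rcond=None)
            base_pred = np.column_stack([np.ones(test.size), w.X[test]]) @ beta
            mae_baseline = float(np.abs(base_pred - w.Y[test]).mean())
        else:
            mae_baseline = np.nan

        for regime in regimes:
            spec, eb_info = _regime_spec(
                regime, sources, space, (config.lambda_grid, config.eb_sources), ev
            )
            post = model_posterior(ev, spec)
            roc = roc_from_scores(post.inclusion_probs, w.truth)
            tp_curves[regime.name].append(tp_at_integer_fp(roc, n_neg))
            row = {
                "replicate": r,
                "seed": rep_seed,
                "regime": regime.name,
                "auc": roc.auc,
                "mae_baseline": mae_baseline,
            }
            if test.size:
                for mode, col in (("model_average", "mae_ma"), ("map", "mae_map")):
                    pred = predict(w.X[test], None, None, post, mode, evidence=ev)
                    row[col] = float(np.abs(pred - w.Y[test]).mean())
            row.update(eb_info)
            rows.append(row)

    avg_roc = {
        name: pd.DataFrame(
            {"fp": np.arange(n_neg + 1), "mean_tp": np.mean(curves, axis=0)}
        )
        for name, curves in tp_curves.items()
        if curves
    }
    return ExperimentReport(
        config={
            "n_train": config.n_train,
            "replicates": config.replicates,
            "d_max": config.d_max,
            "interactions": config.interactions,
            "lambda_grid": list(config.lambda_grid),
            "eb_sources": list(config.eb_sources),
            "seed": config.seed,
        },
        replicates=pd.DataFrame(rows),
        avg_roc=avg_roc,
    )


def loocv(
    X: np.ndarray,
    Y: np.ndarray,
    names: Sequence[str],
    network: Network,
    pathways: PathwayAnnotation,
    config: EvalConfig,
    regimes: Sequence[Regime] = (Regime("eb"),),
) -> ExperimentReport:
    """Leave-one-out cross-validation; empirical Bayes is re-run per fold."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise InvalidArgumentError("LOOCV needs at least 3 samples")
    interactions = True if config.interactions is None else config.interactions
    space = enumerate_models(p, config.d_max)
    sources = prior_sources(pathways, network, names, include_mrf=config.include_mrf)

    rows: List[dict] = []
    for i in range(n):
        keep = np.arange(n) != i
        ev = SpaceEvidence(X[keep], Y[keep], space, interactions=interactions)
        for regime in regimes:
            spec, eb_info = _regime_spec(
                regime, sources, space, (config.lambda_grid, config.eb_sources), ev
            )
            post = model_posterior(ev, spec)
            row = {"replicate": i, "seed": config.seed, "regime": regime.name}
            for mode, col in (("model_average", "err_ma"), ("map", "err_map")):
                pred = predict(X[i : i + 1], None, None, post, mode, evidence=ev)
                row[col] = float(abs(pred[0] - Y[i]))
            row.update(eb_info)
            rows.append(row)
    return ExperimentReport(
        config={"folds": n, "d_max": config.d_max, "interactions": interactions},
        replicates=pd.DataFrame(rows),
    )
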