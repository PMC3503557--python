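"""Biologically informative model priors P(gamma | m, lambda) ∝ exp(lambda f_m(gamma)).

Two pathway-based scoring functions are provided, plus a Markov random field
energy and the flat prior:

* ``f1`` (pathway count): max(0, K_gamma - 1), where K_gamma is the *minimum*
  number of pathways whose restriction to the model jointly covers all
  pathway-annotated included predictors — an exact set cover, so a predictor
  belonging to several pathways is never double counted.
* ``f2`` (intra-pathway distance): max(0, D_gamma - 1), where D_gamma is the
  mean shortest-path distance over all included pairs that share at least one
  pathway, each pair counted once (at its minimum distance across shared
  pathways, computed on the pathway-induced subgraph).  Models containing only
  singletons, and the empty model, have D_gamma = 0, so the prior is
  indifferent between singletons and tightly clustered models (D_gamma = 1).
* MRF energy: gamma^T A gamma over the network adjacency matrix; with
  lambda > 0 this rewards co-inclusion of network neighbours, with lambda < 0
  it penalises them.  Unlike f2 it is not agnostic to model size.

With no pathway information, f1 and f2 are identically zero and the priors
reduce exactly to the flat prior over the restricted space.  The strength
lambda may take either sign for every source.  Normalisers are computed by a
full log-sum-exp pass over the restricted space and cached per (source,
space); lambda = 0 reproduces the flat prior for any source.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, InvalidArgumentError
from .model_space import InclusionVector, ModelSpace

__all__ = [
    "Network",
    "PathwayAnnotation",
    "MRFAdjacency",
    "PathwayFeatures",
    "pathway_count_feature",
    "intra_pathway_distance_feature",
    "mrf_energy",
    "PriorSource",
    "PathwayCountPrior",
    "IntraPathwayDistancePrior",
    "MRFPrior",
    "FlatPrior",
    "PriorSpec",
    "make_prior",
    "log_prior",
    "log_prior_vector",
]

logger = logging.getLogger("ebvs")


class Network:
    """Undirected molecular network over named nodes.

    Directed edge lists are symmetrised on construction; self-loops are
    dropped.  Nodes may be a subset of the predictors and vice versa —
    predictors absent from the network are simply inert in the priors.
    """

    def __init__(
        self,
        edges: Iterable[Tuple[str, str]],
        nodes: Optional[Iterable[str]] = None,
    ) -> None:
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                continue
            g.add_edge(u, v)
        self.graph = g

    @property
    def nodes(self) -> Tuple[str, ...]:
        return tuple(self.graph.nodes)

    @property
    def edges(self) -> Tuple[Tuple[str, str], ...]:
        return tuple(self.graph.edges)

    def adjacency(self, predictor_names: Sequence[str]) -> "MRFAdjacency":
        """Binary adjacency over the predictor ordering; unknown names are
        isolated vertices."""
        p = len(predictor_names)
        index = {name: j for j, name in enumerate(predictor_names)}
        A = np.zeros((p, p))
        for u, v in self.graph.edges:
            if u in index and v in index:
                A[index[u], index[v]] = A[index[v], index[u]] = 1.0
        return MRFAdjacency(A)


@dataclass(frozen=True)
class PathwayAnnotation:
    """Named pathway member sets; membership may overlap, nodes may be
    unassigned.  An empty annotation is legal and yields flat priors."""

    pathways: Mapping[str, FrozenSet[str]]

    @classmethod
    def from_sets(cls, pathways: Mapping[str, Iterable[str]]) -> "PathwayAnnotation":
        return cls({k: frozenset(v) for k, v in pathways.items()})

    @property
    def names(self) -> Tuple[str, ...]:
        return tuple(self.pathways)

    def validate(self, net: Network) -> None:
        """Check each pathway is non-empty and induces a connected subgraph —
        the assumption that makes intra-pathway distances well defined."""
        for name, members in self.pathways.items():
            if not members:
                raise ConfigurationError(f"pathway {name!r} is empty")
            sub = net.graph.subgraph(members & set(net.graph.nodes))
            if len(sub) != len(members):
                missing = sorted(members - set(net.graph.nodes))
                raise ConfigurationError(
                    f"pathway {name!r} has members absent from the network: {missing}"
                )
            if len(sub) > 1 and not nx.is_connected(sub):
                raise ConfigurationError(
                    f"pathway {name!r} does not induce a single connected component"
                )


@dataclass(frozen=True)
class MRFAdjacency:
    """Binary symmetric predictor adjacency matrix with zero diagonal."""

    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise InvalidArgumentError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise InvalidArgumentError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise InvalidArgumentError("adjacency must have zero diagonal")
        if not np.isin(A, (0.0, 1.0)).all():
            raise InvalidArgumentError("adjacency must be binary")
        object.__setattr__(self, "A", A)


def _min_set_cover(sets: List[FrozenSet[int]]) -> int:
    """Exact minimum number of sets covering their union (brute force)."""
    target: FrozenSet[int] = frozenset().union(*sets)
    uniq = sorted(set(sets), key=lambda s: (-len(s), sorted(s)))
    for r in range(1, len(uniq) + 1):
        for comb in itertools.combinations(uniq, r):
            if frozenset().union(*comb) == target:
                return r
    raise AssertionError("unreachable: full collection always covers its union")


class PathwayFeatures:
    """Precomputed f1/f2 machinery for a fixed predictor ordering.

    Shortest paths are computed once per pathway on its induced subgraph; a
    pair sharing several pathways contributes once, at its minimum distance
    across the shared pathways.
    """

    def __init__(
        self,
        ann: PathwayAnnotation,
        net: Optional[Network],
        predictor_names: Sequence[str],
    ) -> None:
        index = {name: j for j, name in enumerate(predictor_names)}
        self.p = len(predictor_names)
        self.member_indices: List[FrozenSet[int]] = []
        self._pair_distance: Dict[Tuple[int, int], float] = {}
        for pw_name, members in ann.pathways.items():
            known = members & index.keys()
            if len(known) < len(members):
                logger.debug(
                    "pathway %r: %d members are not predictors",
                    pw_name,
                    len(members) - len(known),
                )
            idx = frozenset(index[m] for m in known)
            self.member_indices.append(idx)
            if net is None or len(idx) < 2:
                continue
            sub = net.graph.subgraph(members & set(net.graph.nodes))
            for src, dists in nx.all_pairs_shortest_path_length(sub):
                if src not in index:
                    continue
                i = index[src]
                for dst, d in dists.items():
                    if dst not in index:
                        continue
                    j = index[dst]
                    if i < j:
                        key = (i, j)
                        prev = self._pair_distance.get(key)
                        if prev is None or d < prev:
                            self._pair_distance[key] = float(d)

    def pathway_count(self, indices: Sequence[int]) -> int:
        """K_gamma: minimum number of pathways covering the annotated part."""
        included = set(indices)
        restricted = [s & included for s in self.member_indices]
        restricted = [frozenset(s) for s in restricted if s]
        if not restricted:
            return 0
        return _min_set_cover(restricted)

    def f1(self, indices: Sequence[int]) -> float:
        return float(max(0, self.pathway_count(indices) - 1))

    def f2(self, indices: Sequence[int]) -> float:
        included = set(indices)
        dists = []
        for s in self.member_indices:
            hits = sorted(s & included)
            for a, b in itertools.combinations(hits, 2):
                d = self._pair_distance.get((a, b))
                if d is None:
                    raise ConfigurationError(
                        f"no intra-pathway path between predictors {a} and {b}"
                    )
                dists.append(((a, b), d))
        if not dists:
            return 0.0  # singleton-only or empty model
        # each unordered pair contributes once
        by_pair = dict(dists)
        d_gamma = float(np.mean(list(by_pair.values())))
        return max(0.0, d_gamma - 1.0)


def pathway_count_feature(
    gamma: InclusionVector,
    ann: PathwayAnnotation,
    predictor_names: Optional[Sequence[str]] = None,
) -> float:
    """f1(gamma) = max(0, K_gamma - 1) with K_gamma an exact set cover."""
    names = _default_names(gamma.p, predictor_names)
    return PathwayFeatures(ann, None, names).f1(gamma.indices)


def intra_pathway_distance_feature(
    gamma: InclusionVector,
    ann: PathwayAnnotation,
    net: Network,
    predictor_names: Optional[Sequence[str]] = None,
) -> float:
    """f2(gamma) = max(0, D_gamma - 1), mean shared-pathway pair distance."""
    names = _default_names(gamma.p, predictor_names)
    return PathwayFeatures(ann, net, names).f2(gamma.indices)


def mrf_energy(gamma: InclusionVector, adj: MRFAdjacency) -> float:
    """gamma^T A gamma: each included adjacent pair contributes 2."""
    if adj.A.shape[0] != gamma.p:
        raise InvalidArgumentError("adjacency size does not match gamma")
    g = np.asarray(gamma.bits, dtype=float)
    return float(g @ adj.A @ g)


def _default_names(p: int, names: Optional[Sequence[str]]) -> Sequence[str]:
    if names is not None:
        if len(names) != p:
            raise InvalidArgumentError("predictor_names length does not match gamma")
        return names
    return [f"x{j}" for j in range(p)]


# ---------------------------------------------------------------------------
# Prior sources and normalised priors
# ---------------------------------------------------------------------------


class PriorSource:
    """A model-scoring function f_m, with per-space feature caching."""

    name: str = "abstract"
    m: int = -1

    def feature(self, indices: Sequence[int]) -> float:
        raise NotImplementedError

    def feature_vector(self, space: ModelSpace) -> np.ndarray:
        key = (space.p, space.d_max)
        cache = getattr(self, "_fv_cache", None)
        if cache is None:
            cache = {}
            self._fv_cache = cache
        if key not in cache:
            cache[key] = np.array(
                [self.feature(idx) for idx in space.iter_indices()]
            )
        return cache[key]


class FlatPrior(PriorSource):
    """Uninformative source: f ≡ 0, so the prior is uniform at any lambda."""

    name = "flat"
    m = 0

    def feature(self, indices: Sequence[int]) -> float:
        return 0.0


class PathwayCountPrior(PriorSource):
    name = "pathway_count"
    m = 1

    def __init__(
        self,
        ann: PathwayAnnotation,
        predictor_names: Sequence[str],
    ) -> None:
        self._features = PathwayFeatures(ann, None, predictor_names)

    def feature(self, indices: Sequence[int]) -> float:
        return self._features.f1(indices)


class IntraPathwayDistancePrior(PriorSource):
    name = "intra_pathway_distance"
    m = 2

    def __init__(
        self,
        ann: PathwayAnnotation,
        net: Network,
        predictor_names: Sequence[str],
    ) -> None:
        ann.validate(net)
        self._features = PathwayFeatures(ann, net, predictor_names)

    def feature(self, indices: Sequence[int]) -> float:
        return self._features.f2(indices)


class MRFPrior(PriorSource):
    name = "mrf"
    m = 3

    def __init__(self, adj: MRFAdjacency) -> None:
        self.adj = adj

    def feature(self, indices: Sequence[int]) -> float:
        idx = np.asarray(sorted(indices), dtype=np.intp)
        if idx.size < 2:
            return 0.0
        return float(self.adj.A[np.ix_(idx, idx)].sum())


@dataclass(frozen=True)
class PriorSpec:
    """A normalised model prior: source m, strength lambda, log Z over a
    specific restricted space."""

    source: PriorSource
    lam: float
    log_normalizer: float
    space_key: Tuple[int, int] = field(default=None)

    @property
    def m(self) -> int:
        return self.source.m

    @property
    def name(self) -> str:
        return self.source.name


def make_prior(source: PriorSource, lam: float, space: ModelSpace) -> PriorSpec:
    """Normalise exp(lambda f_m(gamma)) over the restricted space."""
    f = source.feature_vector(space)
    log_z = float(logsumexp(lam * f))
    return PriorSpec(
        source=source,
        lam=float(lam),
        log_normalizer=log_z,
        space_key=(space.p, space.d_max),
    )


def _check_space(spec: PriorSpec, space: ModelSpace) -> None:
    if spec.space_key != (space.p, space.d_max):
        raise InvalidArgumentError("prior was normalised over a different space")


def log_prior(gamma: InclusionVector, spec: PriorSpec, space: ModelSpace) -> float:
    """log P(gamma | m, lambda) = lambda f_m(gamma) - log Z(m, lambda)."""
    _check_space(spec, space)
    return spec.lam * spec.source.feature(gamma.indices) - spec.log_normalizer


def log_prior_vector(spec: PriorSpec, space: ModelSpace) -> np.ndarray:
    """Log prior of every model, in the space's canonical order."""
    _check_space(spec, space)
    return spec.lam * spec.source.feature_vector(space) - spec.log_normalizer
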