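"""Synthetic worlds: network-structured predictors with known influential
variable subsets, for testing every stage of the pipeline without external
data.

Predictors are drawn from a zero-mean Gaussian graphical model whose
precision matrix follows the molecular network (nonzero partial correlation
on edges), so adjacent proteins are more correlated than distant ones — an
idealisation of the correlation structure seen in single-cell
phospho-proteomic data.  A known three-variable truth model generates the
response:

* Scenario 1: Y = A + B*C + eps, with {A,B,C} spread over two pathways at a
  large intra-pathway distance — favoured by the distance prior with
  lambda > 0.
* Scenario 2: Y = A + B*C + eps, with {A,B,C} mutually adjacent inside a
  single pathway — favoured by either pathway prior with lambda < 0.
* Scenario 3: Y = A + 2B + 3C + eps, same truth placement as scenario 2 but a
  purely linear response (analysed without interaction terms).

The default world is an 11-protein signalling network with four pathways (two
hub kinases, PKC and PKA, belong to all four), mirroring the classic
single-cell signalling benchmark; its topology is a hand-curated stand-in,
fixed in source, chosen so that the distant trio {PIP3, ERK, P38} has
pathway-count feature f1 = 1 and distance feature f2 = 2.5 while the compact
trio {RAF, MEK, PKA} has f1 = f2 = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError
from .model_space import InclusionVector
from .priors import Network, PathwayAnnotation, PathwayFeatures

__all__ = [
    "SACHS_NODES",
    "SACHS_EDGES",
    "SACHS_PATHWAYS",
    "SimulationScenario",
    "SyntheticWorld",
    "generate_world",
    "sachs_like_fixture",
]

# ---------------------------------------------------------------------------
# Fixed 11-protein fixture topology (synthetic stand-in, hand-curated)
# ---------------------------------------------------------------------------

SACHS_NODES: Tuple[str, ...] = (
    "RAF", "MEK", "PLCG", "PIP2", "PIP3", "ERK", "AKT", "PKA", "PKC", "P38", "JNK",
)

SACHS_EDGES: Tuple[Tuple[str, str], ...] = (
    ("PLCG", "PIP2"),
    ("PLCG", "PIP3"),
    ("PIP2", "PIP3"),
    ("PIP2", "PKC"),
    ("PKC", "PKA"),
    ("PKC", "RAF"),
    ("PKC", "MEK"),
    ("PKC", "P38"),
    ("PKC", "JNK"),
    ("PKA", "RAF"),
    ("PKA", "MEK"),
    ("PKA", "ERK"),
    ("PKA", "AKT"),
    ("RAF", "MEK"),
    ("MEK", "ERK"),
    ("ERK", "AKT"),
)

# Four pathways; PKC and PKA are members of all four.
SACHS_PATHWAYS: Dict[str, Tuple[str, ...]] = {
    "raf_mek_erk": ("RAF", "MEK", "ERK", "PKC", "PKA"),
    "phospholipid": ("PLCG", "PIP2", "PIP3", "ERK", "PKC", "PKA"),
    "stress_mapk": ("P38", "JNK", "ERK", "PKC", "PKA"),
    "akt": ("AKT", "PKC", "PKA"),
}

# Truth placements on the fixture, as (A, B, C) role order.
_FIXTURE_TRUTH = {
    1: ("PIP3", "ERK", "P38"),
    2: ("RAF", "MEK", "PKA"),
    3: ("RAF", "MEK", "PKA"),
}


@dataclass(frozen=True)
class SimulationScenario:
    """Study condition: which truth placement and response rule to use."""

    scenario: int
    n_total: int = 853
    snr: float = 4.0  # var(signal) / var(noise)

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise InvalidArgumentError("scenario must be 1, 2 or 3")
        if self.n_total < 6:
            raise InvalidArgumentError("n_total too small")
        if self.snr <= 0:
            raise InvalidArgumentError("snr must be positive")

    @property
    def interactions(self) -> bool:
        """Scenario 3 is analysed with a linear model without interactions."""
        return self.scenario != 3

    def signal(self, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
        if self.scenario in (1, 2):
            return a + b * c
        return a + 2.0 * b + 3.0 * c


@dataclass
class SyntheticWorld:
    """A network, pathway annotation, predictor matrix and response with a
    known truth model."""

    names: Tuple[str, ...]
    network: Network
    pathways: PathwayAnnotation
    X: np.ndarray
    Y: np.ndarray
    truth: InclusionVector
    truth_roles: Tuple[int, int, int]  # (A, B, C) predictor indices
    scenario: SimulationScenario
    seed: int
    noise_sd: float

    @property
    def p(self) -> int:
        return len(self.names)

    @property
    def n_total(self) -> int:
        return self.X.shape[0]


def _covariance_from_adjacency(A: np.ndarray, rho: float) -> np.ndarray:
    """Correlation matrix of a Gaussian graphical model on the network.

    Precision = I - rho*A, with the diagonal lifted if needed to keep the
    smallest eigenvalue at 0.05; the realised edge partial correlations are
    therefore at most the nominal rho.
    """
    p = A.shape[0]
    omega = np.eye(p) - rho * A
    w_min = float(np.linalg.eigvalsh(omega)[0])
    if w_min < 0.05:
        omega += (0.05 - w_min) * np.eye(p)
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def _general_topology(
    p: int, K: int, rng: np.random.Generator
) -> Tuple[Tuple[str, ...], Network, PathwayAnnotation]:
    """Random connected network partitioned into K connected pathway
    subgraphs sharing two hub nodes; each pathway contains a triangle."""
    names = tuple(f"N{i:02d}" for i in range(p))
    hubs = list(names[:2])
    groups: List[List[str]] = [[] for _ in range(K)]
    for i, name in enumerate(names[2:]):
        groups[i % K].append(name)
    if any(not g for g in groups):
        raise ConfigurationError("not enough nodes to populate every pathway")

    edges = set()
    pathways: Dict[str, Tuple[str, ...]] = {}
    for k, grp in enumerate(groups):
        members = grp + hubs
        order = list(members)
        rng.shuffle(order)
        local_adj: Dict[str, List[str]] = {m: [] for m in members}
        for t in range(1, len(order)):
            parent = order[int(rng.integers(0, t))]
            child = order[t]
            edges.add(tuple(sorted((parent, child))))
            local_adj[parent].append(child)
            local_adj[child].append(parent)
        # close one triangle so a compact truth trio always exists
        if len(members) >= 3:
            v = next(m for m in sorted(local_adj) if len(local_adj[m]) >= 2)
            a, b = sorted(local_adj[v])[:2]
            edges.add(tuple(sorted((a, b))))
        pathways[f"pathway_{k}"] = tuple(sorted(members))

    net = Network(sorted(edges), nodes=names)
    ann = PathwayAnnotation.from_sets(pathways)
    return names, net, ann


def _place_truth(
    scenario: SimulationScenario,
    ann: PathwayAnnotation,
    net: Network,
    names: Sequence[str],
) -> Tuple[int, int, int]:
    """Deterministically place the three influential variables so that the
    truth matches the scenario's prior structure."""
    pf = PathwayFeatures(ann, net, names)
    if scenario.scenario in (2, 3):
        # a triangle within a single pathway: all pairwise distances 1
        for members in pf.member_indices:
            for trio in itertools.combinations(sorted(members), 3):
                pairs = list(itertools.combinations(trio, 2))
                if all(pf._pair_distance.get(pr) == 1.0 for pr in pairs):
                    return trio
        raise ConfigurationError(
            "no mutually adjacent trio inside a single pathway"
        )
    # scenario 1: two pathways, large intra-pathway distance
    best: Optional[Tuple[float, Tuple[int, int, int]]] = None
    for trio in itertools.combinations(range(len(names)), 3):
        pairs = list(itertools.combinations(trio, 2))
        sharing = [pr for pr in pairs if pr in pf._pair_distance]
        if len(sharing) < 2 or pf.pathway_count(trio) != 2:
            continue
        f2 = pf.f2(trio)
        if best is None or f2 > best[0]:
            best = (f2, trio)
    if best is None or best[0] < 1.0:
        raise ConfigurationError(
            "no two-pathway trio with large intra-pathway distance exists"
        )
    return best[1]


def generate_world(
    p: int,
    K: int,
    scenario: SimulationScenario,
    seed: int,
    edge_partial_corr: float = 0.4,
) -> SyntheticWorld:
    """Generate a fully seed-deterministic synthetic world.

    For p = 11, K = 4 the fixed fixture topology is used (so replicates share
    the study network, as in a subsampling protocol); otherwise a random
    topology with two hub nodes shared by all pathways is built.
    """
    if p < 6:
        raise InvalidArgumentError("p must be >= 6")
    if K < 2:
        raise InvalidArgumentError("K must be >= 2")
    rng = np.random.default_rng(seed)
    if p == 11 and K == 4:
        names: Tuple[str, ...] = SACHS_NODES
        net = Network(SACHS_EDGES, nodes=SACHS_NODES)
        ann = PathwayAnnotation.from_sets(SACHS_PATHWAYS)
        roles = tuple(names.index(x) for x in _FIXTURE_TRUTH[scenario.scenario])
    else:
        names, net, ann = _general_topology(p, K, rng)
        roles = _place_truth(scenario, ann, net, names)
    ann.validate(net)

    adj = net.adjacency(names).A
    sigma = _covariance_from_adjacency(adj, edge_partial_corr)
    L = np.linalg.cholesky(sigma)
    X = rng.standard_normal((scenario.n_total, p)) @ L.T

    a, b, c = roles
    signal = scenario.signal(X[:, a], X[:, b], X[:, c])
    noise_sd = float(signal.std(ddof=1) / np.sqrt(scenario.snr))
    Y = signal + noise_sd * rng.standard_normal(scenario.n_total)

    return SyntheticWorld(
        names=names,
        network=net,
        pathways=ann,
        X=X,
        Y=Y,
        truth=InclusionVector.from_indices(p, roles),
        truth_roles=(a, b, c),
        scenario=scenario,
        seed=seed,
        noise_sd=noise_sd,
    )


def sachs_like_fixture(
    seed: int, scenario: int = 1, n_total: int = 853, snr: float = 4.0
) -> SyntheticWorld:
    """The default 11-protein, 4-pathway world with n_total samples."""
    return generate_world(
        p=11, K=4, scenario=SimulationScenario(scenario, n_total=n_total, snr=snr),
        seed=seed,
    )
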