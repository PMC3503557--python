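import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from ebvs import (
    FlatPrior,
    InclusionVector,
    IntraPathwayDistancePrior,
    MRFAdjacency,
    MRFPrior,
    Network,
    PathwayAnnotation,
    PathwayCountPrior,
    enumerate_models,
    intra_pathway_distance_feature,
    log_prior,
    make_prior,
    mrf_energy,
    pathway_count_feature,
)
from ebvs.errors import ConfigurationError, InvalidArgumentError
from ebvs.priors import PathwayFeatures, log_prior_vector
from oracles import min_cover_oracle


@pytest.fixture(scope="module")
def fixture_priors(request):
    from ebvs.synthetic import SACHS_EDGES, SACHS_NODES, SACHS_PATHWAYS

    net = Network(SACHS_EDGES, nodes=SACHS_NODES)
    ann = PathwayAnnotation.from_sets(SACHS_PATHWAYS)
    ann.validate(net)
    return net, ann, list(SACHS_NODES)


def _gamma(names, members):
    return InclusionVector.from_indices(
        len(names), [names.index(m) for m in members]
    )


class TestWorkedFixtureValues:
    """The two trios whose prior features are known on the study network."""

    def test_distant_trio(self, fixture_priors):
        net, ann, names = fixture_priors
        g = _gamma(names, ["PIP3", "ERK", "P38"])
        assert pathway_count_feature(g, ann, names) == 1.0
        assert intra_pathway_distance_feature(g, ann, net, names) == 2.5

    def test_compact_trio(self, fixture_priors):
        net, ann, names = fixture_priors
        g = _gamma(names, ["RAF", "MEK", "PKA"])
        assert pathway_count_feature(g, ann, names) == 0.0
        assert intra_pathway_distance_feature(g, ann, net, names) == 0.0


class TestPathwayCount:
    def test_empty_model(self, fixture_priors):
        net, ann, names = fixture_priors
        g = InclusionVector.from_indices(len(names), [])
        assert pathway_count_feature(g, ann, names) == 0.0

    def test_no_double_counting(self):
        """A node in two pathways is counted once, so E1={a,b}, E2={a,c} and
        gamma={a,b,c} still needs both pathways: K=2, f1=1."""
        ann = PathwayAnnotation.from_sets({"E1": ["a", "b"], "E2": ["a", "c"]})
        g = InclusionVector.from_indices(3, [0, 1, 2])
        assert pathway_count_feature(g, ann, ["a", "b", "c"]) == 1.0

    def test_unannotated_predictors_are_inert(self):
        ann = PathwayAnnotation.from_sets({"E1": ["a"]})
        g = InclusionVector.from_indices(3, [0, 1, 2])  # b, c unassigned
        assert pathway_count_feature(g, ann, ["a", "b", "c"]) == 0.0

    @given(st.data())
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_matches_exhaustive_cover_oracle(self, data):
        n_pw = data.draw(st.integers(1, 6))
        nodes = [f"n{i}" for i in range(8)]
        pws = {
            f"pw{k}": data.draw(
                st.sets(st.sampled_from(nodes), min_size=1, max_size=5)
            )
            for k in range(n_pw)
        }
        included = data.draw(st.sets(st.sampled_from(nodes), max_size=6))
        ann = PathwayAnnotation.from_sets(pws)
        g = InclusionVector.from_indices(
            len(nodes), [nodes.index(x) for x in included]
        )
        k = min_cover_oracle(
            [set(v) & included for v in pws.values()]
        )
        assert pathway_count_feature(g, ann, nodes) == max(0, k - 1)


class TestIntraPathwayDistance:
    def test_singleton_only_model_scores_zero(self, fixture_priors):
        net, ann, names = fixture_priors
        # PLCG (phospholipid only) and JNK (stress only): no shared pathway
        g = _gamma(names, ["PLCG", "JNK"])
        assert intra_pathway_distance_feature(g, ann, net, names) == 0.0

    def test_adding_singleton_leaves_f2_unchanged(self, fixture_priors):
        net, ann, names = fixture_priors
        g = _gamma(names, ["PIP3", "ERK", "P38"])
        # AKT shares no pathway with PIP3 or P38; with ERK it shares none
        # either (AKT pathway contains only AKT + hubs)
        g_plus = _gamma(names, ["PIP3", "ERK", "P38", "AKT"])
        assert intra_pathway_distance_feature(
            g_plus, ann, net, names
        ) == intra_pathway_distance_feature(g, ann, net, names)

    def test_indifference_between_singletons_and_distance_one(self, fixture_priors):
        """Singleton-only models and models with all shared pairs adjacent
        both score 0."""
        net, ann, names = fixture_priors
        adjacent = _gamma(names, ["RAF", "MEK"])
        singletons = _gamma(names, ["PLCG", "JNK"])
        assert intra_pathway_distance_feature(adjacent, ann, net, names) == 0.0
        assert intra_pathway_distance_feature(singletons, ann, net, names) == 0.0

    def test_f2_agnostic_to_model_size_and_pathway_count(self):
        """Models of different sizes and pathway counts share f2 when their
        mean shared-pathway distance coincides."""
        # one path pathway a-b-c-d, another e-f-g
        net = Network([("a", "b"), ("b", "c"), ("c", "d"), ("e", "f"), ("f", "g")])
        names = list("abcdefg")
        ann = PathwayAnnotation.from_sets(
            {"p1": ["a", "b", "c", "d"], "p2": ["e", "f", "g"]}
        )
        ann.validate(net)
        small = InclusionVector.from_indices(7, [0, 2])  # a-c: distance 2
        large = InclusionVector.from_indices(7, [0, 2, 4, 6])  # a-c and e-g
        f_small = intra_pathway_distance_feature(small, ann, net, names)
        f_large = intra_pathway_distance_feature(large, ann, net, names)
        assert f_small == f_large == 1.0

    def test_min_distance_across_shared_pathways(self):
        """A pair in two pathways contributes once, at its smaller
        pathway-local distance."""
        net = Network([("a", "x", ), ("x", "b"), ("a", "b")])
        names = ["a", "b", "x"]
        ann = PathwayAnnotation.from_sets(
            {"long": ["a", "x", "b"], "short": ["a", "b"]}
        )
        ann.validate(net)
        g = InclusionVector.from_indices(3, [0, 1])
        assert intra_pathway_distance_feature(g, ann, net, names) == 0.0


class TestMRF:
    def test_energies(self, fixture_priors):
        net, ann, names = fixture_priors
        adj = net.adjacency(names)
        none_adjacent = _gamma(names, ["PLCG", "JNK"])
        one_edge = _gamma(names, ["RAF", "MEK"])
        assert mrf_energy(none_adjacent, adj) == 0.0
        assert mrf_energy(one_edge, adj) == 2.0
        full = InclusionVector.from_indices(len(names), range(len(names)))
        assert mrf_energy(full, adj) == 2 * len(net.edges)

    def test_adjacency_validation(self):
        with pytest.raises(InvalidArgumentError):
            MRFAdjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))  # asymmetric
        with pytest.raises(InvalidArgumentError):
            MRFAdjacency(np.array([[1.0, 0.0], [0.0, 0.0]]))  # diagonal


class TestNormalisedPrior:
    def test_lambda_zero_is_flat_for_any_source(self, fixture_priors):
        net, ann, names = fixture_priors
        space = enumerate_models(len(names), 2)
        for source in (
            PathwayCountPrior(ann, names),
            IntraPathwayDistancePrior(ann, net, names),
            MRFPrior(net.adjacency(names)),
        ):
            spec = make_prior(source, 0.0, space)
            g = InclusionVector.from_indices(len(names), [0, 4])
            assert log_prior(g, spec, space) == pytest.approx(-np.log(len(space)))

    def test_normalisation_sums_to_one(self, fixture_priors):
        net, ann, names = fixture_priors
        space = enumerate_models(len(names), 3)
        spec = make_prior(IntraPathwayDistancePrior(ann, net, names), 1.5, space)
        total = logsumexp(log_prior_vector(spec, space))
        assert np.exp(total) == pytest.approx(1.0, abs=1e-10)

    def test_probabilities_match_hand_normalised_table(self):
        """p=3, two pathways, lambda=1: exp(f2)/Z by explicit enumeration."""
        net = Network([("a", "b"), ("b", "c")])
        names = ["a", "b", "c"]
        ann = PathwayAnnotation.from_sets({"p1": ["a", "b", "c"]})
        ann.validate(net)
        space = enumerate_models(3, 3)
        source = IntraPathwayDistancePrior(ann, net, names)
        spec = make_prior(source, 1.0, space)
        feats = np.array(
            [source.feature(idx) for idx in space.iter_indices()]
        )
        table = np.exp(feats) / np.exp(feats).sum()
        for g, expect in zip(space, table):
            assert np.exp(log_prior(g, spec, space)) == pytest.approx(expect)

    def test_empty_annotation_reduces_to_flat(self):
        ann = PathwayAnnotation.from_sets({})
        net = Network([])
        names = [f"x{i}" for i in range(5)]
        space = enumerate_models(5, 3)
        flat = make_prior(FlatPrior(), 0.0, space)
        for lam in (-3.0, 2.5):
            for source in (
                PathwayCountPrior(ann, names),
                IntraPathwayDistancePrior(ann, net, names),
            ):
                spec = make_prior(source, lam, space)
                np.testing.assert_array_equal(
                    log_prior_vector(spec, space), log_prior_vector(flat, space)
                )

    def test_space_mismatch_rejected(self, fixture_priors):
        net, ann, names = fixture_priors
        space = enumerate_models(len(names), 2)
        other = enumerate_models(len(names), 3)
        spec = make_prior(PathwayCountPrior(ann, names), 1.0, space)
        g = InclusionVector.from_indices(len(names), [0])
        with pytest.raises(InvalidArgumentError):
            log_prior(g, spec, other)


class TestValidation:
    def test_disconnected_pathway_rejected(self):
        net = Network([("a", "b"), ("c", "d")])
        ann = PathwayAnnotation.from_sets({"bad": ["a", "b", "c", "d"]})
        with pytest.raises(ConfigurationError, match="bad"):
            ann.validate(net)

    def test_empty_pathway_rejected(self):
        net = Network([("a", "b")])
        with pytest.raises(ConfigurationError):
            PathwayAnnotation.from_sets({"void": []}).validate(net)

    def test_symmetrisation_and_self_loops(self):
        net = Network([("a", "b"), ("b", "a"), ("c", "c")])
        assert set(map(frozenset, net.edges)) == {frozenset({"a", "b"})}
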