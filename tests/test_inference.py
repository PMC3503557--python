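import numpy as np
import pytest
from scipy.special import logsumexp

from ebvs import (
    FlatPrior,
    SpaceEvidence,
    enumerate_models,
    inclusion_probabilities,
    make_prior,
    map_model,
    model_posterior,
    predict,
)
from ebvs.inference import PosteriorSummary
from oracles import model_average_prediction_oracle


@pytest.fixture()
def p3_setup():
    rng = np.random.default_rng(9)
    X = rng.standard_normal((15, 3))
    Y = X[:, 1] + 0.4 * X[:, 0] * X[:, 2] + 0.3 * rng.standard_normal(15)
    space = enumerate_models(3, 3)
    ev = SpaceEvidence(X, Y, space)
    spec = make_prior(FlatPrior(), 0.0, space)
    return X, Y, space, ev, spec


def _manual_summary(space, log_post, spec=None):
    return PosteriorSummary(
        space=space, spec=spec, log_posterior=np.asarray(log_post, dtype=float)
    )


class TestModelPosterior:
    def test_normalises_to_one(self, p3_setup):
        X, Y, space, ev, spec = p3_setup
        post = model_posterior(ev, spec)
        assert np.exp(logsumexp(post.log_posterior)) == pytest.approx(1, abs=1e-10)

    def test_flat_prior_posterior_proportional_to_evidence(self, p3_setup):
        X, Y, space, ev, spec = p3_setup
        post = model_posterior(ev, spec)
        np.testing.assert_allclose(
            post.log_posterior, ev.log_ml - logsumexp(ev.log_ml), atol=1e-12
        )

    def test_matches_bruteforce_normalisation(self, p3_setup):
        X, Y, space, ev, spec = p3_setup
        post = model_posterior(ev, spec)
        unnorm = ev.log_ml - np.log(len(space))
        shift = unnorm.max()
        brute = np.exp(unnorm - shift) / np.exp(unnorm - shift).sum()
        np.testing.assert_allclose(np.exp(post.log_posterior), brute, atol=1e-12)

    def test_invariant_under_response_rescaling(self, p3_setup):
        X, Y, space, ev, spec = p3_setup
        post = model_posterior(ev, spec)
        post_scaled = model_posterior(SpaceEvidence(X, 4.2 * Y, space), spec)
        np.testing.assert_allclose(
            post.log_posterior, post_scaled.log_posterior, atol=1e-9
        )


class TestInclusionProbabilities:
    def test_point_mass_posterior(self):
        space = enumerate_models(3, 3)
        log_post = np.full(len(space), -np.inf)
        target = list(space.iter_indices()).index((0, 2))
        log_post[target] = 0.0
        post = _manual_summary(space, log_post)
        np.testing.assert_array_equal(
            inclusion_probabilities(post), [1.0, 0.0, 1.0]
        )

    def test_flat_posterior_gives_half(self):
        space = enumerate_models(3, 3)
        post = _manual_summary(space, np.full(8, -np.log(8)))
        np.testing.assert_allclose(inclusion_probabilities(post), 0.5, atol=1e-12)

    def test_sum_is_expected_model_size(self, p3_setup):
        X, Y, space, ev, spec = p3_setup
        post = model_posterior(ev, spec)
        sizes = np.array([len(idx) for idx in space.iter_indices()])
        expected = float(np.exp(post.log_posterior) @ sizes)
        assert inclusion_probabilities(post).sum() == pytest.approx(expected)
        assert expected <= space.d_max + 1e-12


class TestMAP:
    def test_matches_exhaustive_argmax(self, p3_setup):
        X, Y, space, ev, spec = p3_setup
        post = model_posterior(ev, spec)
        best = max(
            zip(post.log_posterior, space.iter_indices()), key=lambda t: t[0]
        )[1]
        assert map_model(post).indices == best

    def test_tie_broken_by_enumeration_order(self):
        space = enumerate_models(3, 3)
        log_post = np.full(8, -np.inf)
        order = list(space.iter_indices())
        for idx in ((1,), (0, 1)):
            log_post[order.index(idx)] = np.log(0.5)
        post = _manual_summary(space, log_post)
        assert map_model(post).indices == (1,)  # smaller model first


class TestPrediction:
    def test_point_mass_on_empty_model_predicts_training_mean(self, p3_setup):
        X, Y, space, ev, spec = p3_setup
        log_post = np.full(len(space), -np.inf)
        log_post[0] = 0.0  # the empty model is first
        post = _manual_summary(space, log_post, spec)
        preds = predict(X[:4], X, Y, post)
        np.testing.assert_allclose(preds, Y.mean())

    def test_model_average_in_convex_hull(self, p3_setup):
        X, Y, space, ev, spec = p3_setup
        post = model_posterior(ev, spec)
        X_new = np.random.default_rng(1).standard_normal((6, 3))
        ma = predict(X_new, None, None, post, evidence=ev)
        per_model = []
        for g in space:
            point = _manual_summary(space, np.where(
                np.arange(len(space)) ==
                list(space.iter_indices()).index(g.indices), 0.0, -np.inf
            ), spec)
            per_model.append(predict(X_new, None, None, point, evidence=ev))
        per_model = np.array(per_model)
        assert np.all(ma >= per_model.min(axis=0) - 1e-9)
        assert np.all(ma <= per_model.max(axis=0) + 1e-9)

    def test_matches_direct_model_averaging_oracle(self, p3_setup):
        X, Y, space, ev, spec = p3_setup
        post = model_posterior(ev, spec)
        X_new = np.random.default_rng(2).standard_normal((5, 3))
        ours = predict(X_new, None, None, post, evidence=ev)
        oracle = model_average_prediction_oracle(
            X_new, X, Y, space, post.log_posterior
        )
        np.testing.assert_allclose(ours, oracle, atol=1e-10)

    def test_map_mode_uses_map_model_only(self, p3_setup):
        X, Y, space, ev, spec = p3_setup
        post = model_posterior(ev, spec)
        X_new = np.random.default_rng(3).standard_normal((5, 3))
        map_pred = predict(X_new, None, None, post, mode="map", evidence=ev)
        idx = map_model(post).indices
        ids = ev.model_term_ids(idx)
        manual = ev.response.center + ev.transform(X_new)[:, ids] @ ev.coefficients(idx)
        np.testing.assert_allclose(map_pred, manual)


class TestExactness:
    def test_restricted_equals_full_space_when_dmax_is_p(self):
        """With d_max = p the restricted computation is the full-space one."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 6))
        Y = X[:, 0] - X[:, 3] + 0.5 * rng.standard_normal(25)
        full = enumerate_models(6, 6)
        post_full = model_posterior(
            SpaceEvidence(X, Y, full), make_prior(FlatPrior(), 0.0, full)
        )
        # a d_max=6 space over p=6 IS the full space; check pips also equal a
        # hand-rolled sum over all 64 models
        lml = SpaceEvidence(X, Y, full).log_ml
        w = np.exp(lml - logsumexp(lml))
        pips = np.zeros(6)
        for wi, idx in zip(w, full.iter_indices()):
            for j in idx:
                pips[j] += wi
        np.testing.assert_allclose(
            inclusion_probabilities(post_full), pips, atol=1e-12
        )
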