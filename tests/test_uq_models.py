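"""ENN and SNGP estimators: pooling algebra, RFF kernel approximation,
Laplace precision accumulation, and equivalence with an exact GP posterior."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from kuq.nn.autodiff import Tensor
from kuq.nn.train import TrainConfig, train_model
from kuq import toy_data
from kuq.pipeline import split_indices
from kuq.uq_models import (
    BackboneSpec,
    MlpClassifier,
    SngpClassifier,
    build_toy_ensemble,
    build_toy_sngp_pool,
    enn_predict,
    laplace_precision_update,
    pool_sngp,
    rff_features,
    sngp_predict,
)


class IdentityBackbone:
    """Passes 2-D inputs straight to the GP head; lets tests control hidden
    geometry exactly."""

    width = 2
    params: list = []

    def hidden(self, x):
        return Tensor(np.asarray(x, dtype=float))

    def project(self):
        pass


def make_plain_sngp(rff_dim=4096, length_scale=1.0, seed=0):
    return SngpClassifier(IdentityBackbone(), rff_dim=rff_dim,
                          length_scale=length_scale, seed=seed)


class TestEnsemblePooling:
    def test_identical_members_zero_ku(self, blobs):
        X, _ = blobs
        m = MlpClassifier(2, BackboneSpec("mlp", 1, 100), seed=0)
        pred = enn_predict([m, m, m], X[:5])
        np.testing.assert_array_equal(pred.ku, 0.0)

    def test_two_member_symmetric_logits(self):
        class Fixed:
            def __init__(self, value):
                self.value = value

            def predict_logits(self, x):
                return np.full(len(x), self.value)

        pred = enn_predict([Fixed(1.0), Fixed(-1.0)], np.zeros((4, 2)))
        np.testing.assert_allclose(pred.mean_prob, 0.5)
        np.testing.assert_allclose(pred.ku, 1.0)  # population std of {+1,-1}

    def test_order_invariance(self, blobs):
        X, y = blobs
        members = [MlpClassifier(2, BackboneSpec("mlp", 1, 100), seed=s)
                   for s in range(3)]
        a = enn_predict(members, X[:7])
        b = enn_predict(members[::-1], X[:7])
        np.testing.assert_allclose(a.ku, b.ku)
        np.testing.assert_allclose(a.mean_prob, b.mean_prob)

    def test_distinct_seeds_disagree_off_manifold(self, blobs):
        X, y = blobs
        members = [MlpClassifier(2, BackboneSpec("mlp", 1, 100), seed=s)
                   for s in range(5)]
        for m in members:
            train_model(m, ((X,), y), ((X,), y),
                        TrainConfig(lr=1e-2, max_epochs=30, patience=30,
                                    seed=m.seed))
        far = np.array([[30.0, -40.0]])
        assert enn_predict(members, far).ku[0] > 0

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            enn_predict([], np.zeros((1, 2)))


class TestRffFeatures:
    def test_inner_products_approximate_rbf_kernel(self):
        model = make_plain_sngp(rff_dim=4096, length_scale=1.0)
        rng = np.random.default_rng(5)
        x = rng.uniform(-1.5, 1.5, size=(30, 2))
        phi = model.features(x)
        gram = phi @ phi.T
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        exact = np.exp(-d2 / 2.0)
        sel = d2 <= 9.0  # pairs closer than 3 length scales
        assert np.abs(gram - exact)[sel].max() < 0.05

    def test_self_kernel_near_one(self):
        model = make_plain_sngp(rff_dim=4096)
        phi = model.features(np.array([[0.3, -0.7]]))
        assert (phi @ phi.T).item() == pytest.approx(1.0, abs=0.05)

    def test_entries_bounded(self):
        w = np.random.default_rng(0).standard_normal((64, 2))
        b = np.random.default_rng(1).uniform(0, 2 * np.pi, 64)
        phi = rff_features(np.array([[5.0, -3.0]]), w, b)
        assert np.all(np.abs(phi) <= np.sqrt(2.0 / 64) + 1e-12)

    def test_dimension_mismatch_rejected(self):
        w = np.zeros((8, 3))
        with pytest.raises(ValueError):
            rff_features(np.zeros((2, 2)), w, np.zeros(8))


class TestLaplacePrecision:
    def test_empty_batch_identity(self):
        p = np.eye(4)
        np.testing.assert_array_equal(
            laplace_precision_update(p, np.empty((0, 4)), np.empty(0)), p)

    def test_single_observation_rank_one(self):
        phi = np.array([1.0, 2.0, 0.0])
        p = laplace_precision_update(np.eye(3), phi, np.array([0.5]))
        np.testing.assert_allclose(p, np.eye(3) + 0.25 * np.outer(phi, phi))

    def test_minibatch_accumulation_matches_one_shot(self):
        rng = np.random.default_rng(7)
        phi = rng.standard_normal((200, 16))
        prob = rng.uniform(0.05, 0.95, 200)
        brute = np.eye(16) + (phi * (prob * (1 - prob))[:, None]).T @ phi
        acc = np.eye(16)
        for start in range(0, 200, 32):
            acc = laplace_precision_update(acc, phi[start:start + 32],
                                           prob[start:start + 32])
        np.testing.assert_allclose(acc, brute, atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            laplace_precision_update(np.eye(2), np.array([[np.inf, 0.0]]),
                                     np.array([0.5]))


class TestSngpPosterior:
    def test_prior_sigma_is_one(self):
        model = make_plain_sngp()
        rng = np.random.default_rng(0)
        pred = model.predict(rng.uniform(-2, 2, size=(10, 2)))
        np.testing.assert_allclose(pred.sigma, 1.0, atol=0.05)

    def _exact_gp_sigma(self, model, x_train, w, x_query):
        """Posterior sd of a GP with the head's RBF kernel and per-point noise
        1/w, computed in closed form — the oracle SNGP approximates."""
        h_tr = model._normalized_hidden(x_train).data
        h_q = model._normalized_hidden(x_query).data
        ls = model.length_scale

        def k(a, b):
            d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
            return np.exp(-d2 / (2 * ls ** 2))

        K = k(h_tr, h_tr) + np.diag(1.0 / w)
        kq = k(h_q, h_tr)
        var = 1.0 - np.einsum("ij,ij->i", kq, np.linalg.solve(K, kq.T).T)
        return np.sqrt(np.maximum(var, 0.0))

    def test_matches_exact_gp_on_small_dataset(self):
        model = make_plain_sngp(rff_dim=4096, seed=1)
        rng = np.random.default_rng(11)
        x_train = rng.uniform(-2, 2, size=(200, 2))
        model.finalize((x_train,))  # untrained head: p = 0.5, w = 0.25
        x_query = rng.uniform(-2, 2, size=(25, 2))
        sigma = model.predict(x_query).sigma
        exact = self._exact_gp_sigma(model, x_train, np.full(200, 0.25), x_query)
        np.testing.assert_allclose(sigma, exact, rtol=0.10)

    def test_far_query_returns_to_prior(self):
        model = make_plain_sngp(rff_dim=4096, seed=2)
        x_train = np.random.default_rng(0).uniform(-1, 1, size=(100, 2))
        model.finalize((x_train,))
        far = np.array([[30.0, 30.0]])  # >= 5 length scales from everything
        assert model.predict(far).sigma[0] == pytest.approx(1.0, rel=0.10)

    def test_sigma_shrinks_with_repeated_observations(self):
        model = make_plain_sngp(rff_dim=4096, seed=3)
        x_train = np.repeat([[0.5, 0.5]], 100, axis=0)
        model.finalize((x_train,))
        at_data = model.predict(np.array([[0.5, 0.5]])).sigma[0]
        far = model.predict(np.array([[30.0, 30.0]])).sigma[0]
        assert at_data < far
        exact = self._exact_gp_sigma(model, x_train, np.full(100, 0.25),
                                     np.array([[0.5, 0.5]]))
        assert at_data == pytest.approx(exact[0], rel=0.10)

    def test_sngp_predict_wrapper(self):
        model = make_plain_sngp(rff_dim=512)
        model.finalize((np.zeros((5, 2)),))
        pred = sngp_predict(model, np.zeros((3, 2)))
        assert pred.sigma.shape == (3,)


class TestSngpPooling:
    def _fixed(self, mu, sigma):
        class Fixed:
            def predict(self, *inputs):
                from kuq.uq_models import SngpPrediction
                n = len(inputs[0])
                return SngpPrediction(np.full(n, mu), np.full(n, sigma),
                                      np.full(n, 0.5))

        return Fixed()

    def test_single_model_identity(self):
        pred = pool_sngp([self._fixed(0.3, 0.2)], np.zeros((4, 2)))
        np.testing.assert_allclose(pred.sigma, 0.2)

    def test_mean_of_sigmas(self):
        pool = [self._fixed(0.0, 0.2), self._fixed(0.0, 0.4)]
        pred = pool_sngp(pool, np.zeros((2, 2)))
        np.testing.assert_allclose(pred.sigma, 0.3)
        pred2 = pool_sngp(pool[::-1], np.zeros((2, 2)))
        np.testing.assert_allclose(pred.sigma, pred2.sigma)

    def test_sigma2_mode(self):
        pool = [self._fixed(0.0, 0.2), self._fixed(0.0, 0.4)]
        pred = pool_sngp(pool, np.zeros((1, 2)), var_mode="sigma2")
        np.testing.assert_allclose(pred.sigma, np.sqrt((0.04 + 0.16) / 2))

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_sngp([], np.zeros((1, 2)))


class TestToyZoo:
    def test_toy_ensemble_composition(self):
        members = build_toy_ensemble(0)
        assert len(members) == 27
        assert {m.spec.depth for m in members} == {1, 2, 3}
        assert all(100 <= m.spec.width <= 150 for m in members)
        a, b = members[0], members[1]
        assert not np.array_equal(a.backbone.layers[0].w.data,
                                  b.backbone.layers[0].w.data)

    def test_sngp_pool_size(self):
        assert len(build_toy_sngp_pool(0)) == 9

    def test_backbone_spec_ranges(self):
        with pytest.raises(ValueError):
            BackboneSpec("mlp", 4, 100)
        with pytest.raises(ValueError):
            BackboneSpec("transformer", 4, 512)
        with pytest.raises(ValueError):
            BackboneSpec("mlp", 1, 80)


def test_sngp_sigma_tracks_nn_distance_on_moons_far_field():
    """Distance awareness: a trained SNGP's sigma is monotone in the distance
    to the nearest training point over the two-moons far field."""
    data = toy_data.make_two_moons(1500, 0.1, seed=0)
    tr, va, _ = split_indices(1500, seed=1)
    Xtr, ytr = data.coords[tr], data.labels[tr]
    Xva, yva = data.coords[va], data.labels[va]
    model = build_toy_sngp_pool(0, rff_dim=256, length_scale=5.0)[0]
    train_model(model, ((Xtr,), ytr), ((Xva,), yva),
                TrainConfig(lr=1e-3, max_epochs=80, patience=15, seed=0))
    ood = toy_data.make_ood_points(toy_data.LabeledPoints(Xtr, ytr), 0.2,
                                   m=300, seed=2)
    rho = spearmanr(model.predict(ood.coords).sigma, ood.nn_dist).statistic
    assert rho > 0.9
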