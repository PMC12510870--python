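"""The four training-loss terms, their zero cases and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import conscape as cs
from conscape.losses import (
    BatchViews,
    DegenerateBatchError,
    LossWeights,
    distance_distribution_grads,
    distance_distribution_loss,
    latent_pair_mse,
    latent_pair_mse_grads,
    representation_loss,
    self_distance_matrix,
    shannon_stress,
    shannon_stress_grad,
    total_loss,
    wasserstein_1d,
)

finite_floats = st.floats(-50, 50, allow_nan=False, allow_infinity=False)


def rotation(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestSelfDistanceMatrix:
    def test_hand_computed_1d(self):
        D = self_distance_matrix(np.array([[0.0], [3.0], [4.0]]))
        expected = np.array([[0, 3, 4], [3, 0, 1], [4, 1, 0]], dtype=float)
        assert np.allclose(D, expected)

    def test_duplicate_point_gives_zero_off_diagonal(self):
        D = self_distance_matrix(np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]]))
        assert D[0, 1] == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            self_distance_matrix(np.ones((1, 3)))

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(hnp.arrays(float, st.tuples(st.integers(2, 8), st.integers(1, 4)),
                      elements=finite_floats))
    def test_symmetric_zero_diagonal(self, P):
        D = self_distance_matrix(P)
        assert np.array_equal(D, D.T)
        assert np.all(np.diag(D) == 0.0)


class TestLatentPairMse:
    def test_zero_on_coincident_encodings(self):
        Z = np.random.default_rng(0).normal(size=(6, 3))
        views = BatchViews([Z.copy(), Z.copy()], [Z.copy(), Z.copy()])
        assert latent_pair_mse(views) == 0.0

    def test_single_particle_double_sum(self):
        # ordered pairs (1,2) and (2,1) each contribute ||(0,0)-(3,4)||^2 = 25
        views = BatchViews(
            [np.zeros((1, 2)), np.zeros((1, 2))],
            [np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])],
        )
        assert latent_pair_mse(views) == pytest.approx(50.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(1)
        Z = [rng.normal(size=(5, 2)) for _ in range(2)]
        X = [np.zeros((5, 2))] * 2
        base = latent_pair_mse(BatchViews(X, Z))
        scaled = latent_pair_mse(BatchViews(X, [3.0 * z for z in Z]))
        assert scaled == pytest.approx(9.0 * base)


class TestShannonStress:
    def test_zero_for_identity_embedding(self):
        X = np.random.default_rng(0).normal(size=(8, 2))
        assert shannon_stress(X, X.copy()) == pytest.approx(0.0, abs=1e-15)

    def test_zero_under_rigid_rotation(self):
        X = np.random.default_rng(1).normal(size=(8, 2))
        Z = X @ rotation(0.7).T + np.array([2.0, -1.0])
        assert shannon_stress(X, Z) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # X = {0, 1}, Z = {0, 2}: stress = (1-2)^2/1 / 1 = 1
        assert shannon_stress(np.array([[0.0], [1.0]]),
                              np.array([[0.0], [2.0]])) == pytest.approx(1.0)

    def test_degenerate_batch_raises(self):
        with pytest.raises(DegenerateBatchError):
            shannon_stress(np.ones((3, 2)), np.random.default_rng(0).normal(size=(3, 2)))

    def test_duplicate_input_pairs_excluded(self):
        X = np.array([[0.0], [0.0], [1.0]])
        Z = np.array([[0.0], [5.0], [1.0]])
        assert np.isfinite(shannon_stress(X, Z))


class TestWasserstein1d:
    def test_shifted_triple(self):
        assert wasserstein_1d([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0)

    def test_identical_samples(self):
        a = np.random.default_rng(0).normal(size=20)
        assert wasserstein_1d(a, a) == pytest.approx(0.0)

    def test_single_atoms(self):
        assert wasserstein_1d([0.0], [5.0]) == pytest.approx(5.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(st.lists(finite_floats, min_size=1, max_size=10),
           st.lists(finite_floats, min_size=1, max_size=10))
    def test_symmetry_and_nonnegativity(self, a, b):
        w = wasserstein_1d(a, b)
        assert w >= 0.0
        assert w == pytest.approx(wasserstein_1d(b, a))

    def test_equal_sizes_sorted_difference(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=11), rng.normal(size=11)
        oracle = np.mean(np.abs(np.sort(a) - np.sort(b)))
        assert wasserstein_1d(a, b) == pytest.approx(oracle, abs=1e-12)


class TestDistanceDistributionLoss:
    def make_views(self, Z):
        X = [np.zeros_like(z) + 1e-3 * np.arange(z.shape[0])[:, None] for z in Z]
        return BatchViews(X, Z)

    def test_zero_for_identical_batches(self):
        Z = np.random.default_rng(0).normal(size=(6, 2))
        assert distance_distribution_loss(self.make_views([Z, Z.copy()])) == pytest.approx(0.0)

    def test_translation_invariance(self):
        Z = np.random.default_rng(1).normal(size=(6, 2))
        shifted = Z + np.array([10.0, -3.0])
        assert distance_distribution_loss(self.make_views([Z, shifted])) == pytest.approx(0.0, abs=1e-12)

    def test_doubling_matches_sorted_difference_oracle(self):
        Z = np.random.default_rng(2).normal(size=(7, 2))
        d = self_distance_matrix(Z)
        sample = d[~np.eye(7, dtype=bool)]
        oracle = np.mean(np.abs(np.sort(sample) - np.sort(2.0 * sample)))
        got = distance_distribution_loss(self.make_views([Z, 2.0 * Z]))
        assert got == pytest.approx(2.0 * oracle)  # ordered pairs (1,2) and (2,1)


def linear_net(w_enc, w_dec, dims, latent):
    """A depth-1, width-1 network with hand-set weights in the ReLU-linear regime."""
    spec = cs.NetworkSpec(dims, latent, hidden_width=1, hidden_depth=1, seed=0)
    net = cs.build_network(spec)
    for nets, w in ((net.encoders, w_enc), (net.decoders, w_dec)):
        for layers in nets:
            for W, b in layers:
                W[...] = w
                b[...] = 0.0
    return net


class TestRepresentationLoss:
    def test_hand_computed_tiny_linear_net(self):
        # encoders: x -> relu(x) -> z = relu(x); decoders: z -> relu(z) -> y
        # with all weights 1 and positive inputs every map is the identity.
        net = linear_net(1.0, 1.0, (1, 1), 1)
        X = [np.array([[2.0]]), np.array([[3.0]])]
        views = BatchViews(X).with_latents(net)
        # reconstructions: D_n(E_m(x^m)) = x^m, so loss = sum_n sum_m (x^n - x^m)^2
        expected = (2 - 2) ** 2 + (2 - 3) ** 2 + (3 - 2) ** 2 + (3 - 3) ** 2
        assert representation_loss(views, net) == pytest.approx(expected)

    def test_single_space_reduces_to_autoencoder_residual(self, small_net):
        X = np.abs(np.random.default_rng(0).normal(size=(6, 2))) + 0.1
        views = BatchViews([X]).with_latents(small_net)
        recon = small_net.decode(0, small_net.encode(0, X))
        assert representation_loss(views, small_net) == pytest.approx(np.sum((X - recon) ** 2))


class TestTotalLoss:
    def test_additivity(self, small_net, tiny_lset):
        views = BatchViews(tiny_lset.matrices()).with_latents(small_net)
        parts = total_loss(views, small_net)
        assert parts["total"] == pytest.approx(
            parts["rep"] + parts["l1"] + parts["l2"] + parts["l3"])

    def test_weights_select_terms(self, small_net, tiny_lset):
        views = BatchViews(tiny_lset.matrices()).with_latents(small_net)
        w = LossWeights(w_rep=1, w1=0, w2=0, w3=0)
        assert total_loss(views, small_net, w)["total"] == pytest.approx(
            representation_loss(views, small_net))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(w1=-0.5)


class TestRowPermutationInvariance:
    """All terms are invariant under one simultaneous row permutation."""

    def test_all_terms(self, small_net, tiny_lset):
        X = tiny_lset.matrices()
        views = BatchViews(X).with_latents(small_net)
        before = total_loss(views, small_net)
        perm = np.random.default_rng(0).permutation(tiny_lset.num_particles)
        views_p = BatchViews([x[perm] for x in X]).with_latents(small_net)
        after = total_loss(views_p, small_net)
        for key in ("rep", "l1", "l2", "l3"):
            assert after[key] == pytest.approx(before[key], rel=1e-9)


class TestGradients:
    """Analytic regulariser gradients agree with central finite differences."""

    @pytest.mark.parametrize("term", ["l1", "l2", "l3"])
    def test_against_finite_differences(self, term):
        rng = np.random.default_rng(0)
        B, d = 6, 2
        Z = [rng.normal(size=(B, d)) for _ in range(2)]
        X = [rng.normal(size=(B, 2)) for _ in range(2)]
        if term == "l1":
            value = lambda Zs: latent_pair_mse(BatchViews(X, Zs))
            grads = latent_pair_mse_grads(Z)
        elif term == "l2":
            value = lambda Zs: sum(shannon_stress(x, z) for x, z in zip(X, Zs))
            grads = [shannon_stress_grad(x, z) for x, z in zip(X, Z)]
        else:
            value = lambda Zs: distance_distribution_loss(BatchViews(X, Zs))
            grads = distance_distribution_grads(Z)
        eps = 1e-6
        for n in range(2):
            fd = np.zeros_like(Z[n])
            for i in range(B):
                for j in range(d):
                    Zp = [z.copy() for z in Z]
                    Zm = [z.copy() for z in Z]
                    Zp[n][i, j] += eps
                    Zm[n][i, j] -= eps
                    fd[i, j] = (value(Zp) - value(Zm)) / (2 * eps)
            assert np.allclose(grads[n], fd, atol=1e-6)
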