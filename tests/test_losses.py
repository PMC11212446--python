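import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import noisytab.autodiff as ad
from noisytab.autodiff import Tensor
from noisytab.losses import (
    MixupSpec,
    NCRSpec,
    SmoothingSpec,
    cosine_similarity_matrix,
    cross_entropy,
    mixup_batch,
    ncr_loss,
    smooth_labels,
    total_loss,
)

from .oracles import brute_force_ncr


class TestSmoothLabels:
    def test_zero_epsilon_keeps_one_hot(self):
        t = smooth_labels([0, 1, 1], SmoothingSpec(epsilon=0.0))
        np.testing.assert_allclose(t, [[1, 0], [0, 1], [0, 1]])

    def test_binary_smoothing_values(self):
        t = smooth_labels([1], SmoothingSpec(epsilon=0.2, n_classes=2))
        np.testing.assert_allclose(t, [[0.2, 0.8]])

    def test_multiclass_smoothing_values(self):
        t = smooth_labels([0], SmoothingSpec(epsilon=0.2, n_classes=5))
        np.testing.assert_allclose(t, [[0.8, 0.05, 0.05, 0.05, 0.05]])
        assert t.sum() == pytest.approx(1.0)

    def test_epsilon_range_enforced(self):
        with pytest.raises(ValueError, match="epsilon"):
            SmoothingSpec(epsilon=1.0)

    @given(
        eps=st.floats(0.0, 0.999),
        n_classes=st.integers(2, 10),
        label=st.integers(0, 9),
    )
    def test_targets_are_distributions(self, eps, n_classes, label):
        label = label % n_classes
        t = smooth_labels([label], SmoothingSpec(epsilon=eps, n_classes=n_classes))
        assert (t >= 0).all()
        assert t.sum() == pytest.approx(1.0)


class _FakeRng:
    """Deterministic stand-in for the mix-up random stream."""

    def __init__(self, lam, apply=True, perm=None):
        self.lam, self.apply, self.perm = lam, apply, perm

    def random(self):
        return 0.0 if self.apply else 1.0

    def beta(self, a, b):
        return self.lam

    def permutation(self, n):
        return self.perm if self.perm is not None else np.arange(n)[::-1]


class TestMixup:
    def test_lambda_one_returns_originals(self):
        X = np.array([[0.0, 2.0], [2.0, 0.0]])
        Y = np.array([1.0, 0.0])
        Xm, Ym, lam = mixup_batch(X, Y, MixupSpec(p_apply=1.0), rng=_FakeRng(1.0))
        assert lam == 1.0
        np.testing.assert_allclose(Xm, X)
        np.testing.assert_allclose(Ym, Y)

    def test_half_mixing_hand_case(self):
        X = np.array([[0.0, 2.0], [2.0, 0.0]])
        Y = np.array([1.0, 0.0])
        Xm, Ym, lam = mixup_batch(
            X, Y, MixupSpec(p_apply=1.0), rng=_FakeRng(0.5, perm=np.array([1, 0]))
        )
        np.testing.assert_allclose(Xm, [[1.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(Ym, [0.5, 0.5])

    def test_not_applied_with_probability(self):
        X = np.arange(6, dtype=float).reshape(3, 2)
        Y = np.array([0.0, 1.0, 0.0])
        Xm, Ym, lam = mixup_batch(X, Y, MixupSpec(p_apply=0.5), rng=_FakeRng(0.3, apply=False))
        assert lam == 1.0
        np.testing.assert_array_equal(Xm, X)

    def test_outputs_are_convex_combinations(self, rng):
        X = rng.standard_normal((32, 5))
        Y = rng.random(32)
        Xm, Ym, lam = mixup_batch(X, Y, MixupSpec(p_apply=1.0, seed=1))
        assert 0.0 <= lam <= 1.0
        assert (Xm >= X.min(axis=0) - 1e-12).all() and (Xm <= X.max(axis=0) + 1e-12).all()
        assert (Ym >= Y.min() - 1e-12).all() and (Ym <= Y.max() + 1e-12).all()

    def test_single_row_batch_warns_and_passes_through(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            Xm, Ym, lam = mixup_batch(np.ones((1, 2)), np.ones(1), MixupSpec())
        assert lam == 1.0


class TestCosineSimilarity:
    def test_identical_vectors(self):
        S = cosine_similarity_matrix(np.array([[1.0, 2.0], [1.0, 2.0]]))
        np.testing.assert_allclose(S.data[0, 1], 1.0)

    def test_orthogonal_vectors(self):
        S = cosine_similarity_matrix(np.array([[1.0, 0.0], [0.0, 3.0]]))
        np.testing.assert_allclose(S.data[0, 1], 0.0, atol=1e-12)

    def test_known_angle(self):
        S = cosine_similarity_matrix(np.array([[1.0, 0.0], [1.0, 1.0]]))
        np.testing.assert_allclose(S.data[0, 1], 0.7071068, atol=1e-6)

    def test_zero_row_similarity_is_zero(self):
        S = cosine_similarity_matrix(np.array([[0.0, 0.0], [1.0, 1.0]]))
        np.testing.assert_allclose(S.data[0, 1], 0.0)

    def test_symmetric(self, rng):
        S = cosine_similarity_matrix(np.abs(rng.standard_normal((6, 4)))).data
        np.testing.assert_allclose(S, S.T)


@pytest.mark.parametrize("divergence", ["kl", "js", "mae"])
class TestNcrLoss:
    def test_hand_batch_matches_brute_force(self, divergence):
        V = np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0]])
        Z = np.array([2.0, -1.0, 0.5])
        spec = NCRSpec(k=1, divergence=divergence, warmup_epochs=0)
        expected = brute_force_ncr(V, Z, 1, divergence)
        assert ncr_loss(V, Z, spec).item() == pytest.approx(expected, abs=1e-6)

    def test_identical_logits_give_zero(self, divergence, rng):
        V = np.abs(rng.standard_normal((8, 4)))
        Z = np.full(8, 0.7)
        loss = ncr_loss(V, Z, NCRSpec(k=3, divergence=divergence)).item()
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_nonnegative_on_random_batches(self, divergence, rng):
        for _ in range(10):
            V = np.abs(rng.standard_normal((10, 3)))
            Z = rng.standard_normal(10)
            assert ncr_loss(V, Z, NCRSpec(k=4, divergence=divergence)).item() >= 0

    def test_scale_invariance_of_representations(self, divergence, rng):
        V = np.abs(rng.standard_normal((9, 5)))
        Z = rng.standard_normal(9)
        spec = NCRSpec(k=3, divergence=divergence)
        a = ncr_loss(V, Z, spec).item()
        b = ncr_loss(V * 37.5, Z, spec).item()
        assert a == pytest.approx(b, rel=1e-9)

    def test_permutation_leaves_mean_unchanged(self, divergence, rng):
        V = np.abs(rng.standard_normal((7, 4)))
        Z = rng.standard_normal(7)
        spec = NCRSpec(k=2, divergence=divergence)
        perm = rng.permutation(7)
        a = ncr_loss(V, Z, spec).item()
        b = ncr_loss(V[perm], Z[perm], spec).item()
        assert a == pytest.approx(b, rel=1e-9)

    def test_k_must_be_smaller_than_batch(self, divergence):
        with pytest.raises(ValueError, match="batch"):
            ncr_loss(np.ones((3, 2)), np.zeros(3), NCRSpec(k=3, divergence=divergence))

    def test_all_zero_similarity_row_contributes_zero(self, divergence):
        # first row is all-zero: it finds no neighbours, so only rows 2 and 3 count
        V = np.array([[0.0, 0.0], [1.0, 0.2], [1.0, 0.1]])
        Z = np.array([5.0, 1.0, -1.0])
        spec = NCRSpec(k=1, divergence=divergence)
        expected = brute_force_ncr(V, Z, 1, divergence)
        assert ncr_loss(V, Z, spec).item() == pytest.approx(expected, abs=1e-9)

    def test_gradients_match_finite_differences(self, divergence, rng):
        spec = NCRSpec(k=3, divergence=divergence)
        V0 = np.abs(rng.standard_normal((6, 4)))
        Z0 = rng.standard_normal(6)
        V = Tensor(V0, requires_grad=True)
        Z = Tensor(Z0, requires_grad=True)
        ncr_loss(V, Z, spec).backward()
        h = 1e-6

        def f(V_, Z_):
            return ncr_loss(V_, Z_, spec).item()

        for arr, grad, which in ((V0, V.grad, "V"), (Z0, Z.grad, "Z")):
            num = np.zeros_like(arr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                up, down = arr.copy(), arr.copy()
                up[idx] += h
                down[idx] -= h
                if which == "V":
                    num[idx] = (f(up, Z0) - f(down, Z0)) / (2 * h)
                else:
                    num[idx] = (f(V0, up) - f(V0, down)) / (2 * h)
            scale = max(np.abs(num).max(), 1e-8)
            assert np.abs(grad - num).max() / scale < 1e-4


class TestTotalLoss:
    def _batch(self, rng, m=8):
        V = np.abs(rng.standard_normal((m, 3)))
        Z = rng.standard_normal(m)
        p = 1.0 / (1.0 + np.exp(-Z))
        t = rng.integers(0, 2, m).astype(float)
        return p, t, V, Z

    def test_zero_weight_reduces_to_cross_entropy(self, rng):
        p, t, V, Z = self._batch(rng)
        spec = NCRSpec(weight=0.0, warmup_epochs=0, k=2)
        assert total_loss(p, t, V, Z, epoch=50, ncr=spec).item() == pytest.approx(
            cross_entropy(p, t).item()
        )

    def test_warmup_suppresses_ncr_term(self, rng):
        p, t, V, Z = self._batch(rng)
        spec = NCRSpec(weight=5.0, warmup_epochs=30, k=2)
        assert total_loss(p, t, V, Z, epoch=29, ncr=spec).item() == pytest.approx(
            cross_entropy(p, t).item()
        )

    def test_active_epoch_adds_weighted_oracle_value(self, rng):
        p, t, V, Z = self._batch(rng)
        spec = NCRSpec(weight=2.5, warmup_epochs=10, k=2)
        expected = cross_entropy(p, t).item() + 2.5 * brute_force_ncr(V, Z, 2, "kl")
        assert total_loss(p, t, V, Z, epoch=10, ncr=spec).item() == pytest.approx(
            expected, abs=1e-6
        )

    def test_soft_targets_supported(self):
        p = np.array([0.3, 0.9])
        hard = cross_entropy(p, np.array([0.0, 1.0])).item()
        soft = cross_entropy(p, np.array([[0.9, 0.1], [0.1, 0.9]])).item()
        direct = -np.mean(
            [0.1 * np.log(0.3) + 0.9 * np.log(0.7), 0.9 * np.log(0.9) + 0.1 * np.log(0.1)]
        )
        assert soft == pytest.approx(direct, rel=1e-9)
        assert soft != pytest.approx(hard)
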