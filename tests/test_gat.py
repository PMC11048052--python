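import numpy as np
import pytest

from gtadc.gat import (
    GATConfig,
    GATLayer,
    GATModel,
    add_self_loops,
    attention_scores,
    layer_forward,
    loss,
    modulate_and_normalize,
    predict_proportions,
    train,
)
from gtadc.io import ProportionMatrix


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    return A


class TestAttentionScores:
    def test_zero_attention_vector(self):
        assert attention_scores([1.0, 2.0], [3.0, 4.0], np.eye(2), np.zeros(4)) == 0.0

    def test_zero_weight_matrix(self):
        assert attention_scores([1.0, 2.0], [3.0, 4.0], np.zeros((2, 2)), np.ones(4)) == 0.0

    def test_hand_sized_example(self):
        # W=[1,0] maps h to its first coordinate; a=[1,1] sums the pair -> 1+2=3
        W = np.array([[1.0, 0.0]])
        a = np.array([1.0, 1.0])
        assert attention_scores([1.0, 0.0], [2.0, 0.0], W, a) == pytest.approx(3.0)

    def test_negative_preactivation_gets_leaky_slope(self):
        W = np.array([[1.0, 0.0]])
        a = np.array([1.0, 1.0])
        assert attention_scores([-1.0, 0.0], [-2.0, 0.0], W, a) == pytest.approx(-0.6)


class TestModulateAndNormalize:
    def test_isolated_node_attends_to_itself(self):
        A = np.zeros((3, 3))
        E = np.random.default_rng(0).normal(size=(3, 3))
        alpha = modulate_and_normalize(E, A)
        np.testing.assert_allclose(alpha, np.eye(3))

    def test_equal_scores_give_uniform_attention(self):
        n, q = 5, 4  # node 0 connected to q neighbors, all scores equal
        A = np.zeros((n, n))
        A[0, 1:] = A[1:, 0] = 1.0
        E = np.ones((n, n))
        alpha = modulate_and_normalize(E, A)
        np.testing.assert_allclose(alpha[0], np.full(n, 1 / (q + 1)))

    def test_rows_sum_to_one_and_support_respected(self):
        A = random_graph(20, 0.2, 1) * np.random.default_rng(2).random((20, 20))
        A = np.triu(A, 1); A = A + A.T
        E = np.random.default_rng(3).normal(size=(20, 20))
        alpha = modulate_and_normalize(E, A)
        np.testing.assert_allclose(alpha.sum(axis=1), np.ones(20), atol=1e-6)
        off_support = (add_self_loops(A) == 0)
        assert np.all(alpha[off_support] == 0)

    def test_post_softmax_variant_also_normalizes(self):
        A = random_graph(10, 0.3, 4)
        E = np.random.default_rng(5).normal(size=(10, 10))
        alpha = modulate_and_normalize(E, A, modulate="post_softmax")
        np.testing.assert_allclose(alpha.sum(axis=1), np.ones(10), atol=1e-6)


class TestLayerForward:
    def test_identity_propagation(self):
        # no edges -> self-attention only; W=I reproduces the input
        h = np.random.default_rng(0).normal(size=(6, 3))
        layer = GATLayer(W=np.eye(3)[None], a_src=np.zeros((1, 3)),
                         a_dst=np.zeros((1, 3)), merge="concat")
        out = layer_forward(h, np.zeros((6, 6)), layer)
        np.testing.assert_allclose(out, h, atol=1e-12)

    def test_identical_connected_nodes_stay_identical(self):
        rng = np.random.default_rng(1)
        h = np.tile(rng.normal(size=(1, 4)), (2, 1))
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        layer = GATLayer.init(4, 3, heads=2, merge="concat", rng=rng)
        out = layer_forward(h, A, layer)
        np.testing.assert_allclose(out[0], out[1], atol=1e-10)

    def test_concat_output_width(self):
        rng = np.random.default_rng(2)
        layer = GATLayer.init(5, 7, heads=3, merge="concat", rng=rng)
        out = layer_forward(rng.normal(size=(4, 5)), np.zeros((4, 4)), layer)
        assert out.shape == (4, 21)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        n = 30
        h = rng.normal(size=(n, 6))
        A = random_graph(n, 0.2, 7) * rng.random((n, n))
        A = np.triu(A, 1); A = A + A.T
        layer = GATLayer.init(6, 4, heads=2, merge="concat", rng=rng)
        out = layer_forward(h, A, layer)
        perm = rng.permutation(n)
        out_p = layer_forward(h[perm], A[np.ix_(perm, perm)], layer)
        np.testing.assert_allclose(out_p, out[perm], atol=1e-9)


class TestLossAndPredict:
    def test_uniform_logits_give_uniform_proportions(self):
        P = predict_proportions(np.zeros((3, 4)), ["a", "b", "c"], list("wxyz"))
        np.testing.assert_allclose(P.values, 1 / 4)

    def test_softmax_saturation(self):
        logits = np.zeros((1, 3)); logits[0, 1] = 50.0
        P = predict_proportions(logits, ["s"], list("abc"))
        assert P.values[0, 1] > 0.999999

    def test_loss_zero_on_exact_one_hot_match(self):
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert loss(y, y) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_prediction_loss_is_log_k(self):
        k = 5
        pred = np.full((7, k), 1 / k)
        truth = np.random.default_rng(0).dirichlet(np.ones(k), size=7)
        assert loss(pred, truth) == pytest.approx(np.log(k), rel=1e-6)

    def test_loss_nonnegative(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(4), size=10)
        y = rng.dirichlet(np.ones(4), size=10)
        assert loss(p, y) >= 0


class TestGradients:
    def test_manual_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        n, f_in, k = 7, 4, 3
        H = rng.normal(size=(n, f_in))
        A = random_graph(n, 0.4, 2) * rng.random((n, n))
        A = np.triu(A, 1); A = A + A.T
        Y = rng.dirichlet(np.ones(k), size=n)
        cfg = GATConfig(hidden_dim=5, heads=2, dropout=0.0, seed=1)
        model = GATModel.init(f_in, k, cfg)
        A_self = add_self_loops(A)
        mask = A_self > 0

        def forward_loss():
            logits, _ = model.forward(H, A_self, mask, dropout_rng=None)
            ex = np.exp(logits - logits.max(axis=1, keepdims=True))
            P = ex / ex.sum(axis=1, keepdims=True)
            return loss(P, Y)

        logits, caches = model.forward(H, A_self, mask, dropout_rng=None)
        ex = np.exp(logits - logits.max(axis=1, keepdims=True))
        P = ex / ex.sum(axis=1, keepdims=True)
        dP = -(Y / (P + 1e-12)) / n
        inner = (P * dP).sum(axis=1, keepdims=True)
        d_logits = P * (dP - inner)
        d_h1d, g2 = model.layer2.backward(d_logits, caches["c2"])
        from gtadc.gat import _elu_grad
        d_z1 = d_h1d * _elu_grad(caches["z1"], caches["h1"])
        _, g1 = model.layer1.backward(d_z1, caches["c1"])

        eps = 1e-6
        for param, grad in [
            (model.layer1.W, g1.W), (model.layer1.a_src, g1.a_src),
            (model.layer2.W, g2.W), (model.layer2.a_dst, g2.a_dst),
        ]:
            flat = param.ravel()
            gflat = grad.ravel()
            for idx in rng.choice(flat.size, size=6, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = forward_loss()
                flat[idx] = orig - eps
                lm = forward_loss()
                flat[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert gflat[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestTraining:
    def _toy_problem(self, seed=0, n_per=20):
        """Two separable feature blobs, pseudo spots labeled, real spots copies."""
        rng = np.random.default_rng(seed)
        f0 = rng.normal(0, 0.3, size=(n_per, 4)) + np.array([2, 0, 0, 0])
        f1 = rng.normal(0, 0.3, size=(n_per, 4)) + np.array([0, 2, 0, 0])
        pseudo = np.vstack([f0, f1])
        real = pseudo + rng.normal(0, 0.05, size=pseudo.shape)
        H = np.vstack([pseudo, real])
        # graph: connect by proximity
        from gtadc.graph import forest_adjacency
        A = forest_adjacency(H, T=5, leaf_size=12, seed=seed)
        truth_vals = np.zeros((2 * n_per, 2))
        truth_vals[:n_per, 0] = 1.0
        truth_vals[n_per:, 1] = 1.0
        truth = ProportionMatrix(truth_vals, [f"p{i}" for i in range(2 * n_per)], ["A", "B"])
        ids = [f"p{i}" for i in range(2 * n_per)] + [f"r{i}" for i in range(2 * n_per)]
        return H, A, truth, ids, truth_vals

    def test_loss_decreases_and_real_copies_recover_truth(self):
        H, A, truth, ids, truth_vals = self._toy_problem()
        cfg = GATConfig(hidden_dim=8, heads=2, epochs=60, seed=0)
        res = train(H, A, truth, ids, ["A", "B"], cfg)
        assert res.history[20] < res.history[0]
        from gtadc.evaluation import jsd
        jsds = [jsd(res.real_proportions.values[i], truth_vals[i])
                for i in range(truth_vals.shape[0])]
        assert np.mean(jsds) < 0.1

    def test_deterministic_given_seed(self):
        H, A, truth, ids, _ = self._toy_problem(seed=1)
        cfg = GATConfig(hidden_dim=8, heads=2, epochs=30, seed=5)
        r1 = train(H, A, truth, ids, ["A", "B"], cfg)
        r2 = train(H, A, truth, ids, ["A", "B"], cfg)
        np.testing.assert_allclose(
            r1.proportions.values, r2.proportions.values, atol=1e-5
        )

    def test_nonfinite_features_abort_with_diagnostic(self):
        H, A, truth, ids, _ = self._toy_problem(seed=2)
        H = H.copy()
        H[0, 0] = np.inf
        cfg = GATConfig(hidden_dim=4, heads=1, epochs=5, seed=0)
        with pytest.raises(RuntimeError, match="loss at epoch"):
            train(H, A, truth, ids, ["A", "B"], cfg)

    def test_prediction_rows_on_simplex(self):
        H, A, truth, ids, _ = self._toy_problem(seed=3)
        cfg = GATConfig(hidden_dim=6, heads=2, epochs=20, seed=0)
        res = train(H, A, truth, ids, ["A", "B"], cfg)
        sums = res.proportions.values.sum(axis=1)
        np.testing.assert_allclose(sums, np.ones_like(sums), atol=1e-6)
        assert res.proportions.values.min() >= 0
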