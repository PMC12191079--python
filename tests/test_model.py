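"""Model-layer tests against independent brute-force oracles.

The oracle functions below re-implement every stage with plain loops and
scalar math; they share no code with the package's vectorized path.
"""

import math

import numpy as np
import pytest

from emognn.autodiff import Tensor
from emognn.model import (
    EmotionGraphNet,
    ModelConfig,
    attention_adjacency,
    classify,
    flops_attention_layer,
    global_attention_pool,
    graph_conv,
    load_checkpoint,
    normalized_ring_adjacency,
    plain_gcn_layer,
    project,
    save_checkpoint,
    sum_pool,
)


# --------------------------------------------------------------------------
# brute-force oracles (loops + math.exp only)
# --------------------------------------------------------------------------

def oracle_matmul(a, b):
    n, m, k = len(a), len(b[0]), len(b)
    return [[sum(a[i][l] * b[l][j] for l in range(k)) for j in range(m)] for i in range(n)]


def oracle_softmax_rows(m):
    out = []
    for row in m:
        mx = max(row)
        e = [math.exp(v - mx) for v in row]
        s = sum(e)
        out.append([v / s for v in e])
    return out


def oracle_attention_layer(x, w, a):
    """One full attention-convolution layer on a single (E x F) item."""
    h = oracle_matmul(x, w)
    ht = [list(col) for col in zip(*h)]
    scores = oracle_matmul(oracle_matmul(h, a), ht)
    att = oracle_softmax_rows(scores)
    e = len(att)
    sym = [[(att[i][j] + att[j][i]) / 2 for j in range(e)] for i in range(e)]
    z = oracle_matmul(sym, h)
    return h, sym, z


def oracle_global_pool(z, w, b):
    omega = [sum(zi * wi for zi, wi in zip(row, w)) + b for row in z]
    beta = oracle_softmax_rows([omega])[0]
    zp = [[bi * v for v in row] for bi, row in zip(beta, z)]
    return beta, zp


def oracle_head(flat, weights, biases):
    h = list(flat)
    for (w, b) in list(zip(weights, biases))[:-1]:
        h = [max(0.0, v) for v in
             [sum(h[i] * w[i][j] for i in range(len(h))) + b[j] for j in range(len(b))]]
    w, b = weights[-1], biases[-1]
    logits = [sum(h[i] * w[i][j] for i in range(len(h))) + b[j] for j in range(len(b))]
    return oracle_softmax_rows([logits])[0], logits


# --------------------------------------------------------------------------
# functional op contracts
# --------------------------------------------------------------------------

class TestProject:
    def test_identity_projection(self, rng):
        x = rng.standard_normal((2, 3, 4))
        assert np.allclose(project(x, np.eye(4)), x)

    def test_hand_multiplied_example(self):
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        w = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert np.allclose(project(x, w), [[[3.0, 2.0], [7.0, 4.0]]])

    def test_batched_shape(self, rng):
        out = project(rng.standard_normal((64, 62, 5)), rng.standard_normal((5, 32)))
        assert out.shape == (64, 62, 32)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            project(rng.standard_normal((1, 3, 4)), rng.standard_normal((5, 2)))


class TestAttentionAdjacency:
    def test_identity_fixture_matches_hand_computation(self):
        out = attention_adjacency(np.eye(2)[None], np.eye(2))
        e = math.e
        expect = np.array([[e / (e + 1), 1 / (e + 1)], [1 / (e + 1), e / (e + 1)]])
        assert np.allclose(out[0], expect, atol=1e-10)
        assert np.allclose(out[0], [[0.7311, 0.2689], [0.2689, 0.7311]], atol=1e-4)

    def test_rows_sum_to_one_before_symmetrization(self, rng):
        h = rng.standard_normal((3, 5, 4))
        a = rng.standard_normal((4, 4))
        scores = np.matmul(np.matmul(h, a), np.swapaxes(h, -1, -2))
        pre = Tensor(scores).softmax(axis=-1).data
        assert np.allclose(pre.sum(axis=-1), 1.0, atol=1e-6)

    def test_symmetric_exactly(self, rng):
        out = attention_adjacency(rng.standard_normal((4, 6, 3)), rng.standard_normal((3, 3)))
        assert np.max(np.abs(out - np.swapaxes(out, -1, -2))) < 1e-7

    def test_entries_in_unit_interval_and_total_sum_E(self, rng):
        e = 7
        out = attention_adjacency(rng.standard_normal((5, e, 4)), rng.standard_normal((4, 4)))
        assert np.all(out >= 0) and np.all(out <= 1)
        assert np.allclose(out.sum(axis=(1, 2)), e, atol=1e-5)

    def test_large_scores_stay_finite(self):
        h = np.full((1, 3, 2), 1e3)
        out = attention_adjacency(h, np.eye(2))
        assert np.all(np.isfinite(out))

    def test_nonsquare_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_adjacency(rng.standard_normal((1, 3, 4)), rng.standard_normal((4, 3)))


class TestGraphConv:
    def test_identity_adjacency(self, rng):
        h = rng.standard_normal((2, 4, 3))
        assert np.allclose(graph_conv(np.broadcast_to(np.eye(4), (2, 4, 4)), h), h)

    def test_uniform_adjacency_averages(self, rng):
        h = rng.standard_normal((1, 5, 3))
        g = np.full((1, 5, 5), 1.0 / 5)
        out = graph_conv(g, h)
        assert np.allclose(out, np.broadcast_to(h.mean(axis=1, keepdims=True), h.shape))

    def test_two_node_worked_example(self):
        # continuation of the H=I, A=I fixture: Z = A_att @ I = A_att
        g = attention_adjacency(np.eye(2)[None], np.eye(2))
        z = graph_conv(g, np.eye(2)[None])
        assert np.allclose(z, g)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            graph_conv(rng.standard_normal((1, 3, 3)), rng.standard_normal((1, 4, 2)))


class TestGlobalAttentionPool:
    def test_equal_scores_give_uniform_weights(self):
        z = np.ones((2, 6, 3))
        _, beta = global_attention_pool(z, np.zeros(3), np.zeros(1))
        assert np.allclose(beta, 1.0 / 6)

    def test_log3_score_gives_three_quarters(self):
        # omega = [ln 3, 0] -> beta = [0.75, 0.25]
        z = np.array([[[math.log(3.0)], [0.0]]])
        zp, beta = global_attention_pool(z, np.array([1.0]), np.zeros(1))
        assert np.allclose(beta, [[0.75, 0.25]])
        assert np.allclose(zp[0, 0, 0], 0.75 * math.log(3.0))

    def test_weights_sum_to_one(self, rng):
        z = rng.standard_normal((4, 9, 5))
        _, beta = global_attention_pool(z, rng.standard_normal(5), rng.standard_normal(1))
        assert np.allclose(beta.sum(axis=1), 1.0)
        assert np.all(beta >= 0)

    def test_matches_oracle(self, rng):
        z = rng.standard_normal((1, 4, 3))
        w, b = rng.standard_normal(3), rng.standard_normal(1)
        zp, beta = global_attention_pool(z, w, b)
        obeta, ozp = oracle_global_pool(z[0].tolist(), w.tolist(), float(b[0]))
        assert np.allclose(beta[0], obeta, atol=1e-12)
        assert np.allclose(zp[0], ozp, atol=1e-12)


class TestClassify:
    def _zero_head(self, in_w, dims, k):
        widths = [in_w] + dims + [k]
        ws = [np.zeros((a, b)) for a, b in zip(widths[:-1], widths[1:])]
        bs = [np.zeros(b) for b in widths[1:]]
        return ws, bs

    def test_zero_weights_give_uniform_probabilities(self):
        ws, bs = self._zero_head(6, [4, 4, 4], 3)
        probs, _ = classify(np.ones((2, 2, 3)), ws, bs)
        assert np.allclose(probs, 1.0 / 3)

    def test_probabilities_sum_to_one(self, rng):
        widths = [8, 5, 4, 3, 2]
        ws = [rng.standard_normal((a, b)) for a, b in zip(widths[:-1], widths[1:])]
        bs = [rng.standard_normal(b) for b in widths[1:]]
        probs, _ = classify(rng.standard_normal((6, 4, 2)), ws, bs)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_matches_oracle_affine_chain(self, rng):
        widths = [4, 3, 3, 3, 2]
        ws = [rng.standard_normal((a, b)) for a, b in zip(widths[:-1], widths[1:])]
        bs = [rng.standard_normal(b) for b in widths[1:]]
        x = rng.standard_normal((1, 2, 2))
        probs, logits = classify(x, ws, bs)
        oprobs, ologits = oracle_head(x.reshape(-1).tolist(),
                                      [w.tolist() for w in ws], [b.tolist() for b in bs])
        assert np.allclose(logits[0], ologits, atol=1e-10)
        assert np.allclose(probs[0], oprobs, atol=1e-10)

    def test_wrong_flatten_width_raises(self, rng):
        ws, bs = self._zero_head(10, [4, 4, 4], 2)
        with pytest.raises(ValueError, match="width"):
            classify(rng.standard_normal((1, 3, 2)), ws, bs)


class TestPlainGCN:
    def test_no_edges_reduces_to_project(self, rng):
        x = rng.standard_normal((2, 4, 3))
        w = rng.standard_normal((3, 5))
        out = plain_gcn_layer(x, w, np.eye(4))
        assert np.allclose(out, project(x, w))

    def test_ring_adjacency_row_sums_bounded_by_one(self):
        """Spectral oracle on a 4-cycle: symmetric normalization of a
        regular graph gives row sums exactly 1 (largest eigenvalue 1)."""
        a_hat = normalized_ring_adjacency(4, k=1)
        assert np.allclose(a_hat.sum(axis=1), 1.0)
        eigvals = np.linalg.eigvalsh(a_hat)
        assert eigvals.max() <= 1.0 + 1e-12

    def test_non_symmetric_adjacency_rejected(self, rng):
        bad = np.triu(np.ones((3, 3)))
        with pytest.raises(ValueError, match="symmetric"):
            plain_gcn_layer(rng.standard_normal((1, 3, 2)), rng.standard_normal((2, 2)), bad)

    def test_variant_preserves_shapes(self, rng):
        cfg_a = ModelConfig(n_electrodes=5, n_bands=3, layer_dims=[4], classifier_dims=[6, 5, 4],
                            n_classes=3, conv="attention")
        cfg_g = ModelConfig(n_electrodes=5, n_bands=3, layer_dims=[4], classifier_dims=[6, 5, 4],
                            n_classes=3, conv="plain_gcn")
        x = rng.standard_normal((2, 5, 3))
        out_a = EmotionGraphNet(cfg_a, rng=0).forward(x)
        out_g = EmotionGraphNet(cfg_g, rng=0).forward(x)
        assert out_a["probs"].shape == out_g["probs"].shape
        assert out_a["node_embedding"].shape == out_g["node_embedding"].shape


class TestForwardStack:
    def test_full_forward_matches_composed_oracle(self, rng):
        """Every intermediate of a 2-layer, 3-node forward pass agrees with
        the loop-based oracle to 1e-6."""
        cfg = ModelConfig(n_electrodes=3, n_bands=2, layer_dims=[3, 2],
                          classifier_dims=[4, 4, 4], n_classes=2)
        net = EmotionGraphNet(cfg, rng=1)
        x = rng.standard_normal((1, 3, 2))

        out = net.forward(x)

        # oracle, layer by layer
        item = x[0].tolist()
        h1, sym1, z1 = oracle_attention_layer(item, net.layer_W[0].data.tolist(),
                                              net.layer_A[0].data.tolist())
        z1r = [[max(0.0, v) for v in row] for row in z1]  # inter-layer ReLU
        h2, sym2, z2 = oracle_attention_layer(z1r, net.layer_W[1].data.tolist(),
                                              net.layer_A[1].data.tolist())
        assert np.allclose(out["attention_maps"][0][0], sym1, atol=1e-6)
        assert np.allclose(out["attention_maps"][1][0], sym2, atol=1e-6)
        assert np.allclose(out["node_embedding"].data[0], z2, atol=1e-6)

        beta, zp = oracle_global_pool(z2, net.scorer_w.data.tolist(),
                                      float(net.scorer_b.data[0]))
        assert np.allclose(out["beta"][0], beta, atol=1e-6)

        flat = [v for row in zp for v in row]
        oprobs, _ = oracle_head(flat, [w.data.tolist() for w in net.head_W],
                                [b.data.tolist() for b in net.head_b])
        assert np.allclose(out["probs"].data[0], oprobs, atol=1e-6)

    def test_attention_map_bookkeeping(self, rng):
        cfg = ModelConfig(n_electrodes=4, n_bands=3, layer_dims=[5, 6],
                          classifier_dims=[4, 4, 4], n_classes=3)
        out = EmotionGraphNet(cfg, rng=0).forward(rng.standard_normal((7, 4, 3)))
        assert len(out["attention_maps"]) == 2
        assert all(a.shape == (7, 4, 4) for a in out["attention_maps"])

    def test_permutation_equivariance(self, rng):
        """Permuting electrodes permutes attention rows/cols and embeddings."""
        cfg = ModelConfig(n_electrodes=5, n_bands=3, layer_dims=[4],
                          classifier_dims=[4, 4, 4], n_classes=2)
        net = EmotionGraphNet(cfg, rng=2)
        x = rng.standard_normal((2, 5, 3))
        perm = rng.permutation(5)
        out = net.forward(x)
        out_p = net.forward(x[:, perm, :])
        assert np.allclose(out_p["attention_maps"][0],
                           out["attention_maps"][0][:, perm][:, :, perm], atol=1e-10)
        z = out["node_embedding"].data
        assert np.allclose(out_p["node_embedding"].data, z[:, perm, :], atol=1e-10)

    def test_input_shape_validation(self, rng):
        net = EmotionGraphNet(ModelConfig(n_electrodes=4, n_bands=3), rng=0)
        with pytest.raises(ValueError, match="input must be"):
            net.forward(rng.standard_normal((2, 5, 3)))


class TestSumPool:
    def test_direct_summation_matches_oracle(self, rng):
        z = rng.standard_normal((3, 6, 4))
        assert np.allclose(sum_pool(z), z.sum(axis=1))


class TestFlopCounter:
    def test_quadruples_when_electrodes_double(self):
        base = flops_attention_layer(64, 62, 5, 32)
        doubled = flops_attention_layer(64, 124, 5, 32)
        assert 3.5 < doubled / base < 4.5

    def test_asymptotic_ratio_approaches_four(self):
        big = flops_attention_layer(1, 4096, 8, 8)
        bigger = flops_attention_layer(1, 8192, 8, 8)
        assert abs(bigger / big - 4.0) < 0.05

    def test_linear_in_batch(self):
        assert flops_attention_layer(128, 62, 5, 32) == 2 * flops_attention_layer(64, 62, 5, 32)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, rng):
        cfg = ModelConfig(n_electrodes=6, n_bands=4, layer_dims=[5],
                          classifier_dims=[8, 6, 4], n_classes=3)
        net = EmotionGraphNet(cfg, rng=3)
        x = rng.standard_normal((5, 6, 4))
        path = tmp_path / "model.npz"
        save_checkpoint(path, net)
        restored = load_checkpoint(path)
        assert np.allclose(restored.forward(x)["probs"].data, net.forward(x)["probs"].data)
        assert restored.config == cfg

    def test_parameter_count_logged_value_positive(self):
        net = EmotionGraphNet(ModelConfig(), rng=0)
        assert net.n_parameters() > 0


class TestModelConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"layer_dims": []},
            {"classifier_dims": [1, 2]},
            {"n_classes": 1},
            {"pooling": "max"},
            {"conv": "cheb"},
            {"activation": "gelu"},
        ],
    )
    def test_bad_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)
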