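"""Attention-driven dynamic graph convolution over electrode graphs.

One layer projects band features into a latent space (``H = X W``), builds
a data-dependent electrode adjacency ``softmax(H A H^T)`` symmetrized by
averaging with its transpose, and aggregates ``Z = A_att H``. Stacked
layers feed a global attention pool (softmax node weights) and a four-layer
fully connected softmax head. A plain, fixed-graph GCN layer and a direct
summation pool are provided as ablation variants.

All public ops accept either plain numpy arrays (forward evaluation) or
:class:`~emognn.autodiff.Tensor` (differentiable); single code path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "ModelConfig",
    "project",
    "attention_adjacency",
    "graph_conv",
    "global_attention_pool",
    "sum_pool",
    "classify",
    "plain_gcn_layer",
    "normalized_ring_adjacency",
    "EmotionGraphNet",
    "flops_attention_layer",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``layer_dims`` and ``classifier_dims`` defaults are desk-scale choices,
    not canonical values; the head always has four affine layers (three
    hidden widths plus the class layer).
    """

    n_electrodes: int = 62
    n_bands: int = 5
    layer_dims: list[int] = field(default_factory=lambda: [32, 64])
    classifier_dims: list[int] = field(default_factory=lambda: [256, 128, 64])
    n_classes: int = 3
    activation: str = "relu"
    pooling: str = "global_attention"  # or "sum"
    conv: str = "attention"  # or "plain_gcn"
    gcn_ring_neighbors: int = 2

    def __post_init__(self):
        if not self.layer_dims:
            raise ValueError("layer_dims must be non-empty")
        if len(self.classifier_dims) != 3:
            raise ValueError("classifier_dims must list exactly 3 hidden widths")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.activation != "relu":
            raise ValueError(f"unsupported activation {self.activation!r}")
        if self.pooling not in ("global_attention", "sum"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.conv not in ("attention", "plain_gcn"):
            raise ValueError(f"unknown conv variant {self.conv!r}")


# --------------------------------------------------------------------------
# functional ops
# --------------------------------------------------------------------------

def _dispatch(*arrays):
    """Wrap ndarrays as Tensors; remember whether any input was a Tensor."""
    any_tensor = any(isinstance(a, Tensor) for a in arrays)
    return [as_tensor(a) for a in arrays], any_tensor


def _undispatch(out, any_tensor):
    if any_tensor:
        return out
    if isinstance(out, tuple):
        return tuple(o.data if isinstance(o, Tensor) else o for o in out)
    return out.data


def project(X, W):
    """Latent node embedding ``H = X W`` (batched over the leading axis)."""
    (X, W), t = _dispatch(X, W)
    if X.shape[-1] != W.shape[0]:
        raise ValueError(f"feature width {X.shape[-1]} does not match projection input {W.shape[0]}")
    return _undispatch(X @ W, t)


def attention_adjacency(H, A):
    """Batch of symmetric electrode adjacencies from latent embeddings.

    ``softmax(H A H^T)`` over the last electrode axis (max-stabilized),
    then averaged with its transpose. Entries lie in [0, 1]; each matrix
    sums to E.
    """
    (H, A), t = _dispatch(H, A)
    if H.shape[-1] != A.shape[0] or A.shape[0] != A.shape[1]:
        raise ValueError("attention kernel must be square F' x F' matching H")
    scores = (H @ A) @ H.transpose_last()
    if not np.isfinite(scores.data).all():
        raise FloatingPointError("non-finite attention scores")
    att = scores.softmax(axis=-1)
    sym = (att + att.transpose_last()) * 0.5
    return _undispatch(sym, t)


def graph_conv(G, H):
    """One aggregation step ``Z = A_att H``; cost O(B * E^2 * F')."""
    (G, H), t = _dispatch(G, H)
    if G.shape[-1] != H.shape[-2]:
        raise ValueError("adjacency and embedding electrode axes do not match")
    return _undispatch(G @ H, t)


def global_attention_pool(Z, scorer_w, scorer_b):
    """Softmax node weighting.

    A learned linear map scores each node (``omega``); weights ``beta`` are
    the softmax of the scores over electrodes; each node feature is scaled
    by its weight (``Z'_i = beta_i * Z_i``). Returns ``(Z', beta)``.
    """
    (Z, w, b), t = _dispatch(Z, scorer_w, scorer_b)
    omega = (Z @ w.reshape(-1, 1)).reshape(Z.shape[0], Z.shape[1]) + b  # (B, E)
    beta = omega.softmax(axis=-1)
    zp = Z * beta.reshape(Z.shape[0], Z.shape[1], 1)
    return _undispatch((zp, beta), t)


def sum_pool(Z):
    """Ablation pooling: direct summation of node features over electrodes."""
    (Z,), t = _dispatch(Z)
    return _undispatch(Z.sum(axis=1), t)


def classify(Z_pooled, weights, biases):
    """Four affine layers with ReLU between (none after the last), softmax out.

    ``Z_pooled`` is flattened per batch item. Returns ``(probs, logits)``.
    """
    (Zp,), t = _dispatch(Z_pooled)
    ws, bs = zip(*[(as_tensor(w), as_tensor(b)) for w, b in zip(weights, biases)])
    if len(ws) != 4:
        raise ValueError("classifier head requires exactly 4 weight matrices")
    h = Zp.reshape(Zp.shape[0], -1)
    if h.shape[-1] != ws[0].shape[0]:
        raise ValueError(
            f"flattened width {h.shape[-1]} does not match head input {ws[0].shape[0]}"
        )
    for w, b in zip(ws[:-1], bs[:-1]):
        h = (h @ w + b).relu()
    logits = h @ ws[-1] + bs[-1]
    probs = logits.softmax(axis=-1)
    any_tensor = t or any(isinstance(w, Tensor) for w in weights)
    return _undispatch((probs, logits), any_tensor)


def normalized_ring_adjacency(n_nodes: int, k: int = 2) -> np.ndarray:
    """Symmetrically normalized ring graph ``D^-1/2 (A + I) D^-1/2``.

    Each node connects to its ``k`` nearest neighbors on each side in
    montage order (with wraparound).
    """
    A = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for d in range(1, k + 1):
            A[i, (i + d) % n_nodes] = 1.0
            A[i, (i - d) % n_nodes] = 1.0
    A_hat = A + np.eye(n_nodes)
    deg = A_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def plain_gcn_layer(X, W, static_adjacency: np.ndarray):
    """Fixed-graph convolution ``Z = A_hat (X W)`` (ablation variant).

    ``static_adjacency`` must already be symmetric and degree-normalized.
    """
    adj = np.asarray(static_adjacency, dtype=np.float64)
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValueError("static adjacency must be symmetric")
    (X, W, A), t = _dispatch(X, W, adj)
    return _undispatch(A @ (X @ W), t)


def flops_attention_layer(batch: int, n_electrodes: int, f_in: int, f_out: int) -> int:
    """Analytic multiply-add count of one attention convolution layer.

    Dominated by the two E^2 stages (score matrix and aggregation), hence
    quadruples when the electrode count doubles.
    """
    b, e = batch, n_electrodes
    proj = b * e * f_in * f_out            # X W
    kern = b * e * f_out * f_out           # H A
    scores = b * e * e * f_out             # (HA) H^T
    softmax_sym = 3 * b * e * e            # exp/normalize + symmetrize
    agg = b * e * e * f_out                # A_att H
    return proj + kern + scores + softmax_sym + agg


# --------------------------------------------------------------------------
# trainable network
# --------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class EmotionGraphNet:
    """The full classifier: stacked attention convolutions, pooling, head.

    Forward returns a dict exposing every intermediate needed for
    inspection and export: per-layer attention maps, pooling weights,
    pooled features (the domain-branch input), logits and probabilities.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator | int | None = None):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.config = config
        c = config

        self.layer_W: list[Tensor] = []
        self.layer_A: list[Tensor] = []
        f_in = c.n_bands
        for f_out in c.layer_dims:
            self.layer_W.append(Tensor(_glorot(rng, f_in, f_out), requires_grad=True))
            self.layer_A.append(Tensor(_glorot(rng, f_out, f_out), requires_grad=True))
            f_in = f_out

        f_last = c.layer_dims[-1]
        self.scorer_w = Tensor(_glorot(rng, f_last, 1).ravel(), requires_grad=True)
        self.scorer_b = Tensor(np.zeros(1), requires_grad=True)

        head_in = f_last if c.pooling == "sum" else c.n_electrodes * f_last
        widths = [head_in] + list(c.classifier_dims) + [c.n_classes]
        self.head_W = [
            Tensor(_glorot(rng, a, b), requires_grad=True)
            for a, b in zip(widths[:-1], widths[1:])
        ]
        self.head_b = [Tensor(np.zeros(b), requires_grad=True) for b in widths[1:]]

        self._static_adj = normalized_ring_adjacency(c.n_electrodes, c.gcn_ring_neighbors)

    # -------------------------------------------------------------- plumbing
    def parameters(self) -> list[Tensor]:
        params = self.layer_W + self.layer_A + self.head_W + self.head_b
        if self.config.pooling == "global_attention":
            params += [self.scorer_w, self.scorer_b]
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # --------------------------------------------------------------- forward
    def forward_stack(self, X: Tensor) -> tuple[Tensor, list[np.ndarray]]:
        """Stacked convolution layers; ReLU between layers, none after the last.

        Returns the node embedding and the per-layer attention maps
        (B x E x E each; for the plain-GCN variant the fixed graph).
        """
        h = as_tensor(X)
        attention_maps: list[np.ndarray] = []
        n_layers = len(self.layer_W)
        for i, (W, A) in enumerate(zip(self.layer_W, self.layer_A)):
            if self.config.conv == "attention":
                hp = project(h, W)
                g = attention_adjacency(hp, A)
                h = graph_conv(g, hp)
                attention_maps.append(g.data if isinstance(g, Tensor) else g)
            else:
                h = plain_gcn_layer(h, W, self._static_adj)
                attention_maps.append(
                    np.broadcast_to(self._static_adj, (h.shape[0],) + self._static_adj.shape)
                )
            if i < n_layers - 1:
                h = h.relu()
        return h, attention_maps

    def forward(self, X) -> dict:
        X = as_tensor(X)
        if X.ndim != 3 or X.shape[1] != self.config.n_electrodes or X.shape[2] != self.config.n_bands:
            raise ValueError(
                f"input must be (batch, {self.config.n_electrodes}, {self.config.n_bands}); "
                f"got {X.shape}"
            )
        z, attention_maps = self.forward_stack(X)
        if self.config.pooling == "global_attention":
            z_pooled, beta = global_attention_pool(z, self.scorer_w, self.scorer_b)
            beta_data = beta.data
        else:
            z_pooled = sum_pool(z)
            beta_data = np.full((z.shape[0], z.shape[1]), 1.0)
        probs, logits = classify(z_pooled, self.head_W, self.head_b)
        return {
            "logits": logits,
            "probs": probs,
            "pooled": z_pooled,
            "node_embedding": z,
            "attention_maps": attention_maps,
            "beta": beta_data,
        }

    def predict(self, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class predictions; argmax ties broken toward the lowest index."""
        X = np.asarray(X, dtype=np.float64)
        preds = []
        for start in range(0, X.shape[0], batch_size):
            probs = self.forward(X[start : start + batch_size])["probs"].data
            preds.append(np.argmax(probs, axis=-1))  # np.argmax takes first max
        return np.concatenate(preds) if preds else np.empty(0, dtype=np.int64)

    # ------------------------------------------------------------ checkpoint
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (w, a) in enumerate(zip(self.layer_W, self.layer_A)):
            out[f"layer{i}_W"] = w.data
            out[f"layer{i}_A"] = a.data
        out["scorer_w"] = self.scorer_w.data
        out["scorer_b"] = self.scorer_b.data
        for i, (w, b) in enumerate(zip(self.head_W, self.head_b)):
            out[f"head{i}_W"] = w.data
            out[f"head{i}_b"] = b.data
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i in range(len(self.layer_W)):
            self.layer_W[i].data = np.asarray(arrays[f"layer{i}_W"], dtype=np.float64)
            self.layer_A[i].data = np.asarray(arrays[f"layer{i}_A"], dtype=np.float64)
        self.scorer_w.data = np.asarray(arrays["scorer_w"], dtype=np.float64)
        self.scorer_b.data = np.asarray(arrays["scorer_b"], dtype=np.float64)
        for i in range(len(self.head_W)):
            self.head_W[i].data = np.asarray(arrays[f"head{i}_W"], dtype=np.float64)
            self.head_b[i].data = np.asarray(arrays[f"head{i}_b"], dtype=np.float64)


CHECKPOINT_SCHEMA_VERSION = 1


def save_checkpoint(path, model: EmotionGraphNet, extra: dict | None = None) -> None:
    """Single-file npz archive: parameters + config + schema version."""
    meta = {
        "schema_version": CHECKPOINT_SCHEMA_VERSION,
        "config": asdict(model.config),
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_arrays())


def load_checkpoint(path) -> EmotionGraphNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta["schema_version"] != CHECKPOINT_SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema {meta['schema_version']}")
        model = EmotionGraphNet(ModelConfig(**meta["config"]))
        model.load_state_arrays({k: archive[k] for k in archive.files if k != "__meta__"})
    return model
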