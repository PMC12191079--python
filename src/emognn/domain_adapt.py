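"""Adversarial subject adaptation: gradient reversal plus a domain head.

The reversal layer is the identity in the forward pass and multiplies
gradients by ``-alpha`` on the way back, so minimizing the domain loss
drives the upstream feature extractor to *maximize* it — pushing features
toward subject invariance. The domain head is a two-layer network with
batch normalization, ReLU and a log-softmax output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, grad_reverse

__all__ = [
    "GRLConfig",
    "grl_forward",
    "grl_backward",
    "DomainClassifier",
    "domain_classify",
]


@dataclass
class GRLConfig:
    """Reversal strength and switch; ``alpha`` defaults to 0.1."""

    alpha: float = 0.1
    enabled: bool = True
    scheme: str = "binary_source_target"  # or "per_subject"

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.scheme not in ("binary_source_target", "per_subject"):
            raise ValueError(f"unknown domain scheme {self.scheme!r}")


def grl_forward(x, cfg: GRLConfig):
    """Identity on values; wires the reversal into the tape for Tensors."""
    if isinstance(x, Tensor):
        return grad_reverse(x, cfg.alpha) if cfg.enabled else x
    return np.array(x, dtype=np.float64, copy=True)


def grl_backward(upstream_gradient: np.ndarray, cfg: GRLConfig) -> np.ndarray:
    """Explicit backward rule: ``-alpha * g`` (identity when disabled)."""
    g = np.asarray(upstream_gradient, dtype=np.float64)
    return -cfg.alpha * g if cfg.enabled else g.copy()


class _BatchNorm1d:
    """Batch statistics normalization with running estimates for eval mode."""

    def __init__(self, width: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(width), requires_grad=True)
        self.beta = Tensor(np.zeros(width), requires_grad=True)
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
            xhat = centered / (var + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class DomainClassifier:
    """linear -> batchnorm -> ReLU -> linear -> log-softmax over domains."""

    def __init__(
        self,
        in_width: int,
        n_domains: int = 2,
        hidden_width: int = 100,
        rng: np.random.Generator | int | None = None,
    ):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        limit1 = np.sqrt(6.0 / (in_width + hidden_width))
        limit2 = np.sqrt(6.0 / (hidden_width + n_domains))
        self.W1 = Tensor(rng.uniform(-limit1, limit1, (in_width, hidden_width)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden_width), requires_grad=True)
        self.bn = _BatchNorm1d(hidden_width)
        self.W2 = Tensor(rng.uniform(-limit2, limit2, (hidden_width, n_domains)), requires_grad=True)
        self.b2 = Tensor(np.zeros(n_domains), requires_grad=True)
        self.n_domains = n_domains

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2] + self.bn.parameters()

    def __call__(self, z, train: bool = True):
        z = as_tensor(z)
        h = z.reshape(z.shape[0], -1)
        if h.shape[-1] != self.W1.shape[0]:
            raise ValueError(
                f"flattened width {h.shape[-1]} does not match domain head input {self.W1.shape[0]}"
            )
        h = (h @ self.W1 + self.b1)
        h = self.bn(h, train=train)
        h = h.relu()
        return (h @ self.W2 + self.b2).log_softmax(axis=-1)


def domain_classify(z_rev, classifier: DomainClassifier, train: bool = True):
    """Log-probabilities over domains for (possibly reversed) features."""
    out = classifier(as_tensor(z_rev) if not isinstance(z_rev, Tensor) else z_rev, train=train)
    return out if isinstance(z_rev, Tensor) else out.data
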