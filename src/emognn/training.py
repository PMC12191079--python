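"""Optimization loop, evaluation protocols, metrics and ablation runs.

Two protocols are provided: leave-one-subject-out (each fold trains on all
but one subject and tests on the held-out one, optionally using its
unlabeled features as the adversarial target domain) and subject-dependent
(per subject, the first 9 trials train and the remaining trials test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, cross_entropy, nll_loss
from .domain_adapt import DomainClassifier, GRLConfig, grl_forward
from .features import FeatureTensor
from .model import EmotionGraphNet, ModelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "EvalReport",
    "Adam",
    "make_splits",
    "standardize",
    "train_model",
    "evaluate",
    "aggregate_folds",
    "run_protocol",
    "run_ablation",
    "ABLATION_VARIANTS",
]


@dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 40
    lr: float = 0.01
    seed: int = 100
    feature_standardization: str = "per_fold_zscore"  # or "none"

    def __post_init__(self):
        if self.batch_size <= 0 or self.epochs <= 0 or self.lr <= 0:
            raise ValueError("batch_size, epochs and lr must be positive")
        if self.feature_standardization not in ("per_fold_zscore", "none"):
            raise ValueError(
                f"unknown standardization {self.feature_standardization!r}"
            )


@dataclass
class SplitPlan:
    """Folds as (train_indices, test_indices) into the segment axis."""

    protocol: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    fold_names: list[str] = field(default_factory=list)


@dataclass
class EvalReport:
    fold_accuracies: list[float]
    mean_accuracy: float
    std_accuracy: float
    confusion: np.ndarray  # row-normalized, percent
    attention_mean: list[np.ndarray] | None = None  # per-layer E x E means
    beta_mean: np.ndarray | None = None  # mean pooling weights per electrode


class Adam:
    """Adam with the usual bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# --------------------------------------------------------------------------
# splits
# --------------------------------------------------------------------------

def make_splits(
    subject_ids: np.ndarray,
    trial_ids: np.ndarray,
    protocol: str,
    n_train_trials: int = 9,
) -> SplitPlan:
    """Build fold index sets for ``"loso"`` or ``"subject_dependent"``.

    LOSO: one fold per subject, testing on that subject only.
    Subject-dependent: one fold per subject; within the subject, the first
    ``n_train_trials`` trials (in trial-id order) train and the rest test.
    """
    subject_ids = np.asarray(subject_ids)
    trial_ids = np.asarray(trial_ids)
    subjects = np.unique(subject_ids)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    names: list[str] = []
    if protocol == "loso":
        if len(subjects) < 2:
            raise ValueError("LOSO requires at least 2 subjects")
        for s in subjects:
            test = np.flatnonzero(subject_ids == s)
            train = np.flatnonzero(subject_ids != s)
            folds.append((train, test))
            names.append(f"subject_{s}")
    elif protocol == "subject_dependent":
        for s in subjects:
            mask = subject_ids == s
            trials = np.unique(trial_ids[mask])
            if len(trials) <= n_train_trials:
                raise ValueError(
                    f"subject {s} has {len(trials)} trials; need more than "
                    f"{n_train_trials} for a train/test split"
                )
            train_trials = set(trials[:n_train_trials].tolist())
            train = np.flatnonzero(mask & np.isin(trial_ids, list(train_trials)))
            test = np.flatnonzero(mask & ~np.isin(trial_ids, list(train_trials)))
            folds.append((train, test))
            names.append(f"subject_{s}")
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return SplitPlan(protocol=protocol, folds=folds, fold_names=names)


def standardize(
    train_X: np.ndarray, *others: np.ndarray, eps: float = 1e-12
) -> tuple[np.ndarray, ...]:
    """Z-score every (electrode, band) dimension using training statistics only."""
    mu = train_X.mean(axis=0, keepdims=True)
    sd = train_X.std(axis=0, keepdims=True)
    sd = np.where(sd < eps, 1.0, sd)
    return tuple((x - mu) / sd for x in (train_X, *others))


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def train_model(
    X: np.ndarray,
    y: np.ndarray,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    grl_cfg: GRLConfig | None = None,
    domain_labels: np.ndarray | None = None,
    X_target: np.ndarray | None = None,
) -> tuple[EmotionGraphNet, dict]:
    """Train the classifier, optionally with the adversarial domain branch.

    ``X`` must already be standardized if desired (see :func:`run_protocol`
    for the per-fold recipe). With ``grl_cfg.enabled`` and the binary
    scheme, ``X_target`` supplies unlabeled target-domain features; with
    the per-subject scheme ``domain_labels`` gives a domain index per
    training row. Returns the trained model and a history dict with
    per-epoch emotion loss, domain loss and train accuracy.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    rng = np.random.default_rng(train_cfg.seed)
    model = EmotionGraphNet(model_cfg, rng=rng)

    use_domain = grl_cfg is not None and grl_cfg.enabled
    domain_head = None
    if use_domain:
        f_last = model_cfg.layer_dims[-1]
        in_width = f_last if model_cfg.pooling == "sum" else model_cfg.n_electrodes * f_last
        if grl_cfg.scheme == "binary_source_target":
            if X_target is None:
                raise ValueError("binary domain scheme requires X_target features")
            n_domains = 2
        else:
            if domain_labels is None:
                raise ValueError("per_subject domain scheme requires domain_labels")
            domain_labels = np.asarray(domain_labels, dtype=np.int64)
            n_domains = int(domain_labels.max()) + 1
        domain_head = DomainClassifier(in_width, n_domains=n_domains, rng=rng)

    params = model.parameters() + (domain_head.parameters() if domain_head else [])
    opt = Adam(params, lr=train_cfg.lr)

    history = {"emotion_loss": [], "domain_loss": [], "train_accuracy": []}
    n = X.shape[0]
    bs = train_cfg.batch_size
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_dloss, correct, seen = 0.0, 0.0, 0, 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, yb = X[idx], y[idx]
            opt.zero_grad()

            if use_domain and grl_cfg.scheme == "binary_source_target":
                tgt_idx = rng.integers(0, X_target.shape[0], size=len(idx))
                xb_all = np.concatenate([xb, X_target[tgt_idx]], axis=0)
                out = model.forward(xb_all)
                logits_src = out["logits"][np.arange(len(idx))]
                loss_e = cross_entropy(logits_src, yb)
                z_rev = grl_forward(out["pooled"], grl_cfg)
                dom_y = np.concatenate(
                    [np.zeros(len(idx), dtype=np.int64), np.ones(len(idx), dtype=np.int64)]
                )
                loss_d = nll_loss(domain_head(z_rev, train=True), dom_y)
                loss = loss_e + loss_d
                probs_src = out["probs"].data[: len(idx)]
            else:
                out = model.forward(xb)
                loss_e = cross_entropy(out["logits"], yb)
                if use_domain:
                    z_rev = grl_forward(out["pooled"], grl_cfg)
                    loss_d = nll_loss(domain_head(z_rev, train=True), domain_labels[idx])
                    loss = loss_e + loss_d
                else:
                    loss_d = None
                    loss = loss_e
                probs_src = out["probs"].data

            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: emotion={float(loss_e.data)}"
                    + (f", domain={float(loss_d.data)}" if loss_d is not None else "")
                )
            loss.backward()
            opt.step()

            ep_loss += float(loss_e.data) * len(idx)
            if loss_d is not None:
                ep_dloss += float(loss_d.data) * len(idx)
            correct += int((np.argmax(probs_src, axis=-1) == yb).sum())
            seen += len(idx)

        history["emotion_loss"].append(ep_loss / seen)
        history["domain_loss"].append(ep_dloss / seen if use_domain else 0.0)
        history["train_accuracy"].append(100.0 * correct / seen)
        logger.debug(
            "epoch %d: emotion_loss=%.4f domain_loss=%.4f train_acc=%.2f%%",
            epoch, history["emotion_loss"][-1], history["domain_loss"][-1],
            history["train_accuracy"][-1],
        )
    return model, history


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def evaluate(
    model: EmotionGraphNet,
    X_test: np.ndarray,
    y_test: np.ndarray,
    batch_size: int = 64,
    export_attention: bool = False,
) -> dict:
    """Accuracy (%) and row-normalized confusion (%) on one test fold."""
    if len(X_test) == 0:
        raise ValueError("empty test fold")
    y_test = np.asarray(y_test, dtype=np.int64)
    preds = model.predict(np.asarray(X_test, dtype=np.float64), batch_size=batch_size)
    acc = 100.0 * float((preds == y_test).mean())
    k = model.config.n_classes
    confusion = np.zeros((k, k))
    for t, p in zip(y_test, preds):
        confusion[t, p] += 1
    row = confusion.sum(axis=1, keepdims=True)
    confusion = np.where(row > 0, 100.0 * confusion / row, 0.0)
    result = {"accuracy": acc, "confusion": confusion, "predictions": preds}
    if export_attention:
        out = model.forward(np.asarray(X_test[:batch_size], dtype=np.float64))
        result["attention_mean"] = [a.mean(axis=0) for a in out["attention_maps"]]
        result["beta_mean"] = out["beta"].mean(axis=0)
    return result


def aggregate_folds(fold_results: list[dict], n_classes: int) -> EvalReport:
    """Mean +- population std over fold accuracies; pooled confusion."""
    accs = [r["accuracy"] for r in fold_results]
    confusion = np.mean([r["confusion"] for r in fold_results], axis=0)
    # re-normalize rows to exactly 100 (guards against all-zero rows)
    row = confusion.sum(axis=1, keepdims=True)
    confusion = np.where(row > 0, 100.0 * confusion / row, 0.0)
    att = None
    beta = None
    if fold_results and "attention_mean" in fold_results[0]:
        att = [
            np.mean([r["attention_mean"][i] for r in fold_results], axis=0)
            for i in range(len(fold_results[0]["attention_mean"]))
        ]
        beta = np.mean([r["beta_mean"] for r in fold_results], axis=0)
    return EvalReport(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        std_accuracy=float(np.std(accs)),
        confusion=confusion,
        attention_mean=att,
        beta_mean=beta,
    )


def run_protocol(
    features: FeatureTensor,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    grl_cfg: GRLConfig | None = None,
    protocol: str = "loso",
    export_attention: bool = False,
) -> EvalReport:
    """Run a full evaluation protocol over all folds.

    Standardization statistics come from each fold's training rows only.
    For LOSO with the binary adversarial scheme, the held-out subject's
    features (without labels) form the target domain.
    """
    plan = make_splits(features.subject_ids, features.trial_ids, protocol)
    X, y = features.values, features.labels
    fold_results = []
    for (train_idx, test_idx), name in zip(plan.folds, plan.fold_names):
        Xtr, Xte = X[train_idx], X[test_idx]
        if train_cfg.feature_standardization == "per_fold_zscore":
            Xtr, Xte = standardize(Xtr, Xte)
        kwargs: dict = {}
        fold_grl = grl_cfg
        if grl_cfg is not None and grl_cfg.enabled:
            if grl_cfg.scheme == "binary_source_target" and protocol == "loso":
                kwargs["X_target"] = Xte
            elif grl_cfg.scheme == "per_subject":
                subj = features.subject_ids[train_idx]
                _, dom = np.unique(subj, return_inverse=True)
                kwargs["domain_labels"] = dom
            else:
                fold_grl = None  # no target domain available for this protocol
        model, _ = train_model(
            Xtr, y[train_idx], model_cfg, train_cfg, grl_cfg=fold_grl, **kwargs
        )
        res = evaluate(
            model, Xte, y[test_idx], batch_size=train_cfg.batch_size,
            export_attention=export_attention,
        )
        logger.info("fold %s: accuracy %.2f%%", name, res["accuracy"])
        fold_results.append(res)
    return aggregate_folds(fold_results, model_cfg.n_classes)


# --------------------------------------------------------------------------
# ablations
# --------------------------------------------------------------------------

ABLATION_VARIANTS = ("full", "plain_gcn", "sum_pool", "no_grl")


def run_ablation(
    features: FeatureTensor,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    grl_cfg: GRLConfig,
    protocol: str = "loso",
) -> dict[str, EvalReport]:
    """Run the full model plus the three single-module ablations."""
    import copy

    reports: dict[str, EvalReport] = {}
    for variant in ABLATION_VARIANTS:
        cfg = copy.deepcopy(model_cfg)
        grl = copy.deepcopy(grl_cfg)
        if variant == "plain_gcn":
            cfg.conv = "plain_gcn"
        elif variant == "sum_pool":
            cfg.pooling = "sum"
        elif variant == "no_grl":
            grl = None  # entire domain branch removed
        reports[variant] = run_protocol(
            features, cfg, train_cfg, grl_cfg=grl, protocol=protocol
        )
        logger.info(
            "ablation %s: %.2f +- %.2f %%",
            variant, reports[variant].mean_accuracy, reports[variant].std_accuracy,
        )
    return reports
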