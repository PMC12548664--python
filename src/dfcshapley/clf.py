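"""Temporal-filter convolutional classifier for temporal brain networks.

The model is a single convolutional layer whose filter spans all R x R region
pairs and slides only along the time axis:

    Y[k, c] = relu( sum_{i,j,p} X[i, j, k+p-1] * W[i, j, p, c] + b[c] )

with K = T - tau + 1 temporal positions, followed by global max-pooling over
k (Z[c] = max_k Y[k, c]) and a three-layer MLP (C -> 64 -> 32 -> n_classes)
with ReLU between layers and raw logits at the output.  With tau = 1 the
max-pool makes the whole network invariant to the order of time windows.

The bias is per-channel and broadcast over temporal positions (the standard
convolution convention), which is what preserves the tau = 1 invariance; a
per-position bias b[k, c] is available via ``ModelConfig.per_position_bias``
for sensitivity experiments.

Training follows the protocol of small-sample fMRI classification studies:
batch size 1, Adam at learning rate 1e-4, 20 epochs, softmax cross-entropy
on logits, and 15 retrainings over independent stratified 80/20 splits with
mean +/- sd reporting.  The implementation is plain numpy with hand-written
backpropagation; the model is small enough that this runs comfortably on one
CPU and stays bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import GroupShuffleSplit, StratifiedShuffleSplit

from .netbuild import Normalizer, apply_normalizer, fit_normalizer

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TemporalConvModel",
    "MetricsReport",
    "RepetitionRecord",
    "init_model",
    "forward",
    "train_once",
    "evaluate",
    "run_repetitions",
]


@dataclass(frozen=True)
class ModelConfig:
    n_rois: int
    tau: int
    channels: int = 128
    hidden_sizes: tuple[int, int] = (64, 32)
    n_classes: int = 2
    per_position_bias: bool = False
    n_windows: int | None = None  # required only for per-position bias

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.per_position_bias and self.n_windows is None:
            raise ValueError("per_position_bias requires n_windows")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 20
    split_fraction: float = 0.8
    n_repetitions: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size != 1:
            raise ValueError("the training protocol uses batch size 1")


@dataclass
class TemporalConvModel:
    """Learnable parameters; shapes fixed by ModelConfig."""

    config: ModelConfig
    W: np.ndarray          # (R, R, tau, C)
    b: np.ndarray          # (C,) or (K, C) with per-position bias
    mlp_weights: list[np.ndarray]  # [(64, C), (32, 64), (n_classes, 32)]
    mlp_biases: list[np.ndarray]

    def parameter_count(self) -> int:
        n = self.W.size + self.b.size
        for w, bb in zip(self.mlp_weights, self.mlp_biases):
            n += w.size + bb.size
        return n

    def copy(self) -> "TemporalConvModel":
        return TemporalConvModel(
            config=self.config, W=self.W.copy(), b=self.b.copy(),
            mlp_weights=[w.copy() for w in self.mlp_weights],
            mlp_biases=[b.copy() for b in self.mlp_biases])


def init_model(config: ModelConfig, rng: np.random.Generator) -> TemporalConvModel:
    """Fan-in-scaled uniform initialization, U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
    R, tau, C = config.n_rois, config.tau, config.channels

    def unif(shape, fan_in):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    conv_fan = R * R * tau
    W = unif((R, R, tau, C), conv_fan)
    if config.per_position_bias:
        K = config.n_windows - tau + 1
        b = unif((K, C), conv_fan)
    else:
        b = unif((C,), conv_fan)
    sizes = [C, *config.hidden_sizes, config.n_classes]
    mlp_w = [unif((sizes[i + 1], sizes[i]), sizes[i]) for i in range(3)]
    mlp_b = [unif((sizes[i + 1],), sizes[i]) for i in range(3)]
    return TemporalConvModel(config=config, W=W, b=b,
                             mlp_weights=mlp_w, mlp_biases=mlp_b)


def _conv_windows(X: np.ndarray, tau: int) -> np.ndarray:
    """Flatten the K sliding filter supports: (K, R*R*tau), C-order matching
    W.reshape(R*R*tau, C)."""
    R, _, T = X.shape
    K = T - tau + 1
    return np.stack([X[:, :, k:k + tau].reshape(-1) for k in range(K)])


def forward(X: np.ndarray, model: TemporalConvModel,
            return_cache: bool = False):
    """Logits for one sample X of shape (R, R, T); T >= tau required."""
    cfg = model.config
    R, tau = cfg.n_rois, cfg.tau
    if X.shape[0] != R or X.shape[0] != X.shape[1]:
        raise ValueError(f"expected input shape ({R}, {R}, T), got {X.shape}")
    T = X.shape[2]
    if T < tau:
        raise ValueError(f"T={T} smaller than filter length tau={tau}")
    Xw = _conv_windows(X, tau)                      # (K, D)
    Wf = model.W.reshape(-1, cfg.channels)          # (D, C)
    # one GEMV per temporal position: BLAS batch kernels are alignment-
    # sensitive at the last ulp, which would break the exact tau=1
    # order-invariance guarantee of the max-pooled features
    A = np.stack([Xw[k].copy() @ Wf for k in range(Xw.shape[0])]) + model.b
    A = np.ascontiguousarray(A)                     # (K, C)
    Y = np.maximum(A, 0.0)
    kstar = Y.argmax(axis=0)                        # (C,)
    Z = Y[kstar, np.arange(cfg.channels)]
    h, pre = Z, []
    acts = [Z]
    for layer, (w, bb) in enumerate(zip(model.mlp_weights, model.mlp_biases)):
        a = w @ h + bb
        pre.append(a)
        h = a if layer == 2 else np.maximum(a, 0.0)
        acts.append(h)
    logits = h
    if return_cache:
        return logits, {"Xw": Xw, "A": A, "kstar": kstar, "acts": acts,
                        "pre": pre}
    return logits


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def _backward(model: TemporalConvModel, cache: dict, dlogits: np.ndarray):
    """Gradients of the loss w.r.t. every parameter for one sample."""
    cfg = model.config
    grads: dict[str, np.ndarray] = {}
    acts, pre = cache["acts"], cache["pre"]
    d = dlogits
    g_w, g_b = [None] * 3, [None] * 3
    for layer in (2, 1, 0):
        g_w[layer] = np.outer(d, acts[layer])
        g_b[layer] = d
        d = model.mlp_weights[layer].T @ d
        if layer > 0:
            d = d * (pre[layer - 1] > 0)
    dZ = d                                           # (C,)
    K = cache["A"].shape[0]
    dA = np.zeros_like(cache["A"])                   # (K, C)
    kstar = cache["kstar"]
    relu_mask = cache["A"][kstar, np.arange(cfg.channels)] > 0
    dA[kstar, np.arange(cfg.channels)] = dZ * relu_mask
    grads["W"] = (cache["Xw"].T @ dA).reshape(model.W.shape)
    grads["b"] = dA if model.b.ndim == 2 else dA.sum(axis=0)
    grads["mlp_w"], grads["mlp_b"] = g_w, g_b
    return grads


class _Adam:
    """Standard Adam with bias correction, one state slot per parameter."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def _flat_params(model: TemporalConvModel) -> list[np.ndarray]:
    return [model.W, model.b, *model.mlp_weights, *model.mlp_biases]


def train_once(train_X: list[np.ndarray], train_y: np.ndarray,
               model_cfg: ModelConfig, train_cfg: TrainConfig,
               seed: int) -> TemporalConvModel:
    """Train one model: batch size 1, per-epoch reshuffling, Adam, final-epoch
    weights returned (no early stopping).  Deterministic for fixed seed."""
    if len(train_X) == 0:
        raise ValueError("empty training set")
    train_y = np.asarray(train_y, dtype=int)
    present = np.unique(train_y)
    if len(present) < model_cfg.n_classes:
        warnings.warn(
            f"training set covers classes {present.tolist()} of "
            f"{model_cfg.n_classes}")
    rng = np.random.default_rng(seed)
    model = init_model(model_cfg, rng)
    params = _flat_params(model)
    opt = _Adam(params, lr=train_cfg.learning_rate)
    n = len(train_X)
    for _epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        for idx in order:
            logits, cache = forward(train_X[idx], model, return_cache=True)
            probs = _softmax(logits)
            dlogits = probs.copy()
            dlogits[train_y[idx]] -= 1.0
            g = _backward(model, cache, dlogits)
            opt.step(params, [g["W"], g["b"], *g["mlp_w"], *g["mlp_b"]])
    return model


def predict(model: TemporalConvModel, X_list: list[np.ndarray]) -> np.ndarray:
    """Argmax class per sample; argmax ties resolve to the lowest index."""
    return np.array([int(np.argmax(forward(X, model))) for X in X_list])


def accuracy(model: TemporalConvModel, X_list: list[np.ndarray],
             y: np.ndarray) -> float:
    return float(np.mean(predict(model, X_list) == np.asarray(y)))


@dataclass
class MetricsReport:
    """Mean +/- sd of accuracy/precision/recall/F1 across repetitions.

    Precision, recall and F1 are macro-averaged over the classes present in
    the test set (macro == micro on balanced data, but stays well defined on
    unbalanced sets)."""

    per_repetition: list[dict] = field(default_factory=list)

    def add(self, metrics: dict) -> None:
        self.per_repetition.append(metrics)

    def mean(self, key: str) -> float:
        return float(np.mean([m[key] for m in self.per_repetition]))

    def sd(self, key: str) -> float:
        return float(np.std([m[key] for m in self.per_repetition]))

    def summary(self) -> dict:
        return {key: {"mean": self.mean(key), "sd": self.sd(key)}
                for key in ("accuracy", "precision", "recall", "f1")}


def evaluate(model: TemporalConvModel, test_X: list[np.ndarray],
             test_y: np.ndarray) -> dict:
    """One repetition's metrics on a held-out set."""
    if len(test_X) == 0:
        raise ValueError("empty test set")
    test_y = np.asarray(test_y, dtype=int)
    pred = predict(model, test_X)
    present = np.unique(test_y)
    if len(present) < model.config.n_classes:
        warnings.warn(
            f"test set covers classes {present.tolist()}; macro metrics "
            "exclude absent classes")
    prec, rec, f1, _ = precision_recall_fscore_support(
        test_y, pred, labels=present, average="macro", zero_division=0)
    return {"accuracy": float(np.mean(pred == test_y)),
            "precision": float(prec), "recall": float(rec), "f1": float(f1)}


@dataclass
class RepetitionRecord:
    """Everything one training repetition produced, kept for attribution."""

    index: int
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    model: TemporalConvModel
    normalizer: Normalizer
    metrics: dict


def _make_splits(y: np.ndarray, n_repetitions: int, train_frac: float,
                 seed: int, groups=None):
    """Sample-level stratified splits by default; with ``groups`` (e.g.
    subject ids) whole groups go to one side, preventing the same subject
    from appearing in both train and test (not stratified)."""
    if groups is not None:
        splitter = GroupShuffleSplit(n_splits=n_repetitions,
                                     train_size=train_frac,
                                     random_state=seed % (2 ** 31))
        return list(splitter.split(np.zeros(len(y)), y, groups=groups))
    counts = {int(c): int(n) for c, n in zip(*np.unique(y, return_counts=True))}
    if min(counts.values()) < 2:
        raise ValueError(f"stratified split impossible; class counts {counts}")
    splitter = StratifiedShuffleSplit(
        n_splits=n_repetitions, train_size=train_frac,
        random_state=seed % (2 ** 31))
    return list(splitter.split(np.zeros(len(y)), y))


def run_repetitions(networks, y: np.ndarray, model_cfg: ModelConfig,
                    train_cfg: TrainConfig, *,
                    normalizer_scope: str = "per_edge",
                    fit_normalizer_globally: bool = False,
                    groups=None,
                    ) -> tuple[MetricsReport, list[RepetitionRecord]]:
    """The full protocol: n_repetitions stratified 80/20 splits, per-split
    normalizer fit on the training pool only (leakage-safe; set
    ``fit_normalizer_globally=True`` to normalize once on all data), train,
    evaluate, and retain (split, normalizer, model) for attribution.

    ``networks`` is either a list of raw :class:`TemporalNetwork` or a
    callable ``networks(rep_index, rep_seed) -> list[TemporalNetwork]`` —
    the hook the permutation controls use to redraw their shuffle every
    repetition.
    """
    y = np.asarray(y, dtype=int)
    master = np.random.SeedSequence(train_cfg.seed)
    split_seed, *rep_seeds = [
        int(ss.generate_state(1)[0] % (2 ** 31))
        for ss in master.spawn(train_cfg.n_repetitions + 1)]
    splits = _make_splits(y, train_cfg.n_repetitions,
                          train_cfg.split_fraction, split_seed, groups=groups)
    report = MetricsReport()
    records: list[RepetitionRecord] = []
    for rep, (train_idx, test_idx) in enumerate(splits):
        rep_seed = rep_seeds[rep]
        nets = networks(rep, rep_seed) if callable(networks) else networks
        if any(n.normalization_state != "raw" for n in nets):
            raise ValueError("run_repetitions expects raw networks")
        pool = nets if fit_normalizer_globally else [nets[i] for i in train_idx]
        norm = fit_normalizer(pool, scope=normalizer_scope)
        tensors = [apply_normalizer(n, norm).tensor for n in nets]
        model = train_once([tensors[i] for i in train_idx], y[train_idx],
                           model_cfg, train_cfg, seed=rep_seed)
        metrics = evaluate(model, [tensors[i] for i in test_idx], y[test_idx])
        report.add(metrics)
        records.append(RepetitionRecord(
            index=rep, seed=rep_seed, train_idx=train_idx, test_idx=test_idx,
            model=model, normalizer=norm, metrics=metrics))
    return report, records
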