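"""A small 1-D convolutional classifier over the reduced feature vectors.

Topology (fixed, sized by the selector's output dimensionality D):

    conv1d(64 filters, kernel 7, stride 1, valid padding)
      -> batch-norm (momentum 0.8 on the running averages, eps 1e-5)
      -> ELU
      -> flatten                       # (D-6) * 64 units
      -> dense(16, ELU) -> dense(8, ELU) -> dense(1, sigmoid)

Training is plain SGD with momentum 0.9 and learning rate 1e-3 on binary
cross-entropy, with early stopping on validation accuracy (patience 10,
best weights restored).  The network is implemented directly in NumPy with
hand-written backpropagation; gradients are pinned by finite-difference
checks in the test suite.

Batch-norm momentum convention: 0.8 weighs the *running* statistic, i.e.
running <- 0.8 * running + 0.2 * batch.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .feature_selector import SelectorModel

logger = logging.getLogger("sixmanet")


# ---------------------------------------------------------------------------
# activations

def elu(x: np.ndarray | float, alpha: float = 1.0) -> np.ndarray | float:
    """Exponential linear unit: x for x > 0, alpha*(e^x - 1) for x <= 0."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))
    return out if out.ndim else float(out)


def elu_grad(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, 1.0, alpha * np.exp(np.minimum(x, 0.0)))


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Logistic function 1 / (1 + e^-x), computed stably for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class NetworkConfig:
    conv_filters: int = 64
    kernel_size: int = 7
    stride: int = 1
    bn_momentum: float = 0.8  # weight on the running statistic
    bn_epsilon: float = 1e-5
    elu_alpha: float = 1.0
    dense1_units: int = 16
    dense2_units: int = 8

    def __post_init__(self) -> None:
        if min(self.conv_filters, self.kernel_size, self.stride,
               self.dense1_units, self.dense2_units) < 1:
            raise ValueError("layer sizes must be positive integers")
        if not 0.0 < self.bn_momentum < 1.0:
            raise ValueError("bn_momentum must lie in (0,1)")
        if self.elu_alpha <= 0:
            raise ValueError("elu_alpha must be positive")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    sgd_momentum: float = 0.9
    patience: int = 10  # epochs without validation-accuracy improvement
    max_epochs: int = 100
    batch_size: int = 256
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0,1)")


# ---------------------------------------------------------------------------
# network

class Network:
    """The CNN's parameters plus forward/backward passes."""

    PARAM_NAMES = (
        "conv_w", "conv_b", "bn_gamma", "bn_beta",
        "w1", "b1", "w2", "b2", "w3", "b3",
    )

    def __init__(self, input_dim: int, cfg: NetworkConfig, seed: int = 0):
        if input_dim < cfg.kernel_size:
            raise ValueError(
                f"input_dim {input_dim} smaller than kernel size {cfg.kernel_size}"
            )
        self.input_dim = input_dim
        self.cfg = cfg
        self.conv_len = (input_dim - cfg.kernel_size) // cfg.stride + 1
        self.flat_dim = self.conv_len * cfg.conv_filters
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "conv_w": he((cfg.conv_filters, cfg.kernel_size), cfg.kernel_size),
            "conv_b": np.zeros(cfg.conv_filters),
            "bn_gamma": np.ones(cfg.conv_filters),
            "bn_beta": np.zeros(cfg.conv_filters),
            "w1": he((self.flat_dim, cfg.dense1_units), self.flat_dim),
            "b1": np.zeros(cfg.dense1_units),
            "w2": he((cfg.dense1_units, cfg.dense2_units), cfg.dense1_units),
            "b2": np.zeros(cfg.dense2_units),
            "w3": he((cfg.dense2_units, 1), cfg.dense2_units),
            "b3": np.zeros(1),
        }
        self.running_mean = np.zeros(cfg.conv_filters)
        self.running_var = np.ones(cfg.conv_filters)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward -----------------------------------------------------------

    def _conv(self, x: np.ndarray) -> np.ndarray:
        # x: (batch, D) single-channel signal -> (batch, T, F)
        windows = sliding_window_view(x, self.cfg.kernel_size, axis=1)
        windows = windows[:, :: self.cfg.stride]
        return np.tensordot(windows, self.params["conv_w"], axes=([2], [1])) \
            + self.params["conv_b"]

    def forward(self, x: np.ndarray, training: bool = False):
        """Return scores (batch,), caching intermediates when training."""
        p, cfg = self.params, self.cfg
        x = np.asarray(x, dtype=float)
        z_conv = self._conv(x)  # (batch, T, F)

        if training:
            mu = z_conv.mean(axis=(0, 1))
            var = z_conv.var(axis=(0, 1))
            m = cfg.bn_momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + cfg.bn_epsilon)
        xhat = (z_conv - mu) * inv_std
        z_bn = p["bn_gamma"] * xhat + p["bn_beta"]

        a_conv = elu(z_bn, cfg.elu_alpha)
        flat = a_conv.reshape(x.shape[0], -1)
        z1 = flat @ p["w1"] + p["b1"]
        a1 = elu(z1, cfg.elu_alpha)
        z2 = a1 @ p["w2"] + p["b2"]
        a2 = elu(z2, cfg.elu_alpha)
        z3 = (a2 @ p["w3"] + p["b3"]).ravel()
        scores = sigmoid(z3)
        if not training:
            return scores
        cache = dict(x=x, xhat=xhat, inv_std=inv_std, z_bn=z_bn, flat=flat,
                     z1=z1, a1=a1, z2=z2, a2=a2, scores=scores)
        return scores, cache

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, y: np.ndarray) -> dict:
        """Gradients of mean binary cross-entropy w.r.t. every parameter."""
        p, cfg = self.params, self.cfg
        n = y.shape[0]
        grads = {}

        dz3 = ((cache["scores"] - y) / n)[:, None]  # BCE + sigmoid
        grads["w3"] = cache["a2"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        da2 = dz3 @ p["w3"].T
        dz2 = da2 * elu_grad(cache["z2"], cfg.elu_alpha)
        grads["w2"] = cache["a1"].T @ dz2
        grads["b2"] = dz2.sum(axis=0)
        da1 = dz2 @ p["w2"].T
        dz1 = da1 * elu_grad(cache["z1"], cfg.elu_alpha)
        grads["w1"] = cache["flat"].T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dflat = dz1 @ p["w1"].T
        da_conv = dflat.reshape(n, self.conv_len, cfg.conv_filters)
        dz_bn = da_conv * elu_grad(cache["z_bn"], cfg.elu_alpha)

        xhat = cache["xhat"]
        grads["bn_gamma"] = (dz_bn * xhat).sum(axis=(0, 1))
        grads["bn_beta"] = dz_bn.sum(axis=(0, 1))
        dxhat = dz_bn * p["bn_gamma"]
        m = n * self.conv_len  # samples per channel in the batch statistics
        dz_conv = cache["inv_std"] / m * (
            m * dxhat
            - dxhat.sum(axis=(0, 1))
            - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )

        windows = sliding_window_view(cache["x"], cfg.kernel_size, axis=1)
        windows = windows[:, :: cfg.stride]
        grads["conv_w"] = np.tensordot(dz_conv, windows, axes=([0, 1], [0, 1]))
        grads["conv_b"] = dz_conv.sum(axis=(0, 1))
        return grads

    # -- state -------------------------------------------------------------

    def state(self) -> dict:
        s = {k: v.copy() for k, v in self.params.items()}
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, s: dict) -> None:
        for k in self.PARAM_NAMES:
            if self.params[k].shape != s[k].shape:
                raise ValueError(
                    f"weight '{k}' shape {s[k].shape} does not match "
                    f"network shape {self.params[k].shape}"
                )
            self.params[k] = s[k].copy()
        self.running_mean = s["running_mean"].copy()
        self.running_var = s["running_var"].copy()


def build_network(input_dim: int, cfg: NetworkConfig | None = None,
                  seed: int = 0) -> Network:
    """Construct an untrained network for ``input_dim`` reduced features."""
    return Network(input_dim, cfg or NetworkConfig(), seed=seed)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainedModel:
    network: Network
    net_config: NetworkConfig
    train_config: TrainConfig
    selector: SelectorModel | None = None
    history: list[dict] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.network.input_dim


def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    val_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = max(1, int(round(fraction * idx.size)))
        val_idx.append(idx[:k])
    val = np.sort(np.concatenate(val_idx))
    train = np.setdiff1d(np.arange(y.size), val)
    return train, val


def _bce(scores: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(y * np.log(scores + eps)
                          + (1 - y) * np.log(1 - scores + eps)))


def train(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
    selector: SelectorModel | None = None,
) -> TrainedModel:
    """SGD training with early stopping on validation accuracy.

    Stops once validation accuracy has not improved for ``cfg.patience``
    epochs (or at ``max_epochs``) and restores the best epoch's weights.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] != net.input_dim:
        raise ValueError(f"X has {X.shape[1]} columns, network expects {net.input_dim}")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng(cfg.seed)
    tr, va = _stratified_split(y, cfg.validation_fraction, rng)
    X_tr, y_tr, X_va, y_va = X[tr], y[tr], X[va], y[va]

    velocity = {k: np.zeros_like(v) for k, v in net.params.items()}
    best_acc, best_epoch, best_state = -np.inf, -1, net.state()
    history: list[dict] = []

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(y_tr.size)
        losses = []
        for start in range(0, y_tr.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            scores, cache = net.forward(X_tr[batch], training=True)
            loss = _bce(scores, y_tr[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; aborting"
                )
            losses.append(loss)
            grads = net.backward(cache, y_tr[batch])
            for k, g in grads.items():
                g = g.reshape(net.params[k].shape)
                velocity[k] = cfg.sgd_momentum * velocity[k] - cfg.learning_rate * g
                net.params[k] = net.params[k] + velocity[k]

        val_scores = net.forward(X_va)
        val_acc = float(np.mean((val_scores >= 0.5) == y_va))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_accuracy": val_acc})
        if val_acc > best_acc:
            best_acc, best_epoch, best_state = val_acc, epoch, net.state()
        elif epoch - best_epoch >= cfg.patience:
            logger.info("early stop at epoch %d (best %d, val acc %.4f)",
                        epoch, best_epoch, best_acc)
            break

    net.load_state(best_state)
    return TrainedModel(network=net, net_config=net.cfg, train_config=cfg,
                        selector=selector, history=history)


# ---------------------------------------------------------------------------
# inference

def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """6mA probability per row, in [0,1], using the frozen running statistics."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"X has shape {X.shape}; model expects (*, {model.input_dim})"
        )
    return model.network.forward(X)


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary calls from probabilities; a score equal to the threshold is
    called positive (the documented tie-break at exactly 0.5)."""
    scores = np.asarray(scores, dtype=float)
    if np.any(scores < 0) or np.any(scores > 1):
        raise ValueError("scores must lie in [0,1]")
    return (scores >= threshold).astype(int)


# ---------------------------------------------------------------------------
# persistence

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a self-describing model directory.

    Layout: weights.npz (parameters + running stats), config.json (network
    and training configuration), selector.json (feature-selector sidecar),
    history.csv (per-epoch loss and validation accuracy).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **model.network.state())
    (path / "config.json").write_text(json.dumps({
        "input_dim": model.input_dim,
        "network": asdict(model.net_config),
        "training": asdict(model.train_config),
    }, indent=2))
    if model.selector is not None:
        model.selector.save(path / "selector.json")
    with (path / "history.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_accuracy"])
        writer.writeheader()
        writer.writerows(model.history)


def load_model(path: str | Path, require_selector: bool = True) -> TrainedModel:
    """Load a model directory; predictions round-trip to float precision."""
    path = Path(path)
    cfg = json.loads((path / "config.json").read_text())
    net_cfg = NetworkConfig(**cfg["network"])
    train_cfg = TrainConfig(**cfg["training"])
    net = Network(cfg["input_dim"], net_cfg)
    with np.load(path / "weights.npz") as data:
        net.load_state({k: data[k] for k in data.files})

    selector = None
    sel_path = path / "selector.json"
    if sel_path.exists():
        selector = SelectorModel.load(sel_path)
        if selector.n_selected != net.input_dim:
            raise ValueError(
                f"selector retains {selector.n_selected} features but the "
                f"network expects {net.input_dim}"
            )
    elif require_selector:
        raise FileNotFoundError(f"selector sidecar not found: {sel_path}")

    history = []
    hist_path = path / "history.csv"
    if hist_path.exists():
        with hist_path.open(newline="") as fh:
            for row in csv.DictReader(fh):
                history.append({"epoch": int(row["epoch"]),
                                "train_loss": float(row["train_loss"]),
                                "val_accuracy": float(row["val_accuracy"])})
    return TrainedModel(network=net, net_config=net_cfg, train_config=train_cfg,
                        selector=selector, history=history)
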