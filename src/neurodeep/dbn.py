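"""Deep belief networks: greedy layer-wise pre-training of stacked RBMs and
supervised fine-tuning with a softmax head.

Layer 1 is a Gaussian-visible RBM on the (z-scored) input voxels; deeper
layers are trained on the feed-forward activations of the stack below and
use logistic units on both sides.  Fine-tuning initializes a feed-forward
network from the pre-trained weights, adds a softmax output layer, and
trains the whole stack by backpropagation of the cross-entropy with plain
mini-batch gradient descent at per-layer learning rates, with optional
(inverted) dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, softmax as _softmax

from . import data as _data
from .rbm import RBMParams, TrainConfig, hidden_conditional, train_rbm


@dataclass(frozen=True)
class FinetuneConfig:
    """Backpropagation settings; ``learning_rates`` has one entry per hidden
    layer, ``dropout`` one entry per layer plus one leading entry for the
    input."""

    learning_rates: tuple = ()
    head_learning_rate: float = 0.1
    n_epochs: int = 100
    batch_size: int = 10
    dropout: tuple = ()
    seed: int = 0
    plateau_tol: float = 1e-5
    patience: int = 10

    def rates_for(self, n_layers: int) -> np.ndarray:
        if not self.learning_rates:
            return np.full(n_layers, 0.1)
        if len(self.learning_rates) != n_layers:
            raise ValueError("need one learning rate per hidden layer")
        rates = np.asarray(self.learning_rates, float)
        if np.any(rates <= 0):
            raise ValueError("learning rates must be positive")
        return rates

    def dropout_for(self, n_layers: int) -> np.ndarray:
        if not self.dropout:
            return np.zeros(n_layers + 1)
        if len(self.dropout) != n_layers + 1:
            raise ValueError("dropout needs input + one entry per hidden layer")
        return np.asarray(self.dropout, float)


#: Reference hyperparameters for the 50-50-100 structural-MRI architecture:
#: per-layer (pre-training L1, pre-training rate) and fine-tuning
#: (per-layer rates, input+per-layer dropout).
SMRI_PRETRAIN_L1 = (0.1, 0.01, 0.001)
SMRI_PRETRAIN_RATES = (0.01, 0.01, 0.001)
SMRI_PRETRAIN_DROPOUT = (0.2, 0.5, 0.5, 0.5)
SMRI_FINETUNE_RATES = (0.01, 0.1, 1e-8)
SMRI_FINETUNE_DROPOUT = (0.7, 0.5, 0.5, 0.75)


def smri_finetune_config(**overrides) -> FinetuneConfig:
    """The reference fine-tuning configuration for the 50-50-100 stack."""
    kw = dict(learning_rates=SMRI_FINETUNE_RATES, dropout=SMRI_FINETUNE_DROPOUT)
    kw.update(overrides)
    return FinetuneConfig(**kw)


def smri_pretrain_configs(n_epochs: int = 30, seed: int = 0) -> list[TrainConfig]:
    """Per-layer pre-training configurations for the 50-50-100 stack."""
    return [
        TrainConfig(epsilon=r, lambda_l1=l1, n_epochs=n_epochs,
                    dropout_visible=dv, dropout_hidden=dh, seed=seed + i)
        for i, (r, l1, dv, dh) in enumerate(zip(
            SMRI_PRETRAIN_RATES, SMRI_PRETRAIN_L1,
            SMRI_PRETRAIN_DROPOUT[:-1], SMRI_PRETRAIN_DROPOUT[1:]))
    ]


@dataclass(frozen=True)
class DBNModel:
    """Ordered RBM stack, optionally topped by a softmax classification head."""

    layers: tuple            # of RBMParams, input -> output order
    softmax_W: np.ndarray | None = None   # (n_top_hidden, n_classes)
    softmax_b: np.ndarray | None = None
    classes: np.ndarray | None = None

    def __post_init__(self) -> None:
        for lo, hi in zip(self.layers[:-1], self.layers[1:]):
            if hi.n_visible != lo.n_hidden:
                raise ValueError("adjacent layer dimensions are incompatible")

    @property
    def depth(self) -> int:
        return len(self.layers)

    @property
    def layer_sizes(self) -> tuple:
        return tuple(l.n_hidden for l in self.layers)


def feedforward(model: DBNModel, X: np.ndarray, depth: int | None = None) -> np.ndarray:
    """Deterministic feed-forward activations (hidden means, no sampling).

    ``depth`` 0 returns the input itself; depth k the layer-k activations.
    """
    if depth is None:
        depth = model.depth
    if not 0 <= depth <= model.depth:
        raise ValueError(f"depth must be in [0, {model.depth}]")
    A = np.asarray(getattr(X, "values", X), float)
    for layer in model.layers[:depth]:
        A, _ = hidden_conditional(A, layer)
    return A


def predict_proba(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Softmax class probabilities of the fine-tuned model."""
    if model.softmax_W is None:
        raise ValueError("model has no softmax head; fine-tune it first")
    top = feedforward(model, X)
    return _softmax(top @ model.softmax_W + model.softmax_b, axis=1)


def pretrain_stack(
    X,
    layer_sizes: list[int],
    cfgs: list[TrainConfig] | None = None,
    hidden_type: str = "logistic",
    mode: str = "greedy",
    labels: np.ndarray | None = None,
    finetune_cfg: FinetuneConfig | None = None,
) -> DBNModel:
    """Greedy layer-wise unsupervised pre-training.

    Layer 1 sees the raw (z-scored) data through Gaussian visibles; layer
    k > 1 is trained on the feed-forward activations of the stack below.
    With ``mode="interleaved"`` the stack below is discriminatively
    fine-tuned (softmax head, requires ``labels``) before its activations
    feed the next layer's pre-training; ``"greedy"`` skips the intermediate
    fine-tunes.
    """
    if not layer_sizes:
        raise ValueError("layer_sizes must be nonempty")
    if mode not in ("greedy", "interleaved"):
        raise ValueError("mode must be 'greedy' or 'interleaved'")
    if mode == "interleaved" and labels is None:
        raise ValueError("interleaved pre-training needs labels")
    X = np.asarray(getattr(X, "values", X), float)
    if cfgs is None:
        cfgs = [TrainConfig(seed=i) for i in range(len(layer_sizes))]
    if len(cfgs) != len(layer_sizes):
        raise ValueError("need one TrainConfig per layer")

    layers: list[RBMParams] = []
    inputs = X
    for depth, (size, cfg) in enumerate(zip(layer_sizes, cfgs)):
        visible_type = "gaussian" if depth == 0 else "logistic"
        params, _ = train_rbm(inputs, size, cfg, hidden_type=hidden_type,
                              visible_type=visible_type)
        layers.append(params)
        if depth < len(layer_sizes) - 1:
            stack = DBNModel(layers=tuple(layers))
            if mode == "interleaved":
                stack = finetune_softmax(stack, X, labels,
                                         finetune_cfg or FinetuneConfig())
            inputs = feedforward(stack, X)
            layers = list(stack.layers)
    return DBNModel(layers=tuple(layers))


def _forward_train(layers, head_W, head_b, batch, dropout, rng):
    """Forward pass with inverted dropout; returns activations per layer."""
    A = batch
    acts = []
    if dropout[0] > 0:
        keep = 1.0 - dropout[0]
        A = A * (rng.random(A.shape) < keep) / keep
    acts.append(A)
    for i, layer in enumerate(layers):
        z = A / layer.sigma @ layer.W.T + layer.b
        A = np.tanh(z) if layer.hidden_type == "tanh" else expit(z)
        if dropout[i + 1] > 0:
            keep = 1.0 - dropout[i + 1]
            A = A * (rng.random(A.shape) < keep) / keep
        acts.append(A)
    logits = A @ head_W + head_b
    return acts, _softmax(logits, axis=1)


def finetune_softmax(
    model: DBNModel, X, labels: np.ndarray, cfg: FinetuneConfig | None = None
) -> DBNModel:
    """Supervised fine-tuning: softmax head on the top layer, cross-entropy
    backpropagated through every layer (plain mini-batch gradient descent at
    per-layer rates), early-stopped when the training loss plateaus."""
    if cfg is None:
        cfg = FinetuneConfig()
    X = np.asarray(getattr(X, "values", X), float)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("fine-tuning needs at least two classes")
    n, n_classes = X.shape[0], classes.size
    Y = np.eye(n_classes)[y_idx]

    rng = np.random.default_rng(cfg.seed)
    layers = [replace(l) for l in model.layers]
    rates = cfg.rates_for(len(layers))
    dropout = cfg.dropout_for(len(layers))
    top = layers[-1].n_hidden
    head_W = rng.normal(0.0, 0.01, size=(top, n_classes))
    head_b = np.zeros(n_classes)

    best_loss, stall = np.inf, 0
    for _ in range(cfg.n_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch, target = X[idx], Y[idx]
            acts, proba = _forward_train(layers, head_W, head_b, batch,
                                         dropout, rng)
            B = len(idx)
            epoch_loss -= float(np.sum(np.log(proba[np.arange(B), y_idx[idx]]
                                              + 1e-12)))
            delta = (proba - target) / B               # dL/dlogits
            gW_head = acts[-1].T @ delta
            gb_head = delta.sum(axis=0)
            delta = delta @ head_W.T
            head_W = head_W - cfg.head_learning_rate * gW_head
            head_b = head_b - cfg.head_learning_rate * gb_head
            for i in range(len(layers) - 1, -1, -1):
                layer, A = layers[i], acts[i + 1]
                if layer.hidden_type == "tanh":
                    delta = delta * (1.0 - A**2)
                else:
                    delta = delta * A * (1.0 - A)
                gW = delta.T @ (acts[i] / layer.sigma)
                gb = delta.sum(axis=0)
                if i > 0:
                    delta = delta @ (layer.W / layer.sigma)
                layers[i] = replace(layer, W=layer.W - rates[i] * gW,
                                    b=layer.b - rates[i] * gb)
        epoch_loss /= n
        if best_loss - epoch_loss < cfg.plateau_tol:
            stall += 1
            if stall >= cfg.patience:
                break
        else:
            stall = 0
        best_loss = min(best_loss, epoch_loss)
    return DBNModel(layers=tuple(layers), softmax_W=head_W, softmax_b=head_b,
                    classes=classes)


# ---------------------------------------------------------------------------
# serialization


def save_dbn(model: DBNModel, path) -> None:
    arrays, meta = {}, {"depth": model.depth, "layers": []}
    for i, l in enumerate(model.layers):
        arrays.update({f"W{i}": l.W, f"a{i}": l.a, f"b{i}": l.b, f"sigma{i}": l.sigma})
        meta["layers"].append({"hidden_type": l.hidden_type,
                               "visible_type": l.visible_type,
                               "standard_form": l.standard_form})
    if model.softmax_W is not None:
        arrays["softmax_W"] = model.softmax_W
        arrays["softmax_b"] = model.softmax_b
        arrays["classes"] = model.classes
    _data.save_archive(path, arrays, meta)


def load_dbn(path) -> DBNModel:
    arrays, meta = _data.load_archive(path)
    layers = tuple(
        RBMParams(W=arrays[f"W{i}"], a=arrays[f"a{i}"], b=arrays[f"b{i}"],
                  sigma=arrays[f"sigma{i}"], **meta["layers"][i])
        for i in range(meta["depth"])
    )
    return DBNModel(layers=layers,
                    softmax_W=arrays.get("softmax_W"),
                    softmax_b=arrays.get("softmax_b"),
                    classes=arrays.get("classes"))
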