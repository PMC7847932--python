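"""Sparse-response deep belief networks.

A DBN here is an ordered stack of SR-RBMs trained greedily: the first RBM
learns on the data, and each subsequent RBM learns on the deterministic
hidden activation probabilities of the layer below.  The default stack has
one input layer and three hidden layers of equal size.  After pretraining,
an optional supervised fine-tuning pass attaches a softmax output head to
the top hidden layer and runs plain gradient descent on the cross-entropy
of the training labels through the whole network; the head is kept only as
a diagnostic — classification is delegated to the ELM stage downstream.

Feature extraction is a pure deterministic forward pass of sigmoid
activations (no sampling), so extracted features are reproducible
functions of (model, data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List

import numpy as np

from ._utils import ValidationError, as_2d_float, sigmoid, substream
from .srrbm import RBMParams, SRTrainConfig, hidden_probs, init_params, train_srrbm

__all__ = ["DBNModel", "build_dbn", "pretrain", "finetune", "extract_features"]


@dataclass
class DBNModel:
    layers: List[RBMParams]
    layer_sizes: List[int]               # input size followed by hidden sizes
    head_W: np.ndarray | None = None     # softmax head, fine-tuning only
    head_b: np.ndarray | None = None
    finetuned: bool = False
    pretrained: bool = False
    finetune_loss: List[float] = field(default_factory=list)
    pretrain_traces: list = field(default_factory=list)

    def __post_init__(self):
        sizes = [self.layers[0].n_visible] + [l.n_hidden for l in self.layers]
        for t in range(len(self.layers) - 1):
            if self.layers[t].n_hidden != self.layers[t + 1].n_visible:
                raise ValidationError(
                    f"layer {t} hidden size {self.layers[t].n_hidden} does not chain "
                    f"into layer {t + 1} visible size {self.layers[t + 1].n_visible}"
                )
        if list(self.layer_sizes) != sizes:
            raise ValidationError(f"layer_sizes {self.layer_sizes} inconsistent with layers {sizes}")

    @property
    def n_hidden_layers(self) -> int:
        return len(self.layers)


def build_dbn(input_dim: int, hidden_size: int, n_hidden_layers: int = 3,
              seed: int = 0, weight_init_sd: float = 0.01) -> DBNModel:
    """Untrained stack: input_dim -> hidden_size x n_hidden_layers."""
    if input_dim < 1 or hidden_size < 1 or n_hidden_layers < 1:
        raise ValidationError("input_dim, hidden_size and n_hidden_layers must be positive")
    rng = substream(seed, "dbn_init")
    layers = []
    n_v = input_dim
    for _ in range(n_hidden_layers):
        layers.append(init_params(n_v, hidden_size, weight_init_sd, rng))
        n_v = hidden_size
    return DBNModel(layers=layers, layer_sizes=[input_dim] + [hidden_size] * n_hidden_layers)


def pretrain(model: DBNModel, X: np.ndarray, config: SRTrainConfig) -> DBNModel:
    """Greedy layer-wise SR-RBM training.

    Layer t trains on the hidden activation probabilities of the trained
    layer t−1 (probabilities, not samples, so propagation is deterministic).
    Each layer gets its own seed substream derived from config.seed.
    """
    X = as_2d_float(X, "X")
    if X.shape[1] != model.layer_sizes[0]:
        raise ValidationError(
            f"X has {X.shape[1]} features, model input size is {model.layer_sizes[0]}"
        )
    layers, traces = [], []
    data = X
    for t, layer in enumerate(model.layers):
        cfg = replace(config, seed=int(substream(config.seed, "dbn_layer", t).integers(2 ** 31)))
        try:
            trace = train_srrbm(data, cfg, init=layer)
        except Exception as exc:
            raise RuntimeError(f"pretraining failed at layer {t}: {exc}") from exc
        layers.append(trace.params)
        traces.append(trace)
        data = hidden_probs(trace.params, data)
    return DBNModel(
        layers=layers,
        layer_sizes=list(model.layer_sizes),
        pretrained=True,
        pretrain_traces=traces,
    )


def _forward(model: DBNModel, X: np.ndarray) -> list:
    """Activations at every layer, input first."""
    acts = [X]
    for layer in model.layers:
        acts.append(hidden_probs(layer, acts[-1]))
    return acts


def _softmax(Z: np.ndarray) -> np.ndarray:
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def finetune(model: DBNModel, X: np.ndarray, labels, lr: float = 0.1,
             epochs: int = 100, seed: int = 0) -> DBNModel:
    """Supervised backpropagation through the whole stack.

    Attaches a softmax head to the top hidden layer, then runs full-batch
    gradient descent on the mean cross-entropy of the training labels,
    updating every layer's weights and hidden biases plus the head.  With
    lr=0 the parameters are provably unchanged.  The head is retained for
    diagnostics only; downstream classification uses the ELM.
    """
    X = as_2d_float(X, "X")
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != (X.shape[0],):
        raise ValidationError("labels must align with rows of X")
    if lr < 0:
        raise ValidationError("lr must be nonnegative")
    n_classes = int(labels.max()) + 1
    n = X.shape[0]
    T = np.zeros((n, n_classes))
    T[np.arange(n), labels] = 1.0

    rng = substream(seed, "finetune_head")
    model = DBNModel(
        layers=[l.copy() for l in model.layers],
        layer_sizes=list(model.layer_sizes),
        pretrained=model.pretrained,
        pretrain_traces=model.pretrain_traces,
    )
    top = model.layer_sizes[-1]
    head_W = rng.normal(0.0, 0.01, size=(top, n_classes))
    head_b = np.zeros(n_classes)

    losses = []
    for epoch in range(epochs):
        acts = _forward(model, X)
        logits = acts[-1] @ head_W + head_b
        P = _softmax(logits)
        loss = float(-np.mean(np.sum(T * np.log(P + 1e-300), axis=1)))
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite fine-tuning loss at epoch {epoch}")
        losses.append(loss)
        if lr == 0.0:
            continue
        delta = (P - T) / n                       # d loss / d logits
        g_head_W = acts[-1].T @ delta
        g_head_b = delta.sum(axis=0)
        grad = delta @ head_W.T                   # into top hidden activations
        for t in range(len(model.layers) - 1, -1, -1):
            a = acts[t + 1]
            pre = grad * a * (1.0 - a)            # through sigmoid
            gW = acts[t].T @ pre
            gb = pre.sum(axis=0)
            grad = pre @ model.layers[t].W.T
            model.layers[t] = RBMParams(
                model.layers[t].W - lr * gW,
                model.layers[t].c_vis,
                model.layers[t].b_hid - lr * gb,
            )
        head_W -= lr * g_head_W
        head_b -= lr * g_head_b

    model.head_W, model.head_b = head_W, head_b
    model.finetuned = lr > 0.0
    model.finetune_loss = losses
    return model


def extract_features(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Deterministic top-layer features: sigmoid forward pass, no sampling."""
    X = as_2d_float(X, "X")
    if X.shape[1] != model.layer_sizes[0]:
        raise ValidationError(
            f"X has {X.shape[1]} features, model input size is {model.layer_sizes[0]}"
        )
    return _forward(model, X)[-1]
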