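"""Extreme learning machine classifier.

A single-hidden-layer feedforward network in which the input-to-hidden
weights A and hidden biases d are drawn once, uniformly on [-1, 1], and
never trained.  With the hidden output matrix H = sigmoid(X·A + d) fixed,
the output weights are the closed-form minimum-norm least-squares solution

    β̂ = H⁺ T

where H⁺ is the Moore–Penrose pseudoinverse and T the one-hot target
matrix.  Prediction is arg-max of the scores H·β̂; for binary tasks the
positive-class column of the scores serves as the continuous ROC score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

from ._utils import StateError, ValidationError, as_2d_float, sigmoid, substream

__all__ = ["ELMModel", "init_elm", "hidden_matrix", "fit_elm", "predict"]

RCOND = 1e-10  # relative singular-value cutoff for the pseudoinverse


@dataclass
class ELMModel:
    A: np.ndarray                 # (input_dim, L) fixed random input weights
    d_bias: np.ndarray            # (L,) fixed random hidden biases
    L: int
    seed: int
    beta: np.ndarray | None = None        # (L, n_classes) learned output weights
    class_names: list = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.A.shape[0]

    @property
    def fitted(self) -> bool:
        return self.beta is not None


def init_elm(input_dim: int, L: int, seed: int) -> ELMModel:
    """Draw the fixed random hidden layer: A, d ~ Uniform[-1, 1]."""
    if input_dim < 1 or L < 1:
        raise ValidationError(f"input_dim and L must be positive, got {input_dim}, {L}")
    rng = substream(seed, "elm")
    A = rng.uniform(-1.0, 1.0, size=(input_dim, L))
    d = rng.uniform(-1.0, 1.0, size=L)
    return ELMModel(A=A, d_bias=d, L=L, seed=seed)


def hidden_matrix(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """H = sigmoid(X·A + d), one row per sample."""
    X = as_2d_float(X, "X")
    if X.shape[1] != model.input_dim:
        raise ValidationError(
            f"X has {X.shape[1]} features, model expects {model.input_dim}"
        )
    return sigmoid(X @ model.A + model.d_bias)


def fit_elm(model: ELMModel, X: np.ndarray, labels: Sequence[int],
            class_names: Sequence | None = None) -> ELMModel:
    """Solve β̂ = H⁺T for one-hot targets T (1 for the true class, else 0).

    The pseudoinverse is computed by SVD with singular values below
    RCOND·σ_max truncated, giving the minimum-norm least-squares solution.
    """
    X = as_2d_float(X, "X")
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape != (X.shape[0],):
        raise ValidationError("labels must align one-to-one with rows of X")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes to fit a classifier")
    n_classes = int(classes.max()) + 1

    H = hidden_matrix(model, X)
    if H.shape[0] > 1 and np.allclose(H, H[0], atol=1e-12):
        logger.warning("degenerate hidden output matrix H (all rows identical); "
                       "fitting the minimum-norm solution anyway")
    T = np.zeros((X.shape[0], n_classes))
    T[np.arange(X.shape[0]), labels] = 1.0
    beta = np.linalg.pinv(H, rcond=RCOND) @ T
    model.beta = beta
    model.class_names = list(class_names) if class_names is not None else list(range(n_classes))
    return model


def predict(model: ELMModel, X: np.ndarray, positive_class: int | None = None):
    """Arg-max classification plus per-class scores.

    Ties break toward the lowest class code (np.argmax convention).  When
    ``positive_class`` is given, the returned ``roc_score`` is that class's
    raw score column, suitable for ROC analysis.
    """
    if not model.fitted:
        raise StateError("ELM model is not fitted")
    scores = hidden_matrix(model, X) @ model.beta
    pred = np.argmax(scores, axis=1)
    if positive_class is None:
        return pred, scores
    return pred, scores, scores[:, positive_class]
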