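"""Sparse-response restricted Boltzmann machines.

An RBM is a two-layer undirected energy model over binary visible units
``v`` and hidden units ``h`` with energy

    E(v, h) = - v' W h - c' v - b' h

so that ``p(v, h) ∝ exp(-E(v, h))``.  Here ``c`` is the visible bias and
``b`` the hidden bias.  Real-valued inputs in [0, 1] (e.g. normalized image
intensities) are treated as Bernoulli activation probabilities.

Learning is one-step contrastive divergence (CD-1): the intractable
model-distribution expectations in the log-likelihood gradient are replaced
by statistics after one Gibbs step started at the data.  The
"sparse-response" variant adds, after every CD update, a second additive
step along the negative gradient of an L1 penalty on the hidden conditional
activation probabilities, Σ_l ||p(h | v^(l))||_1, scaled by ε·λ.  This
drives hidden units toward low average activation, which yields sparser,
more information-efficient codes.

The module also provides exhaustive-enumeration oracles
(:func:`exact_model_statistics`) usable on tiny models to validate the
sampling-based statistics against the exact equilibrium distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from ._utils import ValidationError, as_2d_float, sigmoid, substream

__all__ = [
    "RBMParams",
    "SRTrainConfig",
    "TrainTrace",
    "init_params",
    "hidden_probs",
    "visible_probs",
    "sample_bernoulli",
    "cd_statistics",
    "cd1_update",
    "sparsity_gradient",
    "train_srrbm",
    "exact_model_statistics",
]


@dataclass
class RBMParams:
    """Weights and biases of one (SR-)RBM.

    W has shape (n_visible, n_hidden); ``c_vis`` is the visible-layer bias,
    ``b_hid`` the hidden-layer bias.
    """

    W: np.ndarray
    c_vis: np.ndarray
    b_hid: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        self.c_vis = np.asarray(self.c_vis, dtype=np.float64)
        self.b_hid = np.asarray(self.b_hid, dtype=np.float64)
        if self.W.ndim != 2:
            raise ValidationError(f"W must be 2-D, got shape {self.W.shape}")
        nv, nh = self.W.shape
        if self.c_vis.shape != (nv,):
            raise ValidationError(
                f"c_vis shape {self.c_vis.shape} inconsistent with W {self.W.shape}"
            )
        if self.b_hid.shape != (nh,):
            raise ValidationError(
                f"b_hid shape {self.b_hid.shape} inconsistent with W {self.W.shape}"
            )
        for name, a in (("W", self.W), ("c_vis", self.c_vis), ("b_hid", self.b_hid)):
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"{name} contains non-finite entries")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.c_vis.copy(), self.b_hid.copy())


@dataclass(frozen=True)
class SRTrainConfig:
    """Hyperparameters of sparse-response CD training.

    epsilon : learning rate ε of the CD update.
    lam     : sparsity weight λ of the L1 activation penalty (0 disables it,
              recovering plain CD-1).
    cd_steps: Gibbs steps k per update (1 in the canonical setting).
    """

    epsilon: float = 0.05
    lam: float = 0.1
    cd_steps: int = 1
    epochs: int = 30
    batch_size: int = 16
    weight_init_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValidationError(f"epsilon must be > 0, got {self.epsilon}")
        if self.lam < 0:
            raise ValidationError(f"lam must be >= 0, got {self.lam}")
        if self.cd_steps < 1:
            raise ValidationError(f"cd_steps must be >= 1, got {self.cd_steps}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be positive")
        if not self.weight_init_sd > 0:
            raise ValidationError("weight_init_sd must be positive")


@dataclass
class TrainTrace:
    """Per-epoch training monitors plus the final parameters."""

    reconstruction_error: List[float] = field(default_factory=list)
    mean_hidden_activation: List[float] = field(default_factory=list)
    params: RBMParams | None = None


def init_params(n_visible: int, n_hidden: int, weight_init_sd: float, rng: np.random.Generator) -> RBMParams:
    """Small Gaussian weights, zero biases — the standard CD starting point."""
    if n_visible < 1 or n_hidden < 1:
        raise ValidationError("layer sizes must be positive")
    W = rng.normal(0.0, weight_init_sd, size=(n_visible, n_hidden))
    return RBMParams(W, np.zeros(n_visible), np.zeros(n_hidden))


def hidden_probs(params: RBMParams, V: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) = sigmoid(Σ_i v_i w_ij + b_j), row-wise over a batch."""
    V = as_2d_float(V, "V")
    if V.shape[1] != params.n_visible:
        raise ValidationError(
            f"V has {V.shape[1]} columns, expected n_visible={params.n_visible}"
        )
    return sigmoid(V @ params.W + params.b_hid)


def visible_probs(params: RBMParams, H: np.ndarray) -> np.ndarray:
    """p(v_i = 1 | h) = sigmoid(Σ_j h_j w_ij + c_i), row-wise over a batch."""
    H = as_2d_float(H, "H")
    if H.shape[1] != params.n_hidden:
        raise ValidationError(
            f"H has {H.shape[1]} columns, expected n_hidden={params.n_hidden}"
        )
    return sigmoid(H @ params.W.T + params.c_vis)


def sample_bernoulli(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli draws from a probability matrix."""
    P = np.asarray(P, dtype=np.float64)
    if P.size and (P.min() < 0.0 or P.max() > 1.0):
        raise ValidationError("probabilities must lie in [0, 1]")
    return (rng.random(P.shape) < P).astype(np.float64)


def cd_statistics(params: RBMParams, V: np.ndarray, k: int, rng: np.random.Generator):
    """Positive- and negative-phase sufficient statistics for CD-k.

    The positive phase pairs the data with hidden *probabilities*.  The
    negative phase runs k alternating Gibbs steps (both layers sampled, so
    the chain's stationary law is the RBM's equilibrium distribution) and
    reads off Rao-Blackwellized statistics at the final step: the visible
    moment uses the reconstruction probabilities given the last hidden
    sample, and the pair/hidden moments use the hidden probabilities given
    the last visible sample.  Each estimator is conditionally exact in one
    layer, so the negative statistics converge to the exact model
    expectations as k grows.  All statistics are batch averages.

    Returns a dict with keys pos_vh, pos_v, pos_h, neg_vh, neg_v, neg_h.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    V = as_2d_float(V, "V")
    m = V.shape[0]
    P_h0 = hidden_probs(params, V)
    H = sample_bernoulli(P_h0, rng)
    for t in range(k):
        P_v = visible_probs(params, H)
        V_neg = sample_bernoulli(P_v, rng)
        P_h = hidden_probs(params, V_neg)
        if t < k - 1:
            H = sample_bernoulli(P_h, rng)
    stats = {
        "pos_vh": V.T @ P_h0 / m,
        "pos_v": V.mean(axis=0),
        "pos_h": P_h0.mean(axis=0),
        "neg_vh": V_neg.T @ P_h / m,
        "neg_v": P_v.mean(axis=0),
        "neg_h": P_h.mean(axis=0),
    }
    return stats


def cd1_update(params: RBMParams, batch: np.ndarray, config: SRTrainConfig,
               rng: np.random.Generator, stats: dict | None = None) -> RBMParams:
    """One contrastive-divergence parameter update.

        w_ij += ε (⟨v_i h_j⟩_data − ⟨v_i h_j⟩_recon)
        c_i  += ε (⟨v_i⟩_data − ⟨v_i⟩_recon)
        b_j  += ε (⟨h_j⟩_data − ⟨h_j⟩_recon)

    ``stats`` may inject precomputed statistics (used by tests to verify the
    fixed point where positive and negative phases coincide).
    """
    batch = as_2d_float(batch, "batch")
    if batch.shape[0] == 0:
        raise ValidationError("batch must be nonempty")
    if stats is None:
        stats = cd_statistics(params, batch, config.cd_steps, rng)
    eps = config.epsilon
    return RBMParams(
        params.W + eps * (stats["pos_vh"] - stats["neg_vh"]),
        params.c_vis + eps * (stats["pos_v"] - stats["neg_v"]),
        params.b_hid + eps * (stats["pos_h"] - stats["neg_h"]),
    )


def sparsity_gradient(params: RBMParams, batch: np.ndarray):
    """Negative gradient of the L1 activation penalty Σ_l ||p(h|v^(l))||_1.

    Returns ``(gW, gb)`` summed over the batch:

        gW[i, j] = − Σ_l p_j(l) (1 − p_j(l)) v_i(l)
        gb[j]    = − Σ_l p_j(l) (1 − p_j(l))

    with p_j(l) = sigmoid(Σ_i v_i(l) w_ij + b_j).  The visible bias receives
    no contribution because the penalty does not depend on it.
    """
    batch = as_2d_float(batch, "batch")
    if batch.shape[0] == 0:
        raise ValidationError("batch must be nonempty")
    P = hidden_probs(params, batch)
    S = P * (1.0 - P)
    gW = -(batch.T @ S)
    gb = -S.sum(axis=0)
    return gW, gb


def _reconstruction_error(params: RBMParams, V: np.ndarray) -> float:
    """Mean squared difference between data and 1-step mean-field reconstruction."""
    P_h = hidden_probs(params, V)
    V_rec = visible_probs(params, P_h)
    return float(np.mean((V - V_rec) ** 2))


def train_srrbm(X: np.ndarray, config: SRTrainConfig,
                n_hidden: int | None = None,
                init: RBMParams | None = None) -> TrainTrace:
    """Train one sparse-response RBM by CD-k plus the sparsity step.

    Each mini-batch applies the CD update, then a second additive step
    ε·λ·(negative sparsity gradient).  With λ=0 this is exactly plain CD
    training.  The trace records, per epoch, the mean squared 1-step
    reconstruction error and the mean hidden activation probability over the
    full dataset.
    """
    X = as_2d_float(X, "X")
    if X.shape[0] == 0:
        raise ValidationError("X must be nonempty")
    if X.min() < 0.0 or X.max() > 1.0:
        raise ValidationError("X values must lie in [0, 1]")
    if n_hidden is None and init is None:
        raise ValidationError("provide n_hidden or an initial RBMParams")

    rng = substream(config.seed, "srrbm")
    params = init.copy() if init is not None else init_params(
        X.shape[1], n_hidden, config.weight_init_sd, rng
    )

    n = X.shape[0]
    trace = TrainTrace()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = X[order[start:start + config.batch_size]]
            params = cd1_update(params, batch, config, rng)
            if config.lam > 0.0:
                gW, gb = sparsity_gradient(params, batch)
                params = RBMParams(
                    params.W + config.epsilon * config.lam * gW,
                    params.c_vis,
                    params.b_hid + config.epsilon * config.lam * gb,
                )
            if not (np.all(np.isfinite(params.W))
                    and np.all(np.isfinite(params.c_vis))
                    and np.all(np.isfinite(params.b_hid))):
                raise FloatingPointError(
                    f"non-finite RBM parameters at epoch {epoch}, batch offset {start}"
                )
        trace.reconstruction_error.append(_reconstruction_error(params, X))
        trace.mean_hidden_activation.append(float(hidden_probs(params, X).mean()))
    trace.params = params
    return trace


def exact_model_statistics(params: RBMParams):
    """Exact equilibrium expectations for a tiny RBM, by enumeration.

    Enumerates all 2^n_v visible configurations and marginalizes the hidden
    layer analytically: the unnormalized visible marginal is

        p*(v) = exp(c'v) Π_j (1 + exp(b_j + v'W_:j))

    and E[h_j | v] = sigmoid(b_j + v'W_:j), which together give every
    first- and second-order moment exactly.  Returns a dict with vh, v, h
    and log_Z.  Limited to n_v + n_h <= 20 units.
    """
    nv, nh = params.n_visible, params.n_hidden
    if nv + nh > 20:
        raise ValidationError(f"model too large for enumeration: {nv}+{nh} > 20 units")
    # all visible configurations as a (2^nv, nv) binary matrix
    V = ((np.arange(2 ** nv)[:, None] >> np.arange(nv)[None, :]) & 1).astype(np.float64)
    act = V @ params.W + params.b_hid            # (2^nv, nh)
    # log p*(v) = c'v + Σ_j log(1 + e^{act_j})
    log_pstar = V @ params.c_vis + np.logaddexp(0.0, act).sum(axis=1)
    log_Z = float(np.logaddexp.reduce(log_pstar))
    p_v = np.exp(log_pstar - log_Z)
    Eh_given_v = sigmoid(act)
    return {
        "vh": (V * p_v[:, None]).T @ Eh_given_v,
        "v": p_v @ V,
        "h": p_v @ Eh_given_v,
        "log_Z": log_Z,
    }
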