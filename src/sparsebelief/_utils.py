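"""Shared helpers: validation errors, sigmoid, seeded RNG substreams."""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class StateError(RuntimeError):
    """Raised when an operation is called on a model in the wrong state."""


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def as_2d_float(X, name: str = "X") -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError(f"{name} must be 2-D, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValidationError(f"{name} contains non-finite values")
    return X


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Deterministic named RNG substream derived from a master seed.

    Keys (strings or ints) are hashed into the entropy pool so that, e.g.,
    the per-modality, per-class streams of the synthetic generator and the
    per-repeat streams of the CV harness never collide.
    """
    ints = []
    for k in keys:
        if isinstance(k, str):
            ints.extend(k.encode("utf-8"))
        else:
            ints.append(int(k) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *ints]))
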