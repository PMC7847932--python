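import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sparsebelief.srrbm import RBMParams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_rbm():
    """4+3-unit RBM with seeded N(0, 0.5) parameters, small enough to enumerate."""
    rng = np.random.default_rng(123)
    return RBMParams(
        rng.normal(0, 0.5, (4, 3)), rng.normal(0, 0.5, 4), rng.normal(0, 0.5, 3)
    )


def enumerate_joint_statistics(params):
    """Brute-force oracle: sum over every joint (v, h) configuration.

    Independent of the package's analytic-marginalization implementation;
    builds the full 2^(n_v+n_h) Boltzmann distribution explicitly.
    """
    nv, nh = params.n_visible, params.n_hidden
    vh_sum = np.zeros((nv, nh))
    v_sum = np.zeros(nv)
    h_sum = np.zeros(nh)
    weights = []
    configs = []
    for code in range(2 ** (nv + nh)):
        bits = [(code >> i) & 1 for i in range(nv + nh)]
        v = np.array(bits[:nv], dtype=float)
        h = np.array(bits[nv:], dtype=float)
        energy = -(v @ params.W @ h + params.c_vis @ v + params.b_hid @ h)
        weights.append(np.exp(-energy))
        configs.append((v, h))
    Z = sum(weights)
    for w, (v, h) in zip(weights, configs):
        p = w / Z
        vh_sum += p * np.outer(v, h)
        v_sum += p * v
        h_sum += p * h
    return {"vh": vh_sum, "v": v_sum, "h": h_sum, "log_Z": float(np.log(Z))}
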