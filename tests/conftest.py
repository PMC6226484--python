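"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the package's eigendecomposition/renormalization
code path: likelihoods are computed by direct matrix products with SciPy's
scaling-and-squaring ``expm``, and Viterbi paths by exhaustive enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from tcphoton import (
    BlinkParams,
    TCParams,
    TwoStateParams,
    make_four_state,
    make_six_state_tc,
    make_three_state_tc,
    make_two_state,
)


# ---------------------------------------------------------------------------
# oracles

def oracle_loglik(times, colors, K, E, v_ini, v_fin):
    """Brute-force likelihood: explicit expm per interval, direct products."""
    E = np.asarray(E, dtype=float)
    F = {1: np.diag(E), 0: np.eye(E.size) - np.diag(E)}
    v = F[int(colors[0])] @ np.asarray(v_ini, dtype=float)
    for i in range(1, len(colors)):
        tau = times[i] - times[i - 1]
        v = F[int(colors[i])] @ (expm(K * tau) @ v)
    val = float(np.asarray(v_fin, dtype=float) @ v)
    return np.log(val) if val > 0 else -np.inf


def oracle_viterbi(times, colors, K, E, p_eq):
    """Exhaustive max-product path over all state sequences."""
    n = K.shape[0]
    N = len(colors)
    E = np.asarray(E, dtype=float)
    f = np.where(np.asarray(colors)[:, None] == 1, E[None, :], 1 - E[None, :])
    Ps = [expm(K * (times[i] - times[i - 1])) for i in range(1, N)]
    best_score, best_path = -np.inf, None
    for seq in itertools.product(range(n), repeat=N):
        s = np.log(p_eq[seq[0]]) + np.log(f[0, seq[0]])
        for i in range(1, N):
            s += np.log(Ps[i - 1][seq[i], seq[i - 1]]) + np.log(f[i, seq[i]])
        if s > best_score:
            best_score, best_path = s, seq
    return np.array(best_path), best_score


def random_trajectory(rng, n_photons, duration=1e-3):
    times = np.sort(rng.uniform(0.0, duration, n_photons))
    while np.any(np.diff(times) <= 0):  # pragma: no cover
        times = np.sort(rng.uniform(0.0, duration, n_photons))
    colors = rng.integers(0, 2, n_photons).astype(np.int8)
    return times, colors


def random_two(rng) -> TwoStateParams:
    e_u = rng.uniform(0.02, 0.45)
    e_b = rng.uniform(e_u + 0.1, 0.95)
    return TwoStateParams(
        E_B=e_b, E_U=e_u,
        k_A_app=rng.uniform(10, 1000), k_D=rng.uniform(10, 1000),
    )


def random_blink(rng) -> BlinkParams:
    return BlinkParams(
        E_d=rng.uniform(0.0, 0.15),
        k_b=rng.uniform(500, 10000),
        k_0=rng.uniform(50, 2000),
    )


def random_tc(rng) -> TCParams:
    return TCParams.from_lifetime(
        rng.uniform(2e-6, 1e-3), rng.uniform(0.1, 0.9)
    )


def random_model(rng, kind: str):
    two = random_two(rng)
    if kind == "two":
        return make_two_state(two)
    if kind == "four":
        return make_four_state(two, random_blink(rng), rng.uniform(50, 900))
    if kind == "three":
        return make_three_state_tc(two, random_tc(rng))
    if kind == "six":
        return make_six_state_tc(two, random_tc(rng), random_blink(rng), rng.uniform(50, 900))
    raise ValueError(kind)


MODEL_KINDS = ("two", "four", "three", "six")


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def idp_two():
    """TAD/NCBD-like two-state parameters."""
    return TwoStateParams(E_B=0.6, E_U=0.25, k_A_app=300.0, k_D=100.0)


@pytest.fixture(scope="session")
def folded_two():
    """Barnase/barstar-like two-state parameters (donor-leak unbound state)."""
    return TwoStateParams(E_B=0.75, E_U=0.06, k_A_app=30.0, k_D=10.0)
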