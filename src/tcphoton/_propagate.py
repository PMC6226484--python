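"""Low-level photon-stream propagation kernels.

The likelihood of a photon trajectory is a product of alternating photon-color
and interval-propagation factors. The propagation ``exp(K tau)`` is evaluated
through a one-off eigendecomposition of the rate matrix; the per-photon loop
renormalizes the state vector to unit sum and accumulates the log norm so that
trajectories with 1e6+ photons do not underflow.

Rate matrices here are Kronecker sums of birth-death chains, so their spectra
are real; a scaling-and-squaring fallback covers near-defective cases.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


NEG_INF = float("-inf")

#: eigenvector condition number above which the eigendecomposition is not trusted
_COND_LIMIT = 1e8


class Decomposition:
    """Cached spectral factorization K = V diag(lam) V^-1 plus emission data."""

    __slots__ = ("lam", "V", "Vinv", "E", "K", "ok")

    def __init__(self, K: np.ndarray, E_diag: np.ndarray):
        self.K = np.asarray(K, dtype=float)
        self.E = np.asarray(E_diag, dtype=float)
        lam, V = np.linalg.eig(self.K)
        ok = True
        if np.abs(lam.imag).max() > 1e-9 * (np.abs(lam.real).max() + 1.0):
            ok = False
        try:
            cond = np.linalg.cond(V)
        except np.linalg.LinAlgError:  # pragma: no cover
            cond = np.inf
        if not np.isfinite(cond) or cond > _COND_LIMIT:
            ok = False
        self.ok = ok
        if ok:
            self.lam = lam.real.copy()
            self.V = V.real.copy()
            self.Vinv = np.linalg.inv(V).real.copy()
        else:  # pragma: no cover - guarded fallback
            self.lam = self.V = self.Vinv = None


_DECOMP_CACHE: dict[bytes, Decomposition] = {}


def get_decomposition(model) -> Decomposition:
    key = model.K.tobytes() + model.E_diag.tobytes()
    dec = _DECOMP_CACHE.get(key)
    if dec is None:
        dec = Decomposition(model.K, model.E_diag)
        if len(_DECOMP_CACHE) > 4096:
            _DECOMP_CACHE.clear()
        _DECOMP_CACHE[key] = dec
    return dec


@njit(cache=True)
def _ll_kernel(taus, colors, V, Vinv, lam, E, v_ini, v_fin):  # pragma: no cover - jit
    n = lam.shape[0]
    N = colors.shape[0]
    v = np.empty(n)
    # first photon: emission factor applied to the initial vector
    for j in range(n):
        f = E[j] if colors[0] == 1 else 1.0 - E[j]
        v[j] = f * v_ini[j]
    s = 0.0
    for j in range(n):
        s += v[j]
    if s <= 0.0:
        return NEG_INF
    lnL = np.log(s)
    for j in range(n):
        v[j] /= s
    w = np.empty(n)
    for i in range(1, N):
        tau = taus[i - 1]
        # w = exp(lam*tau) * (Vinv @ v)
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += Vinv[j, k] * v[k]
            w[j] = acc * np.exp(lam[j] * tau)
        # v = F(c_i) @ (V @ w), clipping round-off negatives
        s = 0.0
        for j in range(n):
            acc = 0.0
            for k in range(n):
                acc += V[j, k] * w[k]
            if acc < 0.0:
                acc = 0.0
            f = E[j] if colors[i] == 1 else 1.0 - E[j]
            acc *= f
            v[j] = acc
            s += acc
        if s <= 0.0:
            return NEG_INF
        lnL += np.log(s)
        for j in range(n):
            v[j] /= s
    s = 0.0
    for j in range(n):
        s += v_fin[j] * v[j]
    if s <= 0.0:
        return NEG_INF
    return lnL + np.log(s)


def _ll_expm(taus, colors, K, E, v_ini, v_fin):
    """Slow scaling-and-squaring fallback with the same renormalization."""
    n = K.shape[0]
    F_a = E
    F_d = 1.0 - E
    v = (F_a if colors[0] == 1 else F_d) * v_ini
    s = v.sum()
    if s <= 0:
        return NEG_INF
    lnL = np.log(s)
    v /= s
    for i in range(1, len(colors)):
        P = expm(K * taus[i - 1])
        v = P @ v
        np.clip(v, 0.0, None, out=v)
        v = (F_a if colors[i] == 1 else F_d) * v
        s = v.sum()
        if s <= 0:
            return NEG_INF
        lnL += np.log(s)
        v /= s
    s = float(v_fin @ v)
    if s <= 0:
        return NEG_INF
    return lnL + np.log(s)


def propagate_loglik(times, colors, dec: Decomposition, v_ini, v_fin) -> float:
    """ln of v_fin^T prod_i [F(c_i) exp(K tau_i)] F(c_1) v_ini."""
    times = np.ascontiguousarray(times, dtype=np.float64)
    colors = np.ascontiguousarray(colors, dtype=np.int8)
    v_ini = np.ascontiguousarray(v_ini, dtype=np.float64)
    v_fin = np.ascontiguousarray(v_fin, dtype=np.float64)
    if colors.size == 0:
        return 0.0
    taus = np.diff(times)
    if dec.ok:
        return float(_ll_kernel(taus, colors, dec.V, dec.Vinv, dec.lam, dec.E, v_ini, v_fin))
    return float(_ll_expm(taus, colors, dec.K, dec.E, v_ini, v_fin))


@njit(cache=True)
def _viterbi_kernel(taus, colors, V, Vinv, lam, E, log_p_ini):  # pragma: no cover - jit
    n = lam.shape[0]
    N = colors.shape[0]
    TINY = 1e-300
    delta = np.empty(n)
    for j in range(n):
        f = E[j] if colors[0] == 1 else 1.0 - E[j]
        delta[j] = log_p_ini[j] + (np.log(f) if f > 0.0 else -1e308)
    back = np.zeros((N, n), dtype=np.int32)
    P = np.empty((n, n))
    work = np.empty(n)
    for i in range(1, N):
        tau = taus[i - 1]
        # P = V diag(exp(lam tau)) Vinv, clipped to a positive floor
        for j in range(n):
            work[j] = np.exp(lam[j] * tau)
        for r in range(n):
            for c in range(n):
                acc = 0.0
                for k in range(n):
                    acc += V[r, k] * work[k] * Vinv[k, c]
                if acc < TINY:
                    acc = TINY
                P[r, c] = acc
        new_delta = np.empty(n)
        for j in range(n):
            best = -1e308
            arg = 0
            for k in range(n):
                cand = delta[k] + np.log(P[j, k])
                if cand > best:
                    best = cand
                    arg = k
            f = E[j] if colors[i] == 1 else 1.0 - E[j]
            new_delta[j] = best + (np.log(f) if f > 0.0 else -1e308)
            back[i, j] = arg
        delta = new_delta
    # argmax with ties toward the lower state index
    best = delta[0]
    arg = 0
    for j in range(1, n):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path = np.empty(N, dtype=np.int32)
    path[N - 1] = arg
    for i in range(N - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path, best


def viterbi_decode(times, colors, dec: Decomposition, p_ini):
    """Most probable state sequence (max-product in log space)."""
    times = np.ascontiguousarray(times, dtype=np.float64)
    colors = np.ascontiguousarray(colors, dtype=np.int8)
    taus = np.diff(times)
    log_p = np.where(p_ini > 0, np.log(np.clip(p_ini, 1e-300, None)), -1e308)
    if not dec.ok:  # pragma: no cover - guarded fallback
        raise np.linalg.LinAlgError("rate matrix not diagonalizable for Viterbi")
    path, score = _viterbi_kernel(taus, colors, dec.V, dec.Vinv, dec.lam, dec.E, log_p)
    if score <= -1e307:
        raise ValueError("Viterbi path has zero probability")
    return np.asarray(path), float(score)
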