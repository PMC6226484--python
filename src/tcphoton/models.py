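"""Kinetic models for two-state binding, acceptor blinking, and the
transient-complex (TC) intermediate.

All models are continuous-time Markov chains described by a rate matrix ``K``
(column convention: ``K[i, j]`` is the rate from state ``j`` to state ``i``,
columns sum to zero), a diagonal matrix of apparent FRET efficiencies, and the
equilibrium population vector ``p_eq``.

State ordering conventions (fixed):

* two-state: ``(B, U)``
* three-state: ``(B, TC, U)``
* four-state: ``(B, U, B_dark, U_dark)``
* six-state: ``(B, TC, U, B_dark, TC_dark, U_dark)``
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "TwoStateParams",
    "BlinkParams",
    "TCParams",
    "SchemeParams",
    "KineticModel",
    "make_two_state",
    "make_four_state",
    "make_four_state_direct",
    "make_three_state_tc",
    "make_six_state_tc",
    "make_six_state_direct",
    "association_rate_coefficient",
    "effective_kA",
    "params_to_dict",
    "params_from_dict",
    "load_params",
    "dump_params",
]

#: reference photon count rate (ms^-1) at which the bright->dark blinking
#: rate equals k_0
N0_REF_MS = 100.0

#: donor-leak apparent efficiency used for acceptor dark/bleached emission
DONOR_LEAK_E = 0.06


class ModelValidationError(ValueError):
    """Raised when model parameters violate their invariants."""


def _check_rate(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ModelValidationError(f"{name} must be a finite positive rate, got {value!r}")


def _check_eff(name: str, value: float) -> None:
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ModelValidationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of the two-state binding model.

    Attributes
    ----------
    E_B, E_U :
        Apparent FRET efficiencies of the bound and unbound states. ``E_U``
        may exceed ``E_B`` is *not* required to be below ``E_B`` (a folded
        donor-only pair has ``E_U`` near the donor leak).
    k_A_app :
        Apparent (pseudo-first-order) association rate in s^-1.
    k_D :
        Dissociation rate in s^-1.
    """

    E_B: float
    E_U: float
    k_A_app: float
    k_D: float

    def __post_init__(self) -> None:
        _check_eff("E_B", self.E_B)
        _check_eff("E_U", self.E_U)
        _check_rate("k_A_app", self.k_A_app)
        _check_rate("k_D", self.k_D)

    @property
    def p_B(self) -> float:
        """Equilibrium bound fraction k_A_app / (k_A_app + k_D)."""
        return self.k_A_app / (self.k_A_app + self.k_D)


@dataclass(frozen=True)
class BlinkParams:
    """Acceptor blinking parameters.

    ``k_b`` is the dark->bright recovery rate; the bright->dark rate scales
    linearly with the photon count rate, ``k_d = k_0 * (n / n_0)`` with the
    reference rate ``n_0`` fixed at 100 photons/ms.
    """

    E_d: float = DONOR_LEAK_E
    k_b: float = 3000.0
    k_0: float = 500.0
    n_0: float = N0_REF_MS

    def __post_init__(self) -> None:
        _check_eff("E_d", self.E_d)
        _check_rate("k_b", self.k_b)
        _check_rate("k_0", self.k_0)
        if self.n_0 != N0_REF_MS:
            raise ModelValidationError(f"n_0 is fixed at {N0_REF_MS} ms^-1")

    def k_d(self, n_ms: float) -> float:
        """Bright->dark rate (s^-1) at count rate ``n_ms`` (photons/ms)."""
        if n_ms <= 0:
            raise ModelValidationError(f"count rate must be positive, got {n_ms!r}")
        return self.k_0 * (n_ms / self.n_0)

    def p_b(self, n_ms: float) -> float:
        """Equilibrium acceptor-bright population at count rate ``n_ms``."""
        kd = self.k_d(n_ms)
        return self.k_b / (self.k_b + kd)


@dataclass(frozen=True)
class TCParams:
    """Transient-complex parameters.

    The TC exits to both neighbors with equal rate ``k_TC``; its lifetime is
    ``t_TC = 1 / (2 k_TC)``. In TC models the binding/dissociation rates are
    divided by ``rate_reduction`` (default 1000) to suppress unresolvable
    multiple transitions inside a single-transition segment.
    """

    k_TC: float
    E_TC: float
    rate_reduction: float = 1000.0

    def __post_init__(self) -> None:
        _check_rate("k_TC", self.k_TC)
        _check_eff("E_TC", self.E_TC)
        if not np.isfinite(self.rate_reduction) or self.rate_reduction < 1:
            raise ModelValidationError("rate_reduction must be >= 1")

    @property
    def t_TC(self) -> float:
        return 1.0 / (2.0 * self.k_TC)

    @classmethod
    def from_lifetime(cls, t_TC: float, E_TC: float, rate_reduction: float = 1000.0) -> "TCParams":
        if t_TC <= 0:
            raise ModelValidationError("t_TC must be positive")
        return cls(k_TC=1.0 / (2.0 * t_TC), E_TC=E_TC, rate_reduction=rate_reduction)


@dataclass(frozen=True)
class SchemeParams:
    """Rate coefficients of the two-step association scheme.

    ``k_plus`` (M^-1 s^-1) forms the TC, ``k_minus`` (s^-1) dissolves it, and
    ``k_f`` (s^-1) folds the disordered chain within the TC.
    """

    k_plus: float
    k_minus: float
    k_f: float

    def __post_init__(self) -> None:
        _check_rate("k_plus", self.k_plus)
        _check_rate("k_minus", self.k_minus)
        _check_rate("k_f", self.k_f)


@dataclass(frozen=True)
class KineticModel:
    """A continuous-time Markov model with per-state apparent efficiencies."""

    state_labels: tuple
    K: np.ndarray
    E_diag: np.ndarray
    p_eq: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        E = np.asarray(self.E_diag, dtype=float)
        n = K.shape[0]
        if K.shape != (n, n) or E.shape != (n,) or len(self.state_labels) != n:
            raise ModelValidationError("inconsistent model dimensions")
        off = K[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ModelValidationError("off-diagonal rate entries must be >= 0")
        scale = max(np.abs(K).max(), 1.0)
        if np.abs(K.sum(axis=0)).max() > 1e-12 * scale:
            raise ModelValidationError("columns of K must sum to zero")
        if np.any(E < 0) or np.any(E > 1):
            raise ModelValidationError("efficiencies must lie in [0, 1]")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "E_diag", E)
        p = self.p_eq
        if p is None:
            p = stationary_distribution(K)
        else:
            p = np.asarray(p, dtype=float)
            if p.shape != (n,) or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
                raise ModelValidationError("p_eq must be a probability vector")
            if np.linalg.norm(K @ p) > 1e-9 * scale:
                raise ModelValidationError("p_eq is not stationary for K")
        object.__setattr__(self, "p_eq", p)

    @property
    def n_states(self) -> int:
        return self.K.shape[0]


def stationary_distribution(K: np.ndarray) -> np.ndarray:
    """Normalized null vector of a rate matrix (columns sum to zero)."""
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    # replace one balance equation with the normalization constraint
    A = np.vstack([K[:-1], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    p, *_ = np.linalg.lstsq(A, b, rcond=None)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def make_two_state(params: TwoStateParams) -> KineticModel:
    """Two-state binding model, state order (B, U)."""
    kA, kD = params.k_A_app, params.k_D
    K = np.array([[-kD, kA], [kD, -kA]])
    pB = params.p_B
    return KineticModel(
        state_labels=("B", "U"),
        K=K,
        E_diag=np.array([params.E_B, params.E_U]),
        p_eq=np.array([pB, 1.0 - pB]),
    )


def make_four_state(two: TwoStateParams, blink: BlinkParams, n_ms: float) -> KineticModel:
    """Two-state binding with acceptor blinking; order (B, U, Bd, Ud).

    The bright->dark rate is tied to the trajectory count rate ``n_ms``
    (photons/ms) through ``k_d = k_0 * n / n_0``.
    """
    return make_four_state_direct(two, blink.E_d, blink.k_b, blink.k_d(n_ms))


def make_four_state_direct(
    two: TwoStateParams, E_d: float, k_b: float, k_d: float
) -> KineticModel:
    """Four-state model with an explicitly supplied bright->dark rate."""
    _check_eff("E_d", E_d)
    _check_rate("k_b", k_b)
    _check_rate("k_d", k_d)
    kA, kD = two.k_A_app, two.k_D
    kb, kd = k_b, k_d
    K = np.array(
        [
            [-kD - kd, kA, kb, 0.0],
            [kD, -kA - kd, 0.0, kb],
            [kd, 0.0, -kD - kb, kA],
            [0.0, kd, kD, -kA - kb],
        ]
    )
    pB = two.p_B
    pb = kb / (kb + kd)
    p_eq = np.array([pB * pb, (1 - pB) * pb, pB * (1 - pb), (1 - pB) * (1 - pb)])
    E = np.array([two.E_B, two.E_U, E_d, E_d])
    return KineticModel(("B", "U", "Bd", "Ud"), K, E, p_eq)


def make_three_state_tc(two: TwoStateParams, tc: TCParams) -> KineticModel:
    """Three-state model (B, TC, U) with reduced binding rates.

    The TC exits to both neighbors at the same rate ``k_TC``; the slow
    binding/dissociation rates are ``k_D' = k_D / rate_reduction`` and
    ``k_A_app' = k_A_app / rate_reduction``.
    """
    kDp = two.k_D / tc.rate_reduction
    kAp = two.k_A_app / tc.rate_reduction
    kt = tc.k_TC
    K = np.array(
        [
            [-kDp, kt, 0.0],
            [kDp, -2 * kt, kAp],
            [0.0, kt, -kAp],
        ]
    )
    E = np.array([two.E_B, tc.E_TC, two.E_U])
    return KineticModel(("B", "TC", "U"), K, E)


def make_six_state_tc(
    two: TwoStateParams, tc: TCParams, blink: BlinkParams, n_ms: float
) -> KineticModel:
    """Six-state model: (B, TC, U) in acceptor-bright and dark copies.

    Kinetic rates in the dark block equal those in the bright block; the dark
    states emit at the dark-state efficiency ``E_d``.
    """
    return make_six_state_direct(two, tc, blink.E_d, blink.k_b, blink.k_d(n_ms))


def make_six_state_direct(
    two: TwoStateParams, tc: TCParams, E_d: float, k_b: float, k_d: float
) -> KineticModel:
    """Six-state model with an explicitly supplied bright->dark rate."""
    _check_eff("E_d", E_d)
    _check_rate("k_b", k_b)
    _check_rate("k_d", k_d)
    bright = make_three_state_tc(two, tc)
    kb, kd = k_b, k_d
    K3 = bright.K
    I3 = np.eye(3)
    K = np.block([[K3 - kd * I3, kb * I3], [kd * I3, K3 - kb * I3]])
    pb = kb / (kb + kd)
    p3 = bright.p_eq
    p_eq = np.concatenate([pb * p3, (1 - pb) * p3])
    E = np.concatenate([bright.E_diag, np.full(3, E_d)])
    return KineticModel(("B", "TC", "U", "Bd", "TCd", "Ud"), K, E, p_eq)


def association_rate_coefficient(k_A_app: float, partner_conc: float) -> float:
    """Bimolecular association rate coefficient k_A = k_A_app / [partner].

    ``partner_conc`` is in molar; the result is in M^-1 s^-1.
    """
    if partner_conc <= 0 or not np.isfinite(partner_conc):
        raise ModelValidationError("partner concentration must be positive")
    if k_A_app < 0:
        raise ModelValidationError("k_A_app must be >= 0")
    return k_A_app / partner_conc


def effective_kA(scheme: SchemeParams) -> float:
    """Overall association rate coefficient k_+ k_f / (k_f + k_-)."""
    return scheme.k_plus * scheme.k_f / (scheme.k_f + scheme.k_minus)


# ---------------------------------------------------------------------------
# flat key-value (de)serialization

_PARAM_KEYS = {
    "two": ("E_B", "E_U", "k_A_app", "k_D"),
    "blink": ("E_d", "k_b", "k_0"),
    "tc": ("k_TC", "E_TC", "rate_reduction"),
}


def params_to_dict(
    two: TwoStateParams,
    blink: BlinkParams | None = None,
    tc: TCParams | None = None,
) -> dict:
    out = {k: getattr(two, k) for k in _PARAM_KEYS["two"]}
    if blink is not None:
        out.update({k: getattr(blink, k) for k in _PARAM_KEYS["blink"]})
    if tc is not None:
        out.update({k: getattr(tc, k) for k in _PARAM_KEYS["tc"]})
    return out


def params_from_dict(d: dict):
    """Inverse of :func:`params_to_dict`; returns (two, blink|None, tc|None)."""
    two = TwoStateParams(*(float(d[k]) for k in _PARAM_KEYS["two"]))
    blink = None
    if "k_b" in d:
        blink = BlinkParams(
            E_d=float(d.get("E_d", DONOR_LEAK_E)),
            k_b=float(d["k_b"]),
            k_0=float(d["k_0"]),
        )
    tc = None
    if "k_TC" in d:
        tc = TCParams(
            k_TC=float(d["k_TC"]),
            E_TC=float(d["E_TC"]),
            rate_reduction=float(d.get("rate_reduction", 1000.0)),
        )
    return two, blink, tc


def dump_params(path, two, blink=None, tc=None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(two, blink, tc), fh, sort_keys=False)


def load_params(path):
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))
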