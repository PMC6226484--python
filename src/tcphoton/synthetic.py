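"""Synthetic photon-trajectory generators.

Two complementary simulators:

* a full continuous-time Markov (Gillespie) simulator emitting Poisson photon
  streams colored by the state-dependent apparent FRET efficiency, with
  optional acceptor blinking, acceptor photobleaching (emission drops to the
  donor-leak efficiency permanently) and donor photobleaching (trajectory
  truncation);
* an interval-preserving recoloring simulator that keeps photon arrival times
  and redraws only the colors, inserting an exponentially distributed
  transient-complex region centered on a transition interval, then overlaying
  acceptor dark periods recolored at E = 0.06.

Random numbers are always drawn in a fixed order (state path, then photon
times, then colors) so seeds stay stable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .models import (
    DONOR_LEAK_E,
    BlinkParams,
    KineticModel,
    TCParams,
    TwoStateParams,
    make_four_state_direct,
    make_six_state_direct,
    make_three_state_tc,
    make_two_state,
)
from .segmentation import BINDING, DISSOCIATION, TransitionSegment
from .trajectory import PhotonTrajectory

__all__ = [
    "SimConfig",
    "simulate_ctmc_photons",
    "recolor_trajectory",
    "simulate_transition_segments",
    "generate_condition_series",
]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the CTMC photon simulator."""

    two: TwoStateParams
    tc: TCParams | None = None
    blink: BlinkParams | None = None
    rate_ms: float = 100.0  # photon count rate, photons per ms
    state_rates_ms: tuple | None = None  # optional per-kinetic-state rates
    duration_s: float = 1.0
    k_bleach_acceptor: float = 0.0
    #: acceptor rides on the binding partner (folded-pair experiments): a
    #: bleach darkens only the current bound dwell and every new binding
    #: brings a fresh acceptor. When False the acceptor sits on the
    #: immobilized molecule and bleaching is permanent.
    acceptor_on_partner: bool = False
    k_bleach_donor: float = 0.0
    n_traj: int = 1
    seed: int = 0
    label: str = "sim"

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.rate_ms < 0 or self.k_bleach_acceptor < 0 or self.k_bleach_donor < 0:
            raise ValueError("rates must be >= 0")

    def build_model(self) -> KineticModel:
        """Generative kinetic model (no rate reduction)."""
        if self.tc is not None:
            tc_gen = TCParams(self.tc.k_TC, self.tc.E_TC, rate_reduction=1.0)
            if self.blink is not None:
                return make_six_state_direct(
                    self.two, tc_gen, self.blink.E_d, self.blink.k_b,
                    self.blink.k_d(self.rate_ms),
                )
            return make_three_state_tc(self.two, tc_gen)
        if self.blink is not None:
            return make_four_state_direct(
                self.two, self.blink.E_d, self.blink.k_b, self.blink.k_d(self.rate_ms)
            )
        return make_two_state(self.two)


def _gillespie(K: np.ndarray, p0: np.ndarray, T: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Jump times and states of a CTMC on [0, T], starting from p0."""
    n = K.shape[0]
    exit_rates = -np.diag(K)
    s = int(rng.choice(n, p=p0 / p0.sum()))
    t = 0.0
    times = [0.0]
    states = [s]
    while True:
        r = exit_rates[s]
        if r <= 0:
            break
        t += rng.exponential(1.0 / r)
        if t >= T:
            break
        probs = K[:, s].copy()
        probs[s] = 0.0
        s = int(rng.choice(n, p=probs / r))
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=np.int32)


def simulate_ctmc_photons(cfg: SimConfig) -> list[PhotonTrajectory]:
    """Simulate photon trajectories from the configured kinetic model.

    Photons arrive as a homogeneous Poisson process (optionally thinned by
    per-state rates) and are colored acceptor with probability E(state); after
    the acceptor bleaches, emission continues at the donor-leak efficiency.
    """
    model = cfg.build_model()
    if cfg.rate_ms == 0:
        import warnings

        warnings.warn("zero photon count rate: empty trajectories")
        return [
            PhotonTrajectory(f"{cfg.label}-{j}", np.empty(0), np.empty(0, dtype=np.int8),
                             {"seed": cfg.seed, "condition": cfg.label})
            for j in range(cfg.n_traj)
        ]
    rate_s = cfg.rate_ms * 1e3
    state_rates = None
    if cfg.state_rates_ms is not None:
        state_rates = np.asarray(cfg.state_rates_ms, dtype=float) * 1e3
        if state_rates.shape != (model.n_states,):
            raise ValueError("state_rates_ms must match the model dimension")
        rate_s = state_rates.max()

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_traj)
    out = []
    for j, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        # 1) state path and bleach times
        t_dbleach = rng.exponential(1.0 / cfg.k_bleach_donor) if cfg.k_bleach_donor > 0 else np.inf
        t_ableach = (
            rng.exponential(1.0 / cfg.k_bleach_acceptor) if cfg.k_bleach_acceptor > 0 else np.inf
        )
        T = min(cfg.duration_s, t_dbleach)
        jump_t, jump_s = _gillespie(model.K, model.p_eq, T, rng)
        dark_windows: list[tuple[float, float]] = []
        if cfg.acceptor_on_partner and cfg.k_bleach_acceptor > 0:
            t_ableach = np.inf  # no permanent bleach; per-dwell darkening
            dark_windows = _per_dwell_bleach_windows(
                jump_t, jump_s, model, T, cfg.k_bleach_acceptor, rng
            )
        # 2) photon arrival times
        n_photons = rng.poisson(rate_s * T)
        times = np.sort(rng.uniform(0.0, T, n_photons))
        times = times[np.concatenate(([True], np.diff(times) > 0))]
        states = jump_s[np.searchsorted(jump_t, times, side="right") - 1]
        if state_rates is not None:
            keep = rng.random(times.size) < state_rates[states] / rate_s
            times, states = times[keep], states[keep]
        # 3) colors
        eff = model.E_diag[states].copy()
        eff[times >= t_ableach] = DONOR_LEAK_E
        for lo, hi in dark_windows:
            eff[(times >= lo) & (times < hi)] = DONOR_LEAK_E
        colors = (rng.random(times.size) < eff).astype(np.int8)
        meta = {
            "condition": cfg.label,
            "seed": cfg.seed,
            "traj_seed_index": j,
            "duration_s": float(T),
            "acceptor_bleach_s": float(t_ableach) if np.isfinite(t_ableach) else None,
            "truth": dataclasses.asdict(cfg.two),
        }
        out.append(PhotonTrajectory(f"{cfg.label}-{j}", times, colors, meta))
    return out


def _per_dwell_bleach_windows(jump_t, jump_s, model, T, k_bleach, rng):
    """Dark windows from per-binding-event acceptor bleaching.

    Within each bound dwell an independent bleach time ~ Exp(k_bleach) is
    drawn from the dwell start; the remainder of that dwell emits at the
    donor-leak efficiency. Rebinding brings a fresh (bright) acceptor.
    """
    half = model.n_states // 2 if model.n_states in (4, 6) else model.n_states
    bound_idx = {0} | ({half} if half < model.n_states else set())
    edges = np.append(jump_t, T)
    windows = []
    for k in range(jump_s.size):
        if int(jump_s[k]) not in bound_idx:
            continue
        t_b = edges[k] + rng.exponential(1.0 / k_bleach)
        if t_b < edges[k + 1]:
            windows.append((t_b, float(edges[k + 1])))
    return windows


def _telegraph_dark_mask(times, t0, t1, k_d, k_b, p_b, rng):
    """Boolean mask of photons falling in acceptor dark intervals."""
    dark = np.zeros(times.size, dtype=bool)
    t = t0
    bright = rng.random() < p_b
    while t < t1:
        rate = k_d if bright else k_b
        if rate <= 0:
            break
        dt = rng.exponential(1.0 / rate)
        t_next = min(t + dt, t1)
        if not bright:
            dark |= (times >= t) & (times < t_next)
        t = t_next
        bright = not bright
    return dark


def recolor_trajectory(
    traj: PhotonTrajectory,
    transition_interval,
    t_TC: float,
    E_B: float,
    E_TC: float,
    E_U: float,
    blink: BlinkParams | None = None,
    seed: int | np.random.Generator = 0,
    direction: str = BINDING,
    truncate: bool = True,
) -> PhotonTrajectory:
    """Recolor a single-transition trajectory, preserving photon times exactly.

    A transient-complex region of exponentially distributed duration (mean
    ``t_TC``) is centered on the midpoint of ``transition_interval`` (a
    ``(t_before, t_after)`` photon pair or a scalar time); flanking regions
    carry the original states implied by ``direction``. Acceptor dark
    intervals drawn from the blink kinetics are then recolored at E = 0.06.
    """
    if transition_interval is None:
        raise ValueError("a transition interval is required for recoloring")
    if len(traj) == 0:
        raise ValueError("cannot recolor an empty trajectory")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mid = (
        float(np.mean(transition_interval))
        if np.ndim(transition_interval) > 0
        else float(transition_interval)
    )
    times = traj.times
    # rng order: TC duration, region colors, blink path, dark recolors
    dur_drawn = rng.exponential(t_TC) if t_TC > 0 else 0.0
    tc_lo, tc_hi = mid - dur_drawn / 2.0, mid + dur_drawn / 2.0
    if truncate:
        tc_lo = max(tc_lo, times[0])
        tc_hi = min(tc_hi, times[-1])
    e_pre, e_post = (E_U, E_B) if direction == BINDING else (E_B, E_U)
    eff = np.where(times < tc_lo, e_pre, np.where(times >= tc_hi, e_post, E_TC))
    if dur_drawn == 0.0:
        eff = np.where(times < mid, e_pre, e_post)
    colors = (rng.random(times.size) < eff).astype(np.int8)
    meta = dict(traj.meta)
    meta.update(
        {
            "recolor_t_TC": t_TC,
            "tc_duration_drawn_s": float(dur_drawn),
            "tc_duration_effective_s": float(max(tc_hi - tc_lo, 0.0)) if dur_drawn else 0.0,
            "direction": direction,
        }
    )
    if blink is not None:
        n_ms = traj.count_rate_ms
        k_d = blink.k_d(n_ms if n_ms > 0 else blink.n_0)
        p_b = blink.k_b / (blink.k_b + k_d)
        dark = _telegraph_dark_mask(times, times[0], times[-1], k_d, blink.k_b, p_b, rng)
        colors[dark] = (rng.random(int(dark.sum())) < blink.E_d).astype(np.int8)
    return PhotonTrajectory(traj.id, times.copy(), colors, meta)


def simulate_transition_segments(
    n_segments: int,
    window_s: float = 2e-3,
    rate_ms: float = 500.0,
    E_B: float = 0.6,
    E_U: float = 0.25,
    E_TC: float | None = None,
    t_TC: float = 0.0,
    blink: BlinkParams | None = None,
    seed: int = 0,
    directions: str = "alternate",
) -> list[TransitionSegment]:
    """Single-transition analysis segments built with the recoloring protocol.

    Each segment has Poisson photon times on ``[0, window_s]`` and one
    transition at the central interphoton interval; ``t_TC = 0`` gives
    instantaneous transitions.
    """
    if E_TC is None:
        E_TC = 0.5 * (E_B + E_U)
    seeds = np.random.SeedSequence(seed).spawn(n_segments)
    segs = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        while True:
            n = rng.poisson(rate_ms * 1e3 * window_s)
            if n >= 4:
                break
        times = np.sort(rng.uniform(0.0, window_s, n))
        times = times[np.concatenate(([True], np.diff(times) > 0))]
        k = int(np.searchsorted(times, window_s / 2.0))
        k = min(max(k, 1), times.size - 1)
        interval = (times[k - 1], times[k])
        if directions == "alternate":
            direction = BINDING if i % 2 == 0 else DISSOCIATION
        else:
            direction = directions
        base = PhotonTrajectory(
            f"seg-{i}", times, np.zeros(times.size, dtype=np.int8), {"window_s": window_s}
        )
        rec = recolor_trajectory(
            base, interval, t_TC, E_B, E_TC, E_U, blink=blink, seed=rng, direction=direction
        )
        segs.append(
            TransitionSegment(
                traj_id=rec.id,
                times=rec.times,
                colors=rec.colors,
                direction=direction,
                t_transition=float(np.mean(interval)),
                window=(0.0, window_s),
                meta=rec.meta,
            )
        )
    return segs


def generate_condition_series(base_cfg: SimConfig, series: list[dict]) -> dict:
    """One simulated dataset per condition, with a ground-truth manifest.

    Each entry of ``series`` carries a ``label`` plus overrides of the
    two-state parameters (and optionally ``partner_conc_M`` and ``seed``).
    """
    conditions = []
    manifest = {"base_seed": base_cfg.seed, "conditions": []}
    for k, spec in enumerate(series):
        spec = dict(spec)
        label = spec.pop("label", f"cond-{k}")
        conc = spec.pop("partner_conc_M", None)
        seed = spec.pop("seed", base_cfg.seed + k)
        two = dataclasses.replace(base_cfg.two, **{
            key: spec.pop(key) for key in list(spec) if key in ("E_B", "E_U", "k_A_app", "k_D")
        })
        cfg = dataclasses.replace(base_cfg, two=two, seed=seed, label=label, **spec)
        trajs = simulate_ctmc_photons(cfg)
        if conc is not None:
            for tr in trajs:
                tr.meta["partner_conc_M"] = conc
        truth = dataclasses.asdict(two)
        truth.update({"label": label, "seed": seed, "partner_conc_M": conc})
        manifest["conditions"].append(truth)
        conditions.append({"label": label, "trajectories": trajs, "truth": truth})
    return {"conditions": conditions, "manifest": manifest}
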