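"""Viterbi state assignment of photon streams and transition-segment extraction.

The Viterbi path maximizes ``p_eq(s1) F(c1)_{s1} prod_i [exp(K tau_i)]_{s_i,s_{i-1}}
F(c_i)_{s_i}`` over state sequences by max-product dynamic programming in log
space, with ties broken toward the lower state index (bound first).

Transitions are kept only when the residence times on both sides exceed a
minimum (default 200 us); shorter excursions — typically acceptor-blinking
artifacts — are merged back into the surrounding state so the photon record
stays contiguous for downstream windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._propagate import get_decomposition, viterbi_decode
from .models import KineticModel
from .trajectory import PhotonTrajectory

__all__ = [
    "StatePath",
    "Transition",
    "TransitionSegment",
    "viterbi_path",
    "find_transitions",
    "extract_segments",
    "first_event_only",
]

log = logging.getLogger(__name__)

BINDING = "binding"
DISSOCIATION = "dissociation"

#: default residence filter (s)
MIN_RESIDENCE = 200e-6
#: default analysis window around a transition (s)
WINDOW_TOTAL = 2e-3
WINDOW_MIN = 400e-6
WINDOW_MAX = 3e-3


@dataclass
class StatePath:
    """Per-photon most-probable state indices and the path log score."""

    traj_id: str
    states: np.ndarray
    score: float
    state_labels: tuple

    def __len__(self) -> int:
        return self.states.size

    def binding_states(self) -> np.ndarray:
        """Collapse blink copies onto the kinetic (bound/unbound/TC) states.

        Labels starting with 'B' map to 0 (bound), 'TC' to 1, 'U' to 2 for
        TC models; for plain two/four-state models 'U*' maps to 1.
        """
        labels = self.state_labels
        has_tc = any(l.startswith("TC") for l in labels)
        lut = np.empty(len(labels), dtype=np.int8)
        for i, l in enumerate(labels):
            if l.startswith("TC"):
                lut[i] = 1
            elif l.startswith("B"):
                lut[i] = 0
            else:
                lut[i] = 2 if has_tc else 1
        return lut[self.states]


@dataclass
class Transition:
    traj_id: str
    time: float  # midpoint of the flagged interphoton interval (s)
    index: int  # photon index of the first photon after the transition
    direction: str  # binding | dissociation
    left_dwell: float
    right_dwell: float


@dataclass
class TransitionSegment:
    """A photon window around a single binding or dissociation transition."""

    traj_id: str
    times: np.ndarray
    colors: np.ndarray
    direction: str
    t_transition: float
    window: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.colors = np.asarray(self.colors, dtype=np.int8)

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]

    @property
    def count_rate_ms(self) -> float:
        if self.duration <= 0:
            return 0.0
        return len(self) / self.duration / 1e3


def viterbi_path(traj: PhotonTrajectory, model: KineticModel) -> StatePath:
    """Most probable per-photon state sequence under ``model``."""
    if len(traj) == 0:
        return StatePath(traj.id, np.empty(0, dtype=np.int32), 0.0, model.state_labels)
    dec = get_decomposition(model)
    try:
        states, score = viterbi_decode(traj.times, traj.colors, dec, model.p_eq)
    except ValueError as exc:
        raise ValueError(f"trajectory {traj.id!r}: {exc}") from exc
    return StatePath(traj.id, states, score, model.state_labels)


def _runs(states: np.ndarray) -> list[list[int]]:
    """Contiguous runs as [state, i_start, i_end] photon index ranges."""
    out = []
    start = 0
    for i in range(1, states.size):
        if states[i] != states[i - 1]:
            out.append([int(states[start]), start, i - 1])
            start = i
    out.append([int(states[start]), start, states.size - 1])
    return out


def _run_bounds(runs, times):
    """Dwell boundaries: trajectory start, interval midpoints, trajectory end."""
    bounds = [times[0]]
    for r in runs[:-1]:
        i = r[2]
        bounds.append(0.5 * (times[i] + times[i + 1]))
    bounds.append(times[-1])
    return np.asarray(bounds)


def find_transitions(
    traj: PhotonTrajectory,
    path: StatePath,
    min_residence: float = MIN_RESIDENCE,
) -> list[Transition]:
    """State changes whose flanking dwells both exceed ``min_residence``.

    Internal dwells shorter than the threshold are merged into the
    surrounding state (shortest first), which removes blink-induced spurious
    round trips instead of leaving photon gaps.
    """
    states = path.binding_states()
    if states.size < 2:
        return []
    times = traj.times
    runs = _runs(states)
    # iteratively merge the shortest sub-threshold internal dwell
    while len(runs) > 2:
        bounds = _run_bounds(runs, times)
        dwells = np.diff(bounds)
        internal = dwells[1:-1]
        if internal.size == 0 or internal.min() >= min_residence:
            break
        k = 1 + int(np.argmin(internal))
        prev_run, cur, next_run = runs[k - 1], runs[k], runs[k + 1]
        if prev_run[0] == next_run[0]:
            merged = [prev_run[0], prev_run[1], next_run[2]]
            runs = runs[: k - 1] + [merged] + runs[k + 2 :]
        else:  # only possible for >2 collapsed states; absorb into the longer side
            prev_run[2] = cur[2]
            runs = runs[:k] + runs[k + 1 :]
    bounds = _run_bounds(runs, times)
    dwells = np.diff(bounds)
    out = []
    for k in range(len(runs) - 1):
        if dwells[k] < min_residence or dwells[k + 1] < min_residence:
            continue
        s0, s1 = runs[k][0], runs[k + 1][0]
        direction = BINDING if s1 < s0 else DISSOCIATION
        out.append(
            Transition(
                traj_id=traj.id,
                time=float(bounds[k + 1]),
                index=runs[k + 1][1],
                direction=direction,
                left_dwell=float(dwells[k]),
                right_dwell=float(dwells[k + 1]),
            )
        )
    return out


def extract_segments(
    traj: PhotonTrajectory,
    transitions: list,
    window_total: float = WINDOW_TOTAL,
    window_min: float = WINDOW_MIN,
    window_max: float = WINDOW_MAX,
) -> list[TransitionSegment]:
    """Photon windows centered on each transition, one transition per window.

    Windows are truncated at neighboring transition midpoints and trajectory
    ends, dropped when shorter than ``window_min`` and capped at ``window_max``.
    """
    half = min(window_total, window_max) / 2.0
    segs = []
    for j, tr in enumerate(transitions):
        lo = tr.time - half
        hi = tr.time + half
        if j > 0:
            lo = max(lo, transitions[j - 1].time)
        if j + 1 < len(transitions):
            hi = min(hi, transitions[j + 1].time)
        lo = max(lo, traj.times[0])
        hi = min(hi, traj.times[-1] + 1e-12)
        if hi - lo < window_min:
            log.debug("segment at t=%.6f s dropped: window %.0f us", tr.time, (hi - lo) * 1e6)
            continue
        sel = (traj.times >= lo) & (traj.times < hi)
        if sel.sum() < 2:
            continue
        segs.append(
            TransitionSegment(
                traj_id=traj.id,
                times=traj.times[sel],
                colors=traj.colors[sel],
                direction=tr.direction,
                t_transition=tr.time,
                window=(lo, hi),
                meta=dict(traj.meta),
            )
        )
    return segs


def first_event_only(transitions: list) -> list:
    """Keep only the first binding transition of each trajectory.

    For donor-only unbound states (folded-pair experiments) later apparent
    dissociations may be acceptor photobleaching, so only the onset of the
    first binding event is trustworthy.
    """
    seen: set = set()
    out = []
    for tr in transitions:
        if tr.traj_id in seen:
            continue
        seen.add(tr.traj_id)
        # trajectories that begin bound have no observed binding onset
        if tr.direction == BINDING:
            out.append(tr)
    return out
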