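"""Binned trajectories, FRET-efficiency histograms, and donor-acceptor
cross-correlation with relaxation-rate extraction."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .trajectory import ACCEPTOR, DONOR, PhotonTrajectory

__all__ = [
    "BinnedTrajectory",
    "CorrelationCurve",
    "bin_trajectory",
    "fret_histogram",
    "cross_correlation",
    "fit_relaxation",
]


@dataclass
class BinnedTrajectory:
    bin_time: float
    t: np.ndarray  # bin left edges (s)
    n_donor: np.ndarray
    n_acceptor: np.ndarray

    @property
    def n_total(self) -> np.ndarray:
        return self.n_donor + self.n_acceptor

    @property
    def efficiency(self) -> np.ndarray:
        """Per-bin apparent efficiency; NaN for empty bins."""
        tot = self.n_total
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.n_acceptor / np.where(tot > 0, tot, 1), np.nan)


@dataclass
class CorrelationCurve:
    lags: np.ndarray  # positive lag times (s)
    C_DA: np.ndarray
    bin_time: float
    segment_min: float
    n_segments: int
    segment_curves: np.ndarray | None = None  # per-segment curves, for jackknife errors
    rate: float | None = None
    rate_stderr: float | None = None
    amplitude: float | None = None
    baseline: float | None = None


def bin_trajectory(traj: PhotonTrajectory, bin_time: float) -> BinnedTrajectory:
    """Left-closed right-open bins from the trajectory start; counts partition
    the photons exactly."""
    if bin_time <= 0:
        raise ValueError("bin_time must be positive")
    if len(traj) == 0:
        z = np.empty(0)
        return BinnedTrajectory(bin_time, z, z.astype(int), z.astype(int))
    t0 = traj.times[0]
    n_bins = int(np.floor((traj.times[-1] - t0) / bin_time)) + 1
    idx = np.minimum(((traj.times - t0) / bin_time).astype(int), n_bins - 1)
    n_a = np.bincount(idx[traj.colors == ACCEPTOR], minlength=n_bins)
    n_d = np.bincount(idx[traj.colors == DONOR], minlength=n_bins)
    t = t0 + bin_time * np.arange(n_bins)
    return BinnedTrajectory(bin_time, t, n_d, n_a)


def fret_histogram(
    trajs,
    bin_time: float = 1e-3,
    n_bins: int = 50,
    min_counts: int = 1,
):
    """Histogram of per-bin apparent efficiencies over all trajectories.

    Bins with fewer than ``min_counts`` photons are excluded (E is undefined
    for empty bins). Returns (counts, edges).
    """
    if isinstance(trajs, PhotonTrajectory):
        trajs = [trajs]
    effs = []
    for tr in trajs:
        b = bin_trajectory(tr, bin_time)
        sel = b.n_total >= min_counts
        effs.append(b.efficiency[sel])
    all_e = np.concatenate(effs) if effs else np.empty(0)
    return np.histogram(all_e, bins=n_bins, range=(0.0, 1.0))


def cross_correlation(
    trajs,
    bin_time: float = 1e-4,
    max_lag: float = 10e-3,
    segment_min: float = 20e-3,
) -> CorrelationCurve:
    """Donor-acceptor cross-correlation
    ``C_DA(tau) = <N_D(t+tau) N_A(t)> / (<N_D><N_A>) - 1``
    averaged over qualifying segments (trajectories longer than
    ``segment_min``); lags are integer multiples of ``bin_time``.
    """
    if isinstance(trajs, PhotonTrajectory):
        trajs = [trajs]
    n_lags = max(int(round(max_lag / bin_time)), 1)
    curves = []
    for tr in trajs:
        if tr.duration < segment_min:
            continue
        b = bin_trajectory(tr, bin_time)
        nd = b.n_donor.astype(float)
        na = b.n_acceptor.astype(float)
        if nd.size <= n_lags or nd.mean() == 0 or na.mean() == 0:
            continue
        c = np.empty(n_lags)
        for k in range(1, n_lags + 1):
            c[k - 1] = np.mean(nd[k:] * na[:-k]) / (nd.mean() * na.mean()) - 1.0
        curves.append(c)
    if not curves:
        raise ValueError(f"no segments longer than {segment_min} s")
    curves = np.asarray(curves)
    lags = bin_time * np.arange(1, n_lags + 1)
    return CorrelationCurve(
        lags=lags,
        C_DA=curves.mean(axis=0),
        bin_time=bin_time,
        segment_min=segment_min,
        n_segments=len(curves),
        segment_curves=curves,
    )


def _fit_exp(lags, c):
    def model(tau, a, lam, base):
        return a * np.exp(-lam * tau) + base

    a0 = float(c[0])
    lam0 = 1.0 / max(lags[-1] / 3.0, lags[0])
    popt, pcov = curve_fit(
        model, lags, c,
        p0=(a0, lam0, 0.0),
        bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=10000,
    )
    return popt, pcov


def fit_relaxation(curve: CorrelationCurve) -> CorrelationCurve:
    """Least-squares fit of ``A exp(-lambda tau) + c``; fills the curve's
    rate, stderr, amplitude and baseline fields and returns it.

    Residuals of the averaged curve are correlated across lags, so when
    per-segment curves are available the rate uncertainty comes from a
    jackknife over segments rather than the covariance of the pooled fit.
    """
    if curve.lags.size < 5:
        raise ValueError("need at least 5 lag points")
    try:
        popt, pcov = _fit_exp(curve.lags, curve.C_DA)
    except RuntimeError as exc:
        curve.rate = None
        curve.rate_stderr = None
        raise RuntimeError(f"relaxation fit did not converge: {exc}") from exc
    curve.amplitude = float(popt[0])
    curve.rate = float(popt[1])
    curve.baseline = float(popt[2])
    curve.rate_stderr = float(np.sqrt(pcov[1, 1]))
    segs = curve.segment_curves
    if segs is not None and segs.shape[0] >= 5:
        n = segs.shape[0]
        total = segs.sum(axis=0)
        loo = []
        for i in range(n):
            try:
                p_i, _ = _fit_exp(curve.lags, (total - segs[i]) / (n - 1))
                loo.append(p_i[1])
            except RuntimeError:  # pragma: no cover
                continue
        if len(loo) >= 5:
            loo = np.asarray(loo)
            m = loo.size
            curve.rate_stderr = float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))
    return curve
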