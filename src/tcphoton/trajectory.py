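"""Photon trajectories and the plain-text photon file format.

A photon trajectory is the atomic input of every analysis stage: strictly
increasing arrival times (seconds) plus a per-photon channel (0 = donor,
1 = acceptor) and free-form metadata.

File format ("PHOT-TSV"): optional ``#``-prefixed ``key=value`` header lines,
then tab-separated columns ``time_s`` and ``channel``, with an optional third
``trajectory_id`` column for multi-molecule files. An equivalent HDF5 layout
(``/trajectories/<id>/times``, ``.../channels`` with attrs) is supported for
large datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhotonTrajectory", "read_phot_tsv", "write_phot_tsv", "read_phot_h5", "write_phot_h5"]

DONOR = 0
ACCEPTOR = 1


@dataclass
class PhotonTrajectory:
    id: str
    times: np.ndarray
    colors: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.colors = np.asarray(self.colors, dtype=np.int8)
        if self.times.ndim != 1 or self.times.shape != self.colors.shape:
            raise ValueError("times and colors must be matching 1-D arrays")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"photon times must be strictly increasing in {self.id!r}")
        bad = ~np.isin(self.colors, (DONOR, ACCEPTOR))
        if bad.any():
            raise ValueError(f"channels must be 0 (donor) or 1 (acceptor) in {self.id!r}")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.times[-1] - self.times[0])

    @property
    def count_rate_ms(self) -> float:
        """Mean photon count rate in photons per millisecond."""
        d = self.duration
        if d <= 0:
            return 0.0
        return len(self) / d / 1e3

    @property
    def n_acceptor(self) -> int:
        return int(np.sum(self.colors == ACCEPTOR))

    @property
    def n_donor(self) -> int:
        return int(np.sum(self.colors == DONOR))

    def mean_efficiency(self) -> float:
        if len(self) == 0:
            return np.nan
        return self.n_acceptor / len(self)

    def window(self, t_lo: float, t_hi: float, new_id: str | None = None) -> "PhotonTrajectory":
        """Photons with t_lo <= t < t_hi, metadata carried over."""
        sel = (self.times >= t_lo) & (self.times < t_hi)
        return PhotonTrajectory(
            id=new_id or self.id,
            times=self.times[sel],
            colors=self.colors[sel],
            meta=dict(self.meta),
        )


def _fmt_meta(meta: dict) -> list[str]:
    return [f"# {k}={v}" for k, v in meta.items()]


def write_phot_tsv(path, trajs) -> None:
    if isinstance(trajs, PhotonTrajectory):
        trajs = [trajs]
    multi = len(trajs) > 1
    with open(path, "w") as fh:
        meta = trajs[0].meta if trajs else {}
        for line in _fmt_meta(meta):
            fh.write(line + "\n")
        if multi:
            fh.write("time_s\tchannel\ttrajectory_id\n")
        else:
            fh.write("time_s\tchannel\n")
        for tr in trajs:
            for t, c in zip(tr.times, tr.colors):
                if multi:
                    fh.write(f"{t:.12f}\t{int(c)}\t{tr.id}\n")
                else:
                    fh.write(f"{t:.12f}\t{int(c)}\n")


def read_phot_tsv(path) -> list[PhotonTrajectory]:
    meta: dict = {}
    times: list[float] = []
    colors: list[int] = []
    ids: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = _coerce(v.strip())
                continue
            parts = line.split("\t")
            if parts[0] == "time_s":  # column header
                continue
            times.append(float(parts[0]))
            colors.append(int(parts[1]))
            ids.append(parts[2] if len(parts) > 2 else "0")
    out = []
    uniq = list(dict.fromkeys(ids))
    times_a = np.array(times)
    colors_a = np.array(colors)
    ids_a = np.array(ids)
    for uid in uniq:
        sel = ids_a == uid
        out.append(PhotonTrajectory(uid, times_a[sel], colors_a[sel], dict(meta)))
    return out


def _coerce(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v


def write_phot_h5(path, trajs) -> None:
    import h5py

    if isinstance(trajs, PhotonTrajectory):
        trajs = [trajs]
    with h5py.File(path, "w") as f:
        root = f.create_group("trajectories")
        for tr in trajs:
            g = root.create_group(str(tr.id))
            g.create_dataset("times", data=tr.times)
            g.create_dataset("channels", data=tr.colors)
            for k, v in tr.meta.items():
                g.attrs[k] = v


def read_phot_h5(path) -> list[PhotonTrajectory]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for uid, g in f["trajectories"].items():
            out.append(
                PhotonTrajectory(
                    uid,
                    np.asarray(g["times"]),
                    np.asarray(g["channels"]),
                    {k: v for k, v in g.attrs.items()},
                )
            )
    return out
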