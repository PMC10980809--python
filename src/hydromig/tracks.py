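"""Trajectory data model, tabular I/O, and preprocessing for migration analysis.

Tracks are time-stamped cell positions (hours, micrometres).  All analysis
downstream assumes a uniform sampling interval ``dt``; raw tracker exports
with frame gaps are split at the gaps rather than interpolated, so no
position is ever fabricated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackSet",
    "read_tracks",
    "write_tracks",
    "filter_short_tracks",
    "project_to_2d",
    "truncate_tracks",
    "speed_vs_time",
]

#: default column names of the delimited track table
DEFAULT_COLUMNS: Mapping[str, str] = {
    "id": "track_id",
    "t": "t_h",
    "x": "x_um",
    "y": "y_um",
    "z": "z_um",
}

_TIME_TOL = 1e-6  # hours; tolerance on dt multiples


class TrackValidationError(ValueError):
    """A track violates an invariant (non-monotone times, bad shape ...)."""


@dataclass(frozen=True)
class Track:
    """A single cell trajectory.

    Parameters
    ----------
    id
        Label of the track (tracker-assigned id).
    times
        Sample times in hours, strictly increasing.
    positions
        ``(n, d)`` array of coordinates in micrometres, ``d`` in (2, 3).
    """

    id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if p.ndim != 2 or p.shape[1] not in (2, 3):
            raise TrackValidationError(
                f"track {self.id!r}: positions must be (n, 2) or (n, 3), got {p.shape}"
            )
        if t.shape[0] != p.shape[0]:
            raise TrackValidationError(
                f"track {self.id!r}: {t.shape[0]} times but {p.shape[0]} positions"
            )
        if t.size and np.any(np.diff(t) <= 0):
            raise TrackValidationError(f"track {self.id!r}: times not strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(p))):
            raise TrackValidationError(f"track {self.id!r}: non-finite values")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", p)

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    def path_length(self) -> float:
        """Total path length: sum of step magnitudes, in micrometres."""
        if self.n_samples < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.positions, axis=0), axis=1).sum())

    def velocities(self, dt: float) -> np.ndarray:
        """Finite-difference velocities ``(n-1, d)`` in um/hr at interval dt."""
        return np.diff(self.positions, axis=0) / dt


@dataclass(frozen=True)
class TrackSet:
    """A collection of tracks sharing one sampling interval and dimensionality."""

    tracks: tuple[Track, ...]
    dt: float
    ndim: int = field(default=0)

    def __post_init__(self) -> None:
        tracks = tuple(self.tracks)
        ndim = self.ndim
        if ndim == 0:
            ndim = tracks[0].ndim if tracks else 2
        for tr in tracks:
            if tr.ndim != ndim:
                raise TrackValidationError(
                    f"track {tr.id!r} is {tr.ndim}D but the set is {ndim}D"
                )
            steps = np.diff(tr.times)
            if steps.size and np.any(np.abs(steps / self.dt - np.round(steps / self.dt)) > _TIME_TOL):
                raise TrackValidationError(
                    f"track {tr.id!r}: time steps are not integer multiples of dt={self.dt}"
                )
        object.__setattr__(self, "tracks", tracks)
        object.__setattr__(self, "ndim", ndim)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def to_frame(self, columns: Mapping[str, str] = DEFAULT_COLUMNS) -> pd.DataFrame:
        """Long-format table of all samples (one row per time point)."""
        coords = ["x", "y", "z"][: self.ndim]
        rows = []
        for tr in self.tracks:
            df = pd.DataFrame(tr.positions, columns=[columns[c] for c in coords])
            df.insert(0, columns["t"], tr.times)
            df.insert(0, columns["id"], tr.id)
            rows.append(df)
        if not rows:
            cols = [columns["id"], columns["t"]] + [columns[c] for c in coords]
            return pd.DataFrame(columns=cols)
        return pd.concat(rows, ignore_index=True)


def _infer_dt(all_times: Iterable[np.ndarray]) -> float:
    """Modal inter-sample difference across all tracks."""
    diffs = np.concatenate([np.diff(t) for t in all_times if len(t) > 1])
    if diffs.size == 0:
        raise TrackValidationError("cannot infer dt: no track has two samples")
    rounded = np.round(diffs, 9)
    values, counts = np.unique(rounded, return_counts=True)
    return float(values[np.argmax(counts)])


def _split_at_gaps(id_: str, times: np.ndarray, pos: np.ndarray, dt: float,
                   gap_factor: float = 1.5) -> list[Track]:
    """Split a trajectory wherever the time step exceeds gap_factor * dt.

    Splitting (rather than interpolating) avoids fabricating positions for
    frames the tracker bridged over.
    """
    if len(times) < 2:
        return [Track(id_, times, pos)]
    breaks = np.where(np.diff(times) > gap_factor * dt)[0]
    if breaks.size == 0:
        return [Track(id_, times, pos)]
    pieces = []
    start = 0
    for b in list(breaks) + [len(times) - 1]:
        stop = b + 1
        seg_t, seg_p = times[start:stop], pos[start:stop]
        if len(seg_t):
            suffix = "" if breaks.size == 0 else f"#{len(pieces)}"
            pieces.append(Track(f"{id_}{suffix}", seg_t, seg_p))
        start = stop
    return pieces


def read_tracks(
    path: str | Path,
    columns: Mapping[str, str] = DEFAULT_COLUMNS,
    delimiter: str = ",",
    split_gaps: bool = True,
) -> TrackSet:
    """Read a delimited track table into a :class:`TrackSet`.

    The file must contain columns for track id, time (hours) and 2-3
    coordinates (micrometres); names are remapped through ``columns``.
    ``dt`` is inferred as the modal inter-sample time difference.  Tracks
    with frame gaps larger than 1.5 dt are split at the gap.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    required = [columns["id"], columns["t"], columns["x"], columns["y"]]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    has_z = columns["z"] in df.columns
    coord_cols = [columns["x"], columns["y"]] + ([columns["z"]] if has_z else [])

    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for id_, g in df.groupby(columns["id"], sort=False):
        g = g.sort_values(columns["t"], kind="stable")
        t = g[columns["t"]].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise TrackValidationError(f"track {id_!r}: duplicate or non-monotone times")
        groups[str(id_)] = (t, g[coord_cols].to_numpy(dtype=float))

    dt = _infer_dt(t for t, _ in groups.values())
    tracks: list[Track] = []
    for id_, (t, p) in groups.items():
        if split_gaps:
            tracks.extend(_split_at_gaps(id_, t, p, dt))
        else:
            tracks.append(Track(id_, t, p))
    return TrackSet(tuple(tracks), dt=dt)


def write_tracks(
    ts: TrackSet,
    path: str | Path,
    columns: Mapping[str, str] = DEFAULT_COLUMNS,
    delimiter: str = ",",
) -> None:
    """Write a TrackSet as delimited text readable by :func:`read_tracks`."""
    ts.to_frame(columns).to_csv(path, sep=delimiter, index=False)


def filter_short_tracks(ts: TrackSet, min_path_length: float = 30.0) -> TrackSet:
    """Drop tracks whose total path length is below ``min_path_length`` (um).

    Mirrors the tracker-export cleaning step that removes short tracks
    (default threshold 30 um) attributable to artifact motion.  Order is
    preserved; the operation is idempotent.
    """
    if min_path_length < 0:
        raise ValueError("min_path_length must be non-negative")
    kept = tuple(tr for tr in ts.tracks if tr.path_length() >= min_path_length)
    return TrackSet(kept, dt=ts.dt, ndim=ts.ndim)


def project_to_2d(ts: TrackSet) -> TrackSet:
    """Project 3D trajectories onto the xy plane (drop the z coordinate)."""
    if ts.ndim == 2:
        warnings.warn("TrackSet is already 2D; project_to_2d is a no-op", stacklevel=2)
        return ts
    tracks = tuple(Track(tr.id, tr.times, tr.positions[:, :2]) for tr in ts.tracks)
    return TrackSet(tracks, dt=ts.dt, ndim=2)


def truncate_tracks(ts: TrackSet, t_start: float, min_samples: int = 3) -> TrackSet:
    """Keep only samples at time >= ``t_start`` hours.

    Used to gate analysis to the time-invariant migration regime (e.g. 30 h
    after spheroid embedding).  Tracks left with fewer than ``min_samples``
    samples are dropped (at least two velocity vectors are needed for the
    angular-displacement and axis statistics).
    """
    if t_start < 0:
        raise ValueError("t_start must be non-negative")
    kept: list[Track] = []
    for tr in ts.tracks:
        sel = tr.times >= t_start - _TIME_TOL
        if int(sel.sum()) >= min_samples:
            kept.append(Track(tr.id, tr.times[sel], tr.positions[sel]))
    if not kept:
        warnings.warn(f"no tracks remain after truncation at t_start={t_start}", stacklevel=2)
    return TrackSet(tuple(kept), dt=ts.dt, ndim=ts.ndim)


def speed_vs_time(ts: TrackSet, window: float) -> pd.DataFrame:
    """Population-mean step speed versus time, in windows of ``window`` hours.

    Each step contributes ``|dr| / dt`` at its midpoint time; windows with no
    steps are omitted.  On a stationary process the profile is flat, which is
    the check that licenses time-invariant trajectory models.

    Returns a DataFrame with columns ``t_h`` (window centre), ``speed_um_hr``
    and ``n_steps``.
    """
    if window < ts.dt - _TIME_TOL:
        raise ValueError("window must be at least dt")
    mids, speeds = [], []
    for tr in ts.tracks:
        if tr.n_samples < 2:
            continue
        step = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
        dt_steps = np.diff(tr.times)
        mids.append((tr.times[:-1] + tr.times[1:]) / 2)
        speeds.append(step / dt_steps)
    if not mids:
        return pd.DataFrame(columns=["t_h", "speed_um_hr", "n_steps"])
    mid = np.concatenate(mids)
    spd = np.concatenate(speeds)
    idx = np.floor(mid / window).astype(int)
    out = []
    for k in np.unique(idx):
        sel = idx == k
        out.append(((k + 0.5) * window, float(spd[sel].mean()), int(sel.sum())))
    return pd.DataFrame(out, columns=["t_h", "speed_um_hr", "n_steps"])
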