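"""Trajectory containers, track-table I/O, pairing and basic route metrics.

A :class:`Trajectory` is one bird's (or a pair-mean) time-ordered planar
track at a nominally fixed 5 Hz sampling rate, with the release metadata
(chain, generation, release) the transmission-chain design needs.  A
:class:`PairFlight` holds the experienced- and naive-role trajectories of
one release, resampled onto a shared time grid.

Pairs whose birds flew on average more than 250 m apart are not treated as
pairs at all and are dropped by :func:`filter_pairs`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError
from .geodesy import project_to_plane

logger = logging.getLogger(__name__)

DT = 0.2  # nominal sampling interval, seconds (5 Hz)


@dataclass
class Trajectory:
    """Planar track of one bird (or a pair mean) for one release."""

    bird_id: str
    chain_id: str
    generation: int
    release: int
    t: np.ndarray          # seconds, strictly increasing
    xy: np.ndarray         # (n, 2) metres, x east / y north
    valid: np.ndarray = None  # bool mask; False = logger gap / masked sample

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.t), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.t) != len(self.xy):
            raise DataError("t and xy lengths differ")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise DataError("timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def flight_key(self) -> tuple:
        return (self.chain_id, self.generation, self.release, self.bird_id)

    def path_length(self) -> float:
        """Cumulative travelled distance in metres over valid samples."""
        xy = self.xy[self.valid]
        if len(xy) < 2:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bird_id": self.bird_id,
            "chain": self.chain_id,
            "generation": self.generation,
            "release": self.release,
            "time_s": self.t,
            "x_m": self.xy[:, 0],
            "y_m": self.xy[:, 1],
        })


@dataclass
class PairFlight:
    """Two role-labelled trajectories on an identical time base."""

    experienced: Trajectory
    naive: Trajectory
    chain_id: str
    generation: int
    release: int
    is_surrogate: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.experienced) != len(self.naive):
            raise DataError("pair trajectories have different lengths")

    def __len__(self) -> int:
        return len(self.experienced)

    @property
    def t(self) -> np.ndarray:
        return self.experienced.t

    @property
    def valid(self) -> np.ndarray:
        return self.experienced.valid & self.naive.valid

    @property
    def flight_key(self) -> tuple:
        return (self.chain_id, self.generation, self.release)

    def mean_distance(self) -> float:
        """Mean Euclidean inter-bird distance over valid samples (m)."""
        m = self.valid
        d = np.hypot(*(self.experienced.xy[m] - self.naive.xy[m]).T)
        return float(np.mean(d))


REQUIRED_COLUMNS = ("bird_id", "chain", "generation", "release", "time_s")


def read_flights(path, origin: tuple[float, float] | None = None) -> list[Trajectory]:
    """Read a track table (CSV) into one Trajectory per (bird, chain, generation, release).

    The table needs columns ``bird_id, chain, generation, release, time_s``
    plus either planar ``x_m, y_m`` or geographic ``lat, lon`` (the latter
    require ``origin=(lat0, lon0)``, normally the home loft, and are
    projected azimuthal-equidistant about it).  Rows are sorted by time;
    duplicated timestamps keep the first row and are logged.
    """
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    if {"x_m", "y_m"} <= set(df.columns):
        planar = True
    elif {"lat", "lon"} <= set(df.columns):
        if origin is None:
            raise FormatError("geographic input requires a projection origin")
        planar = False
    else:
        raise FormatError("missing required column: 'x_m'/'y_m' or 'lat'/'lon'")

    flights = []
    for (bird, chain, gen, rel), grp in df.groupby(
            ["bird_id", "chain", "generation", "release"], sort=True):
        grp = grp.sort_values("time_s", kind="mergesort")
        dup = grp["time_s"].duplicated()
        if dup.any():
            logger.warning("flight %s/%s g%s r%s: dropped %d duplicate timestamp(s)",
                           bird, chain, gen, rel, int(dup.sum()))
            grp = grp[~dup]
        t = grp["time_s"].to_numpy(dtype=float)
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise DataError(f"non-monotone time in flight {bird}/{chain} g{gen} r{rel}")
        if planar:
            xy = grp[["x_m", "y_m"]].to_numpy(dtype=float)
        else:
            xy = project_to_plane(grp["lat"].to_numpy(), grp["lon"].to_numpy(), origin)
        flights.append(Trajectory(str(bird), str(chain), int(gen), int(rel), t, xy))
    return flights


def write_flights(flights, path) -> None:
    """Write trajectories back in the same CSV dialect ``read_flights`` reads."""
    frames = [tr.to_frame() for tr in flights]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)


def align_pair(a: Trajectory, b: Trajectory, *, experienced_first: bool = True,
               dt: float = DT, max_offset: float = 0.1, min_overlap: float = 60.0,
               chain_id=None, generation=None, release=None) -> PairFlight:
    """Resample two trajectories onto the shared ``dt`` grid over their overlap.

    Each grid time takes the nearest sample within ``max_offset`` seconds;
    grid points with no sample that close on either track (logger dropouts,
    clock skew) are masked, never interpolated.  Overlap shorter than
    ``min_overlap`` seconds rejects the flight.
    """
    t0 = max(a.t[0], b.t[0])
    t1 = min(a.t[-1], b.t[-1])
    if t1 - t0 < min_overlap:
        raise AlignmentError(
            f"overlap {max(t1 - t0, 0):.1f} s < required {min_overlap:.0f} s")
    grid = t0 + dt * np.arange(int(np.floor((t1 - t0) / dt)) + 1)

    def resample_mask(tr: Trajectory) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(tr.t, grid)
        idx = np.clip(idx, 1, len(tr.t) - 1)
        left = np.abs(grid - tr.t[idx - 1])
        right = np.abs(tr.t[idx] - grid)
        nearest = np.where(left <= right, idx - 1, idx)
        offset = np.minimum(left, right)
        ok = (offset <= max_offset) & tr.valid[nearest]
        return tr.xy[nearest], ok

    xa, va = resample_mask(a)
    xb, vb = resample_mask(b)
    shared = va & vb
    aa = replace(a, t=grid.copy(), xy=xa, valid=shared.copy())
    bb = replace(b, t=grid.copy(), xy=xb, valid=shared.copy())
    exp, nai = (aa, bb) if experienced_first else (bb, aa)
    return PairFlight(
        experienced=exp, naive=nai,
        chain_id=chain_id if chain_id is not None else a.chain_id,
        generation=generation if generation is not None else a.generation,
        release=release if release is not None else a.release)


def filter_pairs(pairs, max_mean_dist: float = 250.0) -> list[PairFlight]:
    """Drop flights whose mean inter-bird distance exceeds ``max_mean_dist`` m.

    Birds that far apart were effectively flying solo and are not analysed
    as a pair; exclusions are logged with the offending mean distance.
    """
    kept = []
    for pf in pairs:
        d = pf.mean_distance()
        if d <= max_mean_dist:
            kept.append(pf)
        else:
            logger.info("excluded flight %s: mean inter-bird distance %.1f m > %.0f m",
                        pf.flight_key, d, max_mean_dist)
    return kept


def mean_pair_trajectory(pf: PairFlight) -> Trajectory:
    """Pointwise midpoint of the two birds' tracks (the pair's trajectory)."""
    xy = 0.5 * (pf.experienced.xy + pf.naive.xy)
    return Trajectory(
        bird_id=f"{pf.experienced.bird_id}+{pf.naive.bird_id}",
        chain_id=pf.chain_id, generation=pf.generation, release=pf.release,
        t=pf.t.copy(), xy=xy, valid=pf.valid.copy())


def route_efficiency(traj: Trajectory, release_site, home) -> float:
    """Beeline release→home distance divided by distance actually travelled.

    Equals 1 only for a straight flight along the beeline; always ≤ 1 for
    tracks connecting the two endpoints.
    """
    release_site = np.asarray(release_site, dtype=float)
    home = np.asarray(home, dtype=float)
    path = traj.path_length()
    if path <= 0:
        raise DataError("zero path length")
    beeline = float(np.hypot(*(home - release_site)))
    return beeline / path
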