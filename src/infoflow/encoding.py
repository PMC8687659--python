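"""Symbolic encoding of trajectories and the signed front/back distance.

The information-theoretic analysis works on a binary symbolisation of each
track: symbol 0 is a clockwise turn, 1 a counterclockwise turn, decided by
the sign of the planar cross product between consecutive motion vectors.
Encoding at a coarser sampling period first subsamples positions, so a
larger period measures coarser turning.

Relative position within a pair is summarised by ``d_EN``: the vector from
the naive to the experienced bird projected on the pair's current direction
of motion (the normalised sum of the two unit velocity vectors).  Positive
``d_EN`` means the experienced bird is in front.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .io import DT, PairFlight, Trajectory

__all__ = [
    "RotationSeries", "ProjectedDistanceSeries",
    "subsample", "rotation_series", "projected_distance",
]


@dataclass
class RotationSeries:
    """Binary clockwise(0)/counterclockwise(1) symbol stream for one track.

    ``symbols[i]`` is derived from positions ``i, i+1, i+2`` of the
    (subsampled) trajectory, so the series is two symbols shorter than the
    position series.  ``valid`` marks symbols whose three positions were all
    observed; ``tie_mask`` marks exact zero cross products (straight-line
    motion), where the previous symbol is carried forward.
    """

    symbols: np.ndarray                 # int8 in {0, 1}
    sampling_period: float              # seconds
    bird_id: str = ""
    flight_key: tuple = ()
    valid: np.ndarray = None
    tie_mask: np.ndarray = None

    def __post_init__(self):
        self.symbols = np.asarray(self.symbols, dtype=np.int8)
        if self.valid is None:
            self.valid = np.ones(len(self.symbols), dtype=bool)
        if self.tie_mask is None:
            self.tie_mask = np.zeros(len(self.symbols), dtype=bool)
        bad = set(np.unique(self.symbols)) - {0, 1}
        if bad:
            raise DataError(f"symbols outside binary alphabet: {bad}")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def tie_fraction(self) -> float:
        """Share of symbols that were zero cross products (audit figure)."""
        n = len(self.symbols)
        return float(self.tie_mask.sum() / n) if n else 0.0


@dataclass
class ProjectedDistanceSeries:
    """Signed experienced-minus-naive distance along the pair's motion.

    Defined per position sample of the (aligned, possibly subsampled) pair;
    the last sample has no forward velocity and is masked, as are samples
    where either bird's velocity is undefined or where the two headings are
    exactly opposed at equal speed (degenerate mean direction).
    """

    d_en: np.ndarray            # metres, signed
    u_hat: np.ndarray           # (n, 2) unit mean-direction vectors
    valid: np.ndarray
    sampling_period: float
    flight_key: tuple = ()

    def __len__(self) -> int:
        return len(self.d_en)


def subsample(traj: Trajectory, period: float) -> Trajectory:
    """Keep every (period/0.2)-th position, starting at the first sample."""
    step = _period_to_step(period, traj)
    if step == 1:
        return traj
    from dataclasses import replace
    return replace(traj, t=traj.t[::step], xy=traj.xy[::step],
                   valid=traj.valid[::step])


def _period_to_step(period: float, traj: Trajectory | None = None) -> int:
    base = DT
    if traj is not None and len(traj.t) >= 2:
        base = float(np.median(np.diff(traj.t)))
    ratio = period / base
    step = int(round(ratio))
    if step < 1 or abs(ratio - step) > 1e-6:
        raise ConfigurationError(
            f"period {period} s is not a positive multiple of the sampling "
            f"interval {base} s")
    if not (0.0 < period <= 4.0 + 1e-9):
        raise ConfigurationError("period must lie in (0, 4.0] seconds")
    return step


def rotation_series(traj: Trajectory, period: float = DT) -> RotationSeries:
    """Encode a trajectory as binary rotation symbols at ``period`` seconds.

    symbol[i] compares the motion vector from position i to i+1 with that
    from i+1 to i+2: positive cross product → counterclockwise (1),
    negative → clockwise (0).  A zero cross product (collinear motion)
    carries the previous symbol forward (0 at the start of the series) and
    is flagged in ``tie_mask``.
    """
    tr = subsample(traj, period)
    if len(tr) < 3:
        raise DataError("need at least 3 positions to encode rotations")
    v = np.diff(tr.xy, axis=0)                      # motion vectors
    cross = v[:-1, 0] * v[1:, 1] - v[:-1, 1] * v[1:, 0]
    ties = cross == 0.0
    raw = (cross > 0).astype(np.int8)
    symbols = raw.copy()
    if ties.any():
        # carry the previous non-tie symbol through runs of zeros
        idx = np.where(~ties, np.arange(len(cross)), -1)
        np.maximum.accumulate(idx, out=idx)
        symbols = np.where(idx >= 0, raw[np.maximum(idx, 0)], 0).astype(np.int8)
    # a symbol needs positions i, i+1, i+2 all observed
    p = tr.valid
    valid = p[:-2] & p[1:-1] & p[2:]
    return RotationSeries(symbols=symbols, sampling_period=period,
                          bird_id=tr.bird_id, flight_key=tr.flight_key,
                          valid=valid, tie_mask=ties)


def projected_distance(pf: PairFlight, period: float = DT) -> ProjectedDistanceSeries:
    """Signed distance of the experienced bird from the naive one, along the
    pair's mean direction of motion.

    At sample i the velocity of each bird is the forward difference
    ``x[i+1] - x[i]``; ``u_hat(i)`` is the normalised sum of the two unit
    velocity vectors and ``d_EN(i) = (x_E(i) - x_N(i)) · u_hat(i)``.
    """
    e = subsample(pf.experienced, period)
    n = subsample(pf.naive, period)
    m = len(e)
    d_en = np.zeros(m)
    u_hat = np.zeros((m, 2))
    valid = np.zeros(m, dtype=bool)

    ve = np.diff(e.xy, axis=0)
    vn = np.diff(n.xy, axis=0)
    spe = np.hypot(ve[:, 0], ve[:, 1])
    spn = np.hypot(vn[:, 0], vn[:, 1])
    moving = (spe > 0) & (spn > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ue = ve / spe[:, None]
        un = vn / spn[:, None]
    s = np.where(moving[:, None], ue + un, 0.0)
    norm = np.hypot(s[:, 0], s[:, 1])
    ok = moving & (norm > 1e-12)
    u = np.zeros_like(s)
    u[ok] = s[ok] / norm[ok, None]

    sample_ok = e.valid[:-1] & e.valid[1:] & n.valid[:-1] & n.valid[1:] & ok
    delta = e.xy[:-1] - n.xy[:-1]
    d_en[:-1] = np.einsum("ij,ij->i", delta, u)
    u_hat[:-1] = u
    valid[:-1] = sample_ok
    return ProjectedDistanceSeries(d_en=d_en, u_hat=u_hat, valid=valid,
                                   sampling_period=period,
                                   flight_key=pf.flight_key)
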